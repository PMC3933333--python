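"""Virtual sectioning and optical-disector sampling.

A VirtualRegion is cut into thick serial sections along z, of which every
period-th is retained (systematic uniform random series with a random start
within one period).  On each retained section a square grid with a uniform
random offset places one unbiased counting frame per grid cell whose frame
would include a portion of the region's cross-section.  Somata are counted
by the optical-disector rule: a soma scores in a frame iff

  (a) its maximal XY profile disk intersects the closed frame square,
  (b) it does not touch the exclusion (forbidden) line: the left edge with
      its infinite upward extension, the bottom edge, and the infinite
      downward extension through the bottom-right corner (the classical
      unbiased-frame drawing; these are the extensions that make an
      exhaustive tiling count every profile exactly once),
  (c) its leading edge (minimum-z point of the sphere, the first to come
      into focus when focusing downward) lies in the frame's z window
      (z_top + guard, z_top + guard + disector height].

Exclusion dominates ties, so frames at pitch = side tile the plane and count
every soma exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .virtual_tissue import Somata, VirtualRegion, UM3_PER_MM3, UM2_PER_MM2


class EmptySeriesError(ValueError):
    """Section series does not intersect the region."""


class InsufficientSectionsError(ValueError):
    """Fewer than the minimum usable sections remain."""


class OverlappingFramesError(ValueError):
    """Grid pitch smaller than the frame side."""


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionSeries:
    """Serial thick sections: every period-th section of the full cut is
    retained (200 um sections at 1.2 mm increments by default)."""

    thickness: float = 200.0
    period: int = 6
    start_offset: float | None = None  # uniform random in one period if None

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("section thickness must be > 0")
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.start_offset is not None and not (
            0 <= self.start_offset < self.period * self.thickness
        ):
            raise ValueError("start_offset must lie within one period")


DEFAULT_GRID_PITCH = {
    "crusI": 2500.0,
    "crusII": 2200.0,
    "lobuleX": 400.0,
    "lobulesIV_VI": 1400.0,
}


@dataclass(frozen=True)
class SamplingDesign:
    """Optical-disector sampling parameters (defaults as used on the
    postmortem material: 19,600 um^2 frames, 5 um guard, 75 um depth,
    region-specific grid pitches)."""

    frame_area: float = 19600.0  # um^2
    guard_depth: float = 5.0  # um
    disector_height: float = 75.0  # um
    grid_pitch: dict = field(
        default_factory=lambda: dict(DEFAULT_GRID_PITCH)
    )
    rng_seed: int = 0

    def __post_init__(self):
        if self.frame_area <= 0:
            raise ValueError("frame_area must be > 0")
        if self.guard_depth < 0 or self.disector_height <= 0:
            raise ValueError("invalid guard/disector depths")
        for name, pitch in self.grid_pitch.items():
            if pitch < self.frame_side:
                raise OverlappingFramesError(
                    f"grid pitch {pitch} um for {name} is below the frame "
                    f"side {self.frame_side:.1f} um: frames would overlap"
                )

    @property
    def frame_side(self) -> float:
        return float(np.sqrt(self.frame_area))

    @property
    def box_volume_um3(self) -> float:
        """Volume of a single counting box (frame area x disector height)."""
        return self.frame_area * self.disector_height

    def pitch_for(self, region_name: str) -> float:
        try:
            return self.grid_pitch[region_name]
        except KeyError:
            raise KeyError(f"no grid pitch configured for {region_name!r}")

    def validate_for_series(self, series: SectionSeries) -> None:
        if self.guard_depth + self.disector_height > series.thickness:
            raise ValueError(
                "guard + disector height exceeds the section thickness"
            )


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------


@dataclass
class Section:
    """One retained thick section with the somata assigned to it."""

    index: int  # position in the retained series, in z order
    z_top: float
    z_bottom: float
    area_mm2: float  # region cross-section area (for Cavalieri)
    footprint: tuple  # (xmin, xmax, ymin, ymax) of region footprint, um
    somata: Somata

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top


def cut_sections(
    region: VirtualRegion,
    series: SectionSeries,
    rng: np.random.Generator | int | None = None,
) -> list[Section]:
    """Cut the region into a 1-in-period series of thick sections.

    The full knife series partitions z into contiguous slabs of the given
    thickness, starting at a uniform random offset below the region so the
    retained 1-in-period subseries is systematic uniform random.  Each soma
    is assigned to the (single) slab containing its leading edge.  The
    recorded cross-section area is the slab-mean area of the reference solid
    (exact for the Cavalieri identity); the footprint -- where counting
    frames may land -- is the full projection of the region within the slab.
    """
    rng = np.random.default_rng(rng)
    lo, hi = region.spec.box_lo, region.spec.box_hi
    z_extent = hi[2] - lo[2]
    period_um = series.thickness * series.period
    if z_extent <= 0:
        raise EmptySeriesError("region has no z extent")
    if series.start_offset is None:
        offset = rng.uniform(0.0, period_um)
    else:
        offset = series.start_offset
    z0 = lo[2] - offset  # top of retained slab k=0, below the region
    n_slabs = int(np.floor((hi[2] - z0) / period_um)) + 1
    z_lead = region.somata.z_leading
    xy_area_mm2 = (hi[0] - lo[0]) * (hi[1] - lo[1]) / UM2_PER_MM2
    sections = []
    for k in range(n_slabs):
        z_top = z0 + k * period_um
        z_bot = z_top + series.thickness
        if z_bot <= lo[2] or z_top >= hi[2]:
            continue
        overlap = min(z_bot, hi[2]) - max(z_top, lo[2])
        mask = (z_lead >= z_top) & (z_lead < z_bot)
        sec_somata = Somata(
            region.somata.xyz[mask],
            region.somata.diameter[mask],
            region.name,
        )
        sections.append(
            Section(
                index=len(sections),
                z_top=z_top,
                z_bottom=z_bot,
                area_mm2=xy_area_mm2 * overlap / series.thickness,
                footprint=(lo[0], hi[0], lo[1], hi[1]),
                somata=sec_somata,
            )
        )
    if not sections:
        raise EmptySeriesError(
            "section series thicker than the region extent: no sections"
        )
    return sections


def apply_degradation(
    sections: Sequence[Section],
    loss_fraction: float = 0.0,
    fray_depth_um: float = 0.0,
    rng: np.random.Generator | int | None = None,
    min_sections: int = 3,
) -> list[Section]:
    """Tissue-processing damage: whole-section loss and folium-edge fraying.

    A fraction of whole sections is removed at random (processing loss, up
    to ~10% in the source material) and each remaining section's boundary is
    eroded by fray_depth_um, deleting both the eroded rim area and the
    somata whose centres fall inside it, so density remains estimable.
    """
    if not (0.0 <= loss_fraction < 1.0):
        raise ValueError("loss_fraction must be in [0, 1)")
    if fray_depth_um < 0:
        raise ValueError("fray_depth_um must be >= 0")
    rng = np.random.default_rng(rng)
    sections = list(sections)
    n_lose = int(np.floor(loss_fraction * len(sections)))
    if len(sections) - n_lose < min_sections:
        raise InsufficientSectionsError(
            f"loss would leave {len(sections) - n_lose} < {min_sections} sections"
        )
    keep = np.ones(len(sections), dtype=bool)
    if n_lose:
        keep[rng.choice(len(sections), size=n_lose, replace=False)] = False
    out = []
    for sec in (s for s, k in zip(sections, keep) if k):
        x0, x1, y0, y1 = sec.footprint
        if fray_depth_um > 0:
            x0f, x1f = x0 + fray_depth_um, x1 - fray_depth_um
            y0f, y1f = y0 + fray_depth_um, y1 - fray_depth_um
            if x1f <= x0f or y1f <= y0f:
                raise ValueError("fray depth consumes the whole footprint")
            xyz = sec.somata.xyz
            m = (
                (xyz[:, 0] >= x0f)
                & (xyz[:, 0] <= x1f)
                & (xyz[:, 1] >= y0f)
                & (xyz[:, 1] <= y1f)
            )
            shrink = ((x1f - x0f) * (y1f - y0f)) / ((x1 - x0) * (y1 - y0))
            sec = Section(
                index=sec.index,
                z_top=sec.z_top,
                z_bottom=sec.z_bottom,
                area_mm2=sec.area_mm2 * shrink,
                footprint=(x0f, x1f, y0f, y1f),
                somata=Somata(xyz[m], sec.somata.diameter[m], sec.somata.region),
            )
        out.append(sec)
    for i, sec in enumerate(out):
        sec.index = i
    return out


# ---------------------------------------------------------------------------
# counting frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased counting frame: inclusion = top + right edges; exclusion =
    left + bottom edges plus the upward extension of the left edge and the
    downward extension through the bottom-right corner."""

    x0: float
    y0: float
    side: float
    z_window: tuple  # (z_lo, z_hi]; leading edges in this half-open window

    @property
    def x1(self) -> float:
        return self.x0 + self.side

    @property
    def y1(self) -> float:
        return self.y0 + self.side


def place_frames(
    section: Section,
    region: VirtualRegion,
    design: SamplingDesign,
    rng: np.random.Generator | int | None = None,
    grid_offset: tuple | None = None,
) -> list[CountingFrame]:
    """Place one frame per grid cell whose frame footprint intersects the
    region's cross-section on this section.

    The grid has pitch p per axis and a uniform random offset; the frame is
    anchored at the top-left (minimum x, minimum y corner in axis terms) of
    each half-open cell [k*p, (k+1)*p).
    """
    rng = np.random.default_rng(rng)
    pitch = design.pitch_for(region.name)
    side = design.frame_side
    if pitch < side:
        raise OverlappingFramesError("pitch below frame side")
    if grid_offset is None:
        ox, oy = rng.uniform(0.0, pitch, size=2)
    else:
        ox, oy = grid_offset
    x0, x1, y0, y1 = section.footprint
    if x1 <= x0 or y1 <= y0:
        return []
    z_lo = section.z_top + design.guard_depth
    z_hi = z_lo + design.disector_height
    # frames with positive-area overlap with the footprint rectangle:
    # k*pitch + offset in (x0 - side, x1)
    kx0 = int(np.floor((x0 - side - ox) / pitch)) + 1
    kx1 = int(np.ceil((x1 - ox) / pitch)) - 1
    ky0 = int(np.floor((y0 - side - oy) / pitch)) + 1
    ky1 = int(np.ceil((y1 - oy) / pitch)) - 1
    frames = []
    for ky in range(ky0, ky1 + 1):
        fy = oy + ky * pitch
        for kx in range(kx0, kx1 + 1):
            frames.append(
                CountingFrame(ox + kx * pitch, fy, side, (z_lo, z_hi))
            )
    return frames


def _disk_hits_rect(u, v, r, side):
    """Distance from disk centre (u, v) (frame-corner coordinates) to the
    closed frame square, compared with radius r."""
    dx = np.maximum(np.maximum(-u, u - side), 0.0)
    dy = np.maximum(np.maximum(-v, v - side), 0.0)
    return dx * dx + dy * dy <= r * r


def _disk_hits_exclusion(u, v, r, side):
    """Touching the forbidden line (frame-corner coordinates): the left
    edge with its upward extension {x=0, y >= 0}, the bottom edge
    {y=0, 0 <= x <= side}, or the downward extension through the
    bottom-right corner {x=side, y <= 0}."""
    # left edge + upward extension
    dl2 = u * u + np.where(v < 0.0, v * v, 0.0)
    # bottom edge
    dx = np.maximum(np.maximum(-u, u - side), 0.0)
    db2 = dx * dx + v * v
    # downward extension below the bottom-right corner
    dr2 = (u - side) ** 2 + np.where(v > 0.0, v * v, 0.0)
    r2 = r * r
    return (dl2 <= r2) | (db2 <= r2) | (dr2 <= r2)


def count_frame(frame: CountingFrame, somata: Somata) -> int:
    """Apply the optical-disector counting rule in one frame."""
    if len(somata) == 0:
        return 0
    z_lo, z_hi = frame.z_window
    zl = somata.z_leading
    in_z = (zl > z_lo) & (zl <= z_hi)
    u = somata.xyz[:, 0] - frame.x0
    v = somata.xyz[:, 1] - frame.y0
    r = somata.radius
    hit = _disk_hits_rect(u, v, r, frame.side)
    excl = _disk_hits_exclusion(u, v, r, frame.side)
    return int(np.count_nonzero(in_z & hit & ~excl))


def count_section(
    section: Section,
    frames: Sequence[CountingFrame],
    fast: bool = True,
) -> np.ndarray:
    """Per-frame counts for one section.

    The fast path exploits that all frames of a section lie on one grid
    (same side and z window, positions on a lattice) and that somata are
    small relative to the pitch, so each soma can touch at most one frame;
    it is exactly equivalent to looping count_frame over frames (verified in
    tests) but vectorises over somata.
    """
    if not frames:
        return np.zeros(0, dtype=int)
    somata = section.somata
    q = np.zeros(len(frames), dtype=int)
    if len(somata) == 0:
        return q
    side = frames[0].side
    xs = np.array([f.x0 for f in frames])
    ys = np.array([f.y0 for f in frames])
    ux = np.unique(xs)
    uy = np.unique(ys)
    pitch_x = np.min(np.diff(ux)) if len(ux) > 1 else np.inf
    pitch_y = np.min(np.diff(uy)) if len(uy) > 1 else np.inf
    rmax = somata.radius.max()
    same_window = all(f.z_window == frames[0].z_window for f in frames)
    lattice_ok = (
        same_window
        and min(pitch_x, pitch_y) > side + 2.0 * rmax
    )
    if not (fast and lattice_ok):
        for i, f in enumerate(frames):
            q[i] = count_frame(f, somata)
        return q
    z_lo, z_hi = frames[0].z_window
    zl = somata.z_leading
    in_z = (zl > z_lo) & (zl <= z_hi)
    xyz = somata.xyz[in_z]
    r = somata.radius[in_z]
    if not len(xyz):
        return q
    # nearest lattice frame per axis (wrap-free: pitch >> soma diameter)
    ox, oy = ux[0], uy[0]
    px = pitch_x if np.isfinite(pitch_x) else 1.0
    py = pitch_y if np.isfinite(pitch_y) else 1.0
    ix = np.rint((xyz[:, 0] - side / 2.0 - ox) / px) if np.isfinite(pitch_x) else np.zeros(len(xyz))
    iy = np.rint((xyz[:, 1] - side / 2.0 - oy) / py) if np.isfinite(pitch_y) else np.zeros(len(xyz))
    u = xyz[:, 0] - (ox + ix * px)
    v = xyz[:, 1] - (oy + iy * py)
    hit = _disk_hits_rect(u, v, r, side) & ~_disk_hits_exclusion(u, v, r, side)
    if not np.any(hit):
        return q
    # map lattice indices to placed-frame slots
    key = {(round(f.x0, 6), round(f.y0, 6)): i for i, f in enumerate(frames)}
    fx = ox + ix[hit] * px
    fy = oy + iy[hit] * py
    for xf, yf in zip(fx, fy):
        slot = key.get((round(xf, 6), round(yf, 6)))
        if slot is not None:
            q[slot] += 1
    return q


# ---------------------------------------------------------------------------
# region sample
# ---------------------------------------------------------------------------


@dataclass
class RegionSample:
    """Raw disector output for one region of one specimen."""

    region: str
    per_section_counts: np.ndarray  # Q_i ordered by section position
    per_section_frames: np.ndarray
    per_section_areas_mm2: np.ndarray
    section_z: np.ndarray
    design: SamplingDesign
    series: SectionSeries

    @property
    def q_total(self) -> int:
        return int(self.per_section_counts.sum())

    @property
    def n_frames(self) -> int:
        return int(self.per_section_frames.sum())

    @property
    def n_sections(self) -> int:
        return len(self.per_section_counts)

    @property
    def sampled_volume_mm3(self) -> float:
        """Summed disector-box volume: n_frames x frame area x height."""
        return self.n_frames * self.design.box_volume_um3 / UM3_PER_MM3

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                section=np.arange(self.n_sections),
                z_top=self.section_z,
                area_mm2=self.per_section_areas_mm2,
                n_frames=self.per_section_frames,
                q=self.per_section_counts,
                region=self.region,
            )
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_region(
    region: VirtualRegion,
    series: SectionSeries | None = None,
    design: SamplingDesign | None = None,
    rng: np.random.Generator | int | None = None,
    loss_fraction: float = 0.0,
    fray_depth_um: float = 0.0,
) -> RegionSample:
    """Full virtual assay of one region: cut -> (degrade) -> place frames ->
    count, recording per-section counts and the summed disector volume."""
    series = series or SectionSeries()
    design = design or SamplingDesign()
    design.validate_for_series(series)
    rng = np.random.default_rng(rng)
    sections = cut_sections(region, series, rng)
    if loss_fraction > 0 or fray_depth_um > 0:
        sections = apply_degradation(
            sections, loss_fraction, fray_depth_um, rng
        )
    counts, nframes, areas, zs = [], [], [], []
    for sec in sections:
        frames = place_frames(sec, region, design, rng)
        q = count_section(sec, frames)
        counts.append(int(q.sum()))
        nframes.append(len(frames))
        areas.append(sec.area_mm2)
        zs.append(sec.z_top)
    return RegionSample(
        region=region.name,
        per_section_counts=np.asarray(counts, dtype=int),
        per_section_frames=np.asarray(nframes, dtype=int),
        per_section_areas_mm2=np.asarray(areas, dtype=float),
        section_z=np.asarray(zs, dtype=float),
        design=design,
        series=series,
    )
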