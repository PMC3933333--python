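"""Virtual cerebellar tissue phantoms.

A cerebellar region is modelled as a set of *folia* -- tubes swept along
polyline centerlines -- inside a rectangular reference volume (the region
"contour").  Purkinje-cell somata sit in a jittered monolayer on a
cylindrical surface inside each folium, mimicking the PC layer apposed to
the granule cell layer.  All geometry is analytic: a tube of radius R along
a centerline of arc length L has volume pi*R^2*L (Pappus, exact for gentle
planar bends), and the monolayer surface at radius r has area 2*pi*r*L.

Coordinates are in micrometres, right handed, with z the sectioning axis.
Densities are reported per mm^3 (1 mm^3 = 1e9 um^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

UM3_PER_MM3 = 1e9
UM2_PER_MM2 = 1e6


class InvalidGeometryError(ValueError):
    """Degenerate or inconsistent geometric specification."""


class PackingError(RuntimeError):
    """Hard-core point process could not reach the target count."""


class GeometryOverlapError(ValueError):
    """Folium solids overlap beyond the configured tolerance."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoliumSpec:
    """Geometry of a single folium.

    centerline_control_points : (n, 3) array-like, um.  The tube axis.
    folium_radius : um, white-matter core to pial surface.
    pc_layer_offset : um, radial depth of the PC monolayer below the pial
        surface (monolayer radius = folium_radius - pc_layer_offset).
    pc_layer_jitter_sd : um, SD of the radial scatter of somata about the
        monolayer surface.
    soma_diameter_mean, soma_diameter_sd : um, lognormal soma diameters.
    """

    centerline_control_points: tuple
    folium_radius: float
    pc_layer_offset: float
    pc_layer_jitter_sd: float = 15.0
    soma_diameter_mean: float = 25.0
    soma_diameter_sd: float = 4.0

    def __post_init__(self):
        pts = np.asarray(self.centerline_control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise InvalidGeometryError(
                "centerline needs >= 2 control points of dimension 3"
            )
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) <= 0.0):
            raise InvalidGeometryError("coincident consecutive control points")
        if not (self.folium_radius > self.pc_layer_offset > 0):
            raise InvalidGeometryError(
                "need folium_radius > pc_layer_offset > 0"
            )
        if self.soma_diameter_mean <= 0:
            raise InvalidGeometryError("soma_diameter_mean must be > 0")
        if self.pc_layer_jitter_sd < 0 or self.soma_diameter_sd < 0:
            raise InvalidGeometryError("negative scatter parameters")
        object.__setattr__(
            self, "centerline_control_points", tuple(map(tuple, pts))
        )

    @property
    def monolayer_radius(self) -> float:
        return self.folium_radius - self.pc_layer_offset


REGION_NAMES = ("lobulesIV_VI", "crusI", "crusII", "lobuleX")


@dataclass(frozen=True)
class RegionSpec:
    """A cerebellar region: folia plus a rectangular reference volume.

    volume_mode selects the density reference volume: "bounding_box" (the
    anatomical contour within which counting frames are placed -- cortex
    plus interstitial white matter, as sampled in practice) or "folia"
    (sum of folium solids; used for closed-form examples).
    """

    name: str
    folium_specs: tuple
    bounding_box: tuple  # ((xmin,ymin,zmin),(xmax,ymax,zmax)) um
    target_surface_density: float  # PC per mm^2 of monolayer surface
    rng_seed: int = 0
    volume_mode: Literal["bounding_box", "folia"] = "bounding_box"
    hard_core: bool = True
    min_separation: float | None = None  # default: soma_diameter_mean

    def __post_init__(self):
        lo, hi = (np.asarray(v, float) for v in self.bounding_box)
        if lo.shape != (3,) or hi.shape != (3,) or np.any(hi <= lo):
            raise InvalidGeometryError("bounding box must have positive extent")
        if self.target_surface_density < 0:
            raise InvalidGeometryError("surface density must be >= 0")
        object.__setattr__(self, "folium_specs", tuple(self.folium_specs))
        object.__setattr__(
            self, "bounding_box", (tuple(lo), tuple(hi))
        )

    @property
    def box_lo(self) -> np.ndarray:
        return np.asarray(self.bounding_box[0])

    @property
    def box_hi(self) -> np.ndarray:
        return np.asarray(self.bounding_box[1])

    @property
    def box_volume_um3(self) -> float:
        return float(np.prod(self.box_hi - self.box_lo))


# ---------------------------------------------------------------------------
# folium solid
# ---------------------------------------------------------------------------


class Folium:
    """A tube swept along a polyline centerline, with its PC monolayer."""

    def __init__(self, spec: FoliumSpec):
        self.spec = spec
        pts = np.asarray(spec.centerline_control_points, dtype=float)
        self.points = pts
        seg = np.diff(pts, axis=0)
        self.seg_len = np.linalg.norm(seg, axis=1)
        self.tangent = seg / self.seg_len[:, None]
        self.length = float(self.seg_len.sum())
        self.cum_len = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        # per-segment orthonormal frame (normal, binormal)
        zhat = np.array([0.0, 0.0, 1.0])
        n = np.cross(self.tangent, zhat)
        nn = np.linalg.norm(n, axis=1)
        vertical = nn < 1e-9
        if np.any(vertical):
            n[vertical] = np.array([1.0, 0.0, 0.0])
            nn[vertical] = 1.0
        self.normal = n / nn[:, None]
        self.binormal = np.cross(self.tangent, self.normal)

    @property
    def volume_um3(self) -> float:
        """Pappus volume pi R^2 L of the flat-ended swept tube (exact for
        a straight tube; for gentle bends the outside-wedge gaps and
        inside-wedge overlaps of consecutive segment cylinders cancel to
        second order in bend angle)."""
        return float(np.pi * self.spec.folium_radius**2 * self.length)

    @property
    def monolayer_area_um2(self) -> float:
        return float(2.0 * np.pi * self.spec.monolayer_radius * self.length)

    # -- geometry queries ---------------------------------------------------

    def distance_to_centerline(self, points: np.ndarray) -> np.ndarray:
        """Min distance from (n,3) points to the polyline centerline."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        best = np.full(len(pts), np.inf)
        for i in range(len(self.seg_len)):
            a = self.points[i]
            t = self.tangent[i]
            rel = pts - a
            proj = np.clip(rel @ t, 0.0, self.seg_len[i])
            d = np.linalg.norm(rel - proj[:, None] * t, axis=1)
            np.minimum(best, d, out=best)
        return best

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-in-solid test consistent with the Pappus volume: within
        R of the centerline polyline, trimmed flat at the two terminal
        planes (no end caps).  At interior bends the corner fill and the
        inside-wedge overlap cancel to second order in the bend angle."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = self.spec.folium_radius
        inside = self.distance_to_centerline(pts) <= r
        start_ax = (pts - self.points[0]) @ self.tangent[0]
        end_ax = (pts - self.points[-1]) @ self.tangent[-1]
        return inside & (start_ax >= 0.0) & (end_ax <= 0.0)

    # -- surface sampling ---------------------------------------------------

    def sample_monolayer(self, n: int, rng: np.random.Generator):
        """n points ~ uniform on the monolayer surface.

        Returns (base, radial) where base is the centerline foot point and
        radial the unit radial direction; a point at radius r is
        base + r * radial.  Segments are treated as independent cylinders
        (joint wedges are negligible for the gentle bends used here).
        """
        seg_idx = rng.choice(
            len(self.seg_len), size=n, p=self.seg_len / self.length
        )
        s = rng.uniform(0.0, self.seg_len[seg_idx])
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        base = self.points[seg_idx] + s[:, None] * self.tangent[seg_idx]
        radial = (
            np.cos(theta)[:, None] * self.normal[seg_idx]
            + np.sin(theta)[:, None] * self.binormal[seg_idx]
        )
        return base, radial


def generate_folium(spec: FoliumSpec, rng_seed: int = 0) -> Folium:
    """Build the folium solid.  Deterministic: geometry depends only on the
    spec; the seed is accepted for interface symmetry with the stochastic
    operations."""
    return Folium(spec)


# ---------------------------------------------------------------------------
# somata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaPoint:
    x: float
    y: float
    z: float
    diameter: float
    region: str = ""


class Somata:
    """Array-backed collection of PC somata."""

    def __init__(self, xyz: np.ndarray, diameter: np.ndarray, region: str = ""):
        self.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        self.diameter = np.asarray(diameter, dtype=float).reshape(-1)
        if len(self.diameter) != len(self.xyz):
            raise ValueError("xyz and diameter length mismatch")
        if np.any(self.diameter <= 0):
            raise ValueError("soma diameters must be > 0")
        self.region = region

    def __len__(self) -> int:
        return len(self.diameter)

    def __iter__(self) -> Iterator[SomaPoint]:
        for (x, y, z), d in zip(self.xyz, self.diameter):
            yield SomaPoint(x, y, z, d, self.region)

    @property
    def radius(self) -> np.ndarray:
        return self.diameter / 2.0

    @property
    def z_leading(self) -> np.ndarray:
        """Leading edge: the minimum-z point of each soma sphere (the first
        to come into focus when focusing downward)."""
        return self.xyz[:, 2] - self.radius

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                x=self.xyz[:, 0], y=self.xyz[:, 1], z=self.xyz[:, 2],
                diameter=self.diameter, region=self.region,
            )
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def concatenate(cls, parts: Sequence["Somata"], region: str = "") -> "Somata":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls(np.empty((0, 3)), np.empty(0), region)
        return cls(
            np.vstack([p.xyz for p in parts]),
            np.concatenate([p.diameter for p in parts]),
            region,
        )


def _sample_diameters(spec: FoliumSpec, n: int, rng: np.random.Generator):
    """Lognormal soma diameters with the spec's mean/sd, clipped to a
    physiological range around the mean."""
    m, s = spec.soma_diameter_mean, spec.soma_diameter_sd
    if s == 0:
        return np.full(n, m)
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    d = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.clip(d, 0.4 * m, 1.8 * m)


def place_somata(
    folium: Folium,
    target_surface_density: float,
    jitter_sd: float | None = None,
    rng: np.random.Generator | int | None = None,
    hard_core: bool = True,
    min_separation: float | None = None,
    max_rounds: int = 60,
    region: str = "",
) -> Somata:
    """Poisson (optionally hard-core) point process on the monolayer.

    target_surface_density is in PC per mm^2 of monolayer surface; the
    expected count is density * area.  Somata are displaced radially by
    Normal(0, jitter_sd).  With hard_core=True, placement is by random
    sequential adsorption: candidates conflicting (3D distance below
    min_separation, default the mean soma diameter) with already accepted
    somata are redrawn, in bounded rounds.
    """
    if target_surface_density < 0:
        raise ValueError("target_surface_density must be >= 0")
    rng = np.random.default_rng(rng)
    spec = folium.spec
    if jitter_sd is None:
        jitter_sd = spec.pc_layer_jitter_sd
    if min_separation is None:
        min_separation = spec.soma_diameter_mean
    area_mm2 = folium.monolayer_area_um2 / UM2_PER_MM2
    n_target = rng.poisson(target_surface_density * area_mm2)
    if n_target == 0:
        return Somata(np.empty((0, 3)), np.empty(0), region)

    r_mono = spec.monolayer_radius

    def draw(n):
        base, radial = folium.sample_monolayer(n, rng)
        r = r_mono + rng.normal(0.0, jitter_sd, size=n)
        return base + r[:, None] * radial

    if not hard_core or min_separation <= 0:
        pts = draw(n_target)
    else:
        accepted = np.empty((0, 3))
        for _ in range(max_rounds):
            deficit = n_target - len(accepted)
            if deficit <= 0:
                break
            cand = draw(int(np.ceil(deficit * 1.3)) + 8)
            # candidate-vs-candidate conflicts: keep the earlier of each pair
            pairs = cKDTree(cand).query_pairs(min_separation, output_type="ndarray")
            drop = np.zeros(len(cand), dtype=bool)
            if len(pairs):
                keep_order = np.sort(pairs, axis=1)
                drop[keep_order[:, 1]] = True
            cand = cand[~drop]
            # candidate-vs-accepted conflicts
            if len(accepted):
                d, _ = cKDTree(accepted).query(
                    cand, k=1, distance_upper_bound=min_separation
                )
                cand = cand[np.isinf(d)]
            accepted = np.vstack([accepted, cand[: n_target - len(accepted)]])
        else:
            raise PackingError(
                f"could not place {n_target} somata at separation "
                f"{min_separation} um in {max_rounds} rounds"
            )
        pts = accepted
    diam = _sample_diameters(spec, len(pts), rng)
    return Somata(pts, diam, region)


# ---------------------------------------------------------------------------
# region assembly
# ---------------------------------------------------------------------------


@dataclass
class VirtualRegion:
    """Ground-truth phantom: somata plus analytic reference volume."""

    spec: RegionSpec
    folia: list
    somata: Somata
    volume_mm3: float
    monolayer_area_mm2: float

    @property
    def true_density(self) -> float:
        """PC per mm^3 of the reference volume."""
        return len(self.somata) / self.volume_mm3

    @property
    def name(self) -> str:
        return self.spec.name


def _check_region_geometry(spec: RegionSpec, folia: list, overlap_tol: float):
    lo, hi = spec.box_lo, spec.box_hi
    samples, radii, ids = [], [], []
    for k, f in enumerate(folia):
        fs = f.spec
        margin = (
            fs.folium_radius
            + 5.0 * fs.pc_layer_jitter_sd
            + fs.soma_diameter_mean
        )
        # resample centerline every ~200 um for proximity checks
        n = max(int(f.length / 200.0), 2)
        s = np.linspace(0.0, f.length, n)
        seg = np.clip(np.searchsorted(f.cum_len, s, side="right") - 1, 0,
                      len(f.seg_len) - 1)
        pts = f.points[seg] + (s - f.cum_len[seg])[:, None] * f.tangent[seg]
        if np.any(pts - margin < lo) or np.any(pts + margin > hi):
            raise InvalidGeometryError(
                f"folium {k} (with soma margin) exceeds the bounding box"
            )
        samples.append(pts)
        radii.append(fs.folium_radius)
        ids.append(np.full(n, k))
    pts = np.vstack(samples)
    ids = np.concatenate(ids)
    rmax = max(radii)
    pairs = cKDTree(pts).query_pairs(2 * rmax - overlap_tol,
                                     output_type="ndarray")
    if len(pairs):
        different = ids[pairs[:, 0]] != ids[pairs[:, 1]]
        if np.any(different):
            bad = pairs[different][0]
            d = np.linalg.norm(pts[bad[0]] - pts[bad[1]])
            ra = radii[ids[bad[0]]] + radii[ids[bad[1]]]
            if d < ra - overlap_tol:
                raise GeometryOverlapError(
                    f"folia {ids[bad[0]]} and {ids[bad[1]]} overlap "
                    f"(centerline distance {d:.0f} um < {ra:.0f} um)"
                )


def assemble_region(
    spec: RegionSpec, overlap_tol: float = 1.0, check_geometry: bool = True
) -> VirtualRegion:
    """Instantiate all folia, place and pool somata, record analytic volume.

    Deterministic for a fixed spec (rng_seed included).
    """
    folia = [generate_folium(fs) for fs in spec.folium_specs]
    if check_geometry and folia:
        _check_region_geometry(spec, folia, overlap_tol)
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(max(len(folia), 1))
    parts = []
    for f, ss in zip(folia, seeds):
        parts.append(
            place_somata(
                f,
                spec.target_surface_density,
                rng=np.random.default_rng(ss),
                hard_core=spec.hard_core,
                min_separation=spec.min_separation,
                region=spec.name,
            )
        )
    somata = Somata.concatenate(parts, region=spec.name)
    if spec.volume_mode == "folia":
        volume_um3 = sum(f.volume_um3 for f in folia)
    else:
        volume_um3 = spec.box_volume_um3
    area_mm2 = sum(f.monolayer_area_um2 for f in folia) / UM2_PER_MM2
    return VirtualRegion(
        spec=spec,
        folia=folia,
        somata=somata,
        volume_mm3=volume_um3 / UM3_PER_MM3,
        monolayer_area_mm2=area_mm2,
    )
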