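"""Calibrated default phantoms and sampling designs.

The four default virtual regions are calibrated against the published assay
design: 19,600 um^2 frames, 5 um guard, 75 um disector depth, 1-in-6 series
of 200 um sections, grid pitches of 2500 / 2200 / 400 / 1400 um, mean frame
totals of 1106 / 818 / 1392 / 1690, and roughly 450 somata counted per
region per pass.  Those figures pin down each region's sampled volume
(n_frames x pitch^2 x 1.2 mm) and true density (~450 / (n_frames x
1.47e-3 mm^3)); the phantom box and soma count are solved from them.

Inside each box, folia are laid out as layered serpentine tubes: parallel
rows in the section plane, layers along z, with a small per-folium lateral
wiggle and a larger z undulation whose phase is shared within a region
(shared phase keeps layer clearances constant while smearing the monolayer
across the sectioning axis).  Rows run diagonally to the counting grid and
are staggered in z by a golden-ratio fraction of the layer pitch, so that
neither the frame lattice nor the 1.2 mm section period can alias with the
folium lattice.  Somata sit on each folium's monolayer at the surface
density implied by the region's target count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .sampling import SamplingDesign, SectionSeries, DEFAULT_GRID_PITCH
from .virtual_tissue import FoliumSpec, RegionSpec, UM3_PER_MM3


@dataclass(frozen=True)
class RegionCalibration:
    """Published design targets plus the geometric layout for one region."""

    name: str
    grid_pitch: float  # um
    n_frames_target: int  # mean counting frames per specimen
    n_sections: int  # sections the region appears on
    q_target: float = 450.0  # somata counted per pass
    folium_radius: float = 450.0  # um
    pc_layer_offset: float = 150.0  # um
    y_pitch: float = 1200.0  # folium row spacing, um
    # layer spacing leaves 2R plus clearance along the *perpendicular*
    # between slanted neighbours: z_pitch / sqrt(1 + max slope^2) > 2R
    z_pitch: float = 1100.0
    y_amp: float = 80.0  # per-folium lateral wiggle amplitude, um
    y_wavelength: float = 5000.0
    z_amp: float = 400.0  # shared z undulation amplitude, um
    z_wavelength: float = 8000.0
    pc_layer_jitter_sd: float = 60.0  # um, radial scatter of the monolayer
    # folia run diagonally to the counting grid so monolayer bands sweep
    # through all grid phases instead of aliasing with the frame lattice
    angle_deg: float = 27.0


REGION_CALIBRATIONS = {
    "crusI": RegionCalibration("crusI", 2500.0, 1106, 13),
    "crusII": RegionCalibration("crusII", 2200.0, 818, 11),
    "lobulesIV_VI": RegionCalibration("lobulesIV_VI", 1400.0, 1690, 12),
    # flocculonodular folia are small and undulate on a shorter wavelength
    "lobuleX": RegionCalibration(
        "lobuleX", 400.0, 1392, 8,
        folium_radius=300.0, pc_layer_offset=120.0,
        y_pitch=900.0, z_pitch=800.0,
        z_wavelength=5000.0, pc_layer_jitter_sd=40.0,
    ),
}


def default_section_series(start_offset: float | None = None) -> SectionSeries:
    """200 um sections, every 6th retained (1.2 mm increments)."""
    return SectionSeries(thickness=200.0, period=6, start_offset=start_offset)


def default_sampling_design(rng_seed: int = 0) -> SamplingDesign:
    return SamplingDesign(rng_seed=rng_seed)


def validation_design(region_names=None, pitch: float = 500.0,
                      frame_area: float = 2500.0) -> SamplingDesign:
    """A fine design (50 um frames by default) for estimator-validation
    phantoms: small frames relative to the region keep the frame-placement
    edge effect well below the unbiasedness tolerance."""
    names = region_names or list(DEFAULT_GRID_PITCH) + ["phantom"]
    return SamplingDesign(
        frame_area=frame_area,
        grid_pitch={n: pitch for n in names},
    )


def target_density(cal: RegionCalibration,
                   design: SamplingDesign | None = None) -> float:
    """True density (PC/mm^3) implied by the counted-cell and frame-count
    targets: q_target / (n_frames x box volume)."""
    design = design or default_sampling_design()
    return cal.q_target / (cal.n_frames_target * design.box_volume_um3
                           / UM3_PER_MM3)


def _frame_margin(cal: RegionCalibration) -> float:
    # folium radius + 5 sd radial jitter + one soma diameter
    return cal.folium_radius + 5.0 * cal.pc_layer_jitter_sd + 25.0


def _layout_folia(cal: RegionCalibration, w: float, z_extent: float,
                  rng: np.random.Generator):
    """Serpentine diagonal folium layout inside a w x w x z_extent box.

    Returns (folium_specs, total_centerline_length_um).
    """
    margin = _frame_margin(cal)
    m_xy = margin + cal.y_amp + 10.0
    m_z = margin + cal.z_amp + 10.0
    # one extra pitch of headroom for the per-row z stagger (below)
    n_layers = int((z_extent - 2.0 * m_z - cal.z_pitch) // cal.z_pitch) + 1
    if n_layers < 1 or w <= 2.0 * m_xy:
        raise ValueError(f"box too small for folium layout in {cal.name}")
    z_start = (z_extent - n_layers * cal.z_pitch) / 2.0

    phase_z = rng.uniform(0.0, 2.0 * math.pi)  # shared by all folia
    specs = []
    total_len = 0.0

    # diagonal row layout: folia run along u = (cos a, sin a), rows are
    # spaced along the in-plane perpendicular v = (-sin a, cos a)
    a = math.radians(cal.angle_deg)
    ux, uy = math.cos(a), math.sin(a)
    vx, vy = -math.sin(a), math.cos(a)
    cx = cy = w / 2.0
    half_span = (w * (abs(ux) + abs(uy))) / 2.0
    n_rows = int(2.0 * half_span // cal.y_pitch) + 1
    row_cs = (np.arange(n_rows) - (n_rows - 1) / 2.0) * cal.y_pitch

    def _clip_row(c):
        """t-range of centre + t*u + c*v inside the margin-shrunk box."""
        t0, t1 = -np.inf, np.inf
        for comp_u, comp_v, centre in ((ux, vx, cx), (uy, vy, cy)):
            lo = m_xy - centre - c * comp_v
            hi = (w - m_xy) - centre - c * comp_v
            if abs(comp_u) < 1e-12:
                if lo > 0 or hi < 0:
                    return None
                continue
            ta, tb = lo / comp_u, hi / comp_u
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
        return (t0, t1) if t1 - t0 >= 2000.0 else None

    for il in range(n_layers):
        for ir, c in enumerate(row_cs):
            t_range = _clip_row(c)
            if t_range is None:
                continue
            # golden-ratio z stagger per row: breaks any commensurability
            # between the layer lattice and the 1.2 mm section period
            # without changing within-row or within-layer clearances
            frac = (ir * 0.3819660113) % 1.0
            z_l = z_start + (il + frac) * cal.z_pitch
            phase_y = rng.uniform(0.0, 2.0 * math.pi)
            ts = np.arange(t_range[0], t_range[1] + 1.0, 250.0)
            wig = cal.y_amp * np.sin(
                2.0 * math.pi * ts / cal.y_wavelength + phase_y
            )
            xs_r = cx + ts * ux + (c + wig) * vx
            ys_r = cy + ts * uy + (c + wig) * vy
            zs = z_l + cal.z_amp * np.sin(
                2.0 * math.pi * ts / cal.z_wavelength + phase_z
            )
            pts = np.column_stack([xs_r, ys_r, zs])
            total_len += float(
                np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
            )
            specs.append(
                FoliumSpec(
                    centerline_control_points=tuple(map(tuple, pts)),
                    folium_radius=cal.folium_radius,
                    pc_layer_offset=cal.pc_layer_offset,
                    pc_layer_jitter_sd=cal.pc_layer_jitter_sd,
                )
            )
    return specs, total_len


def _spec_from_layout(name, cal, w, z_extent, density_per_mm3, rng_seed):
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xF0]))
    folium_specs, total_len = _layout_folia(cal, w, z_extent, rng)
    r_mono = cal.folium_radius - cal.pc_layer_offset
    box_volume_mm3 = w * w * z_extent / UM3_PER_MM3
    n_target = density_per_mm3 * box_volume_mm3
    area_mm2 = 2.0 * math.pi * r_mono * total_len / 1e6
    surface_density = n_target / area_mm2
    if not (30.0 <= surface_density <= 700.0):
        raise ValueError(
            f"implausible monolayer surface density {surface_density:.0f} "
            f"PC/mm^2 for {name}"
        )
    return RegionSpec(
        name=name,
        folium_specs=tuple(folium_specs),
        bounding_box=((0.0, 0.0, 0.0), (w, w, z_extent)),
        target_surface_density=surface_density,
        rng_seed=rng_seed,
    )


def default_region_spec(
    name: str,
    rng_seed: int = 0,
    design: SamplingDesign | None = None,
    series: SectionSeries | None = None,
    density_scale: float = 1.0,
) -> RegionSpec:
    """Build the calibrated RegionSpec for one of the four regions.

    density_scale multiplies the calibrated true density (used when a
    phantom must carry a specific subject's density).
    """
    cal = REGION_CALIBRATIONS[name]
    design = design or default_sampling_design()
    series = series or default_section_series()
    side = design.frame_side
    period_um = series.thickness * series.period
    # lateral size: E[n_frames] = n_sections * ((W+side)/pitch)^2
    w = cal.grid_pitch * math.sqrt(cal.n_frames_target / cal.n_sections) - side
    # z extent: E[#intersecting retained sections] = (Z + thickness)/period
    z_extent = cal.n_sections * period_um - series.thickness
    density = target_density(cal, design) * density_scale
    return _spec_from_layout(name, cal, w, z_extent, density, rng_seed)


def box_region_spec(
    name: str,
    width_um: float,
    z_extent_um: float,
    density_per_mm3: float,
    rng_seed: int = 0,
    cal: RegionCalibration | None = None,
) -> RegionSpec:
    """A free-size box phantom with the standard folium architecture, at an
    arbitrary true density (validation phantoms, per-case phantoms)."""
    cal = cal or replace(REGION_CALIBRATIONS["crusI"], name=name)
    return _spec_from_layout(
        name, cal, width_um, z_extent_um, density_per_mm3, rng_seed
    )


def all_default_region_specs(rng_seed: int = 0) -> dict:
    return {
        name: default_region_spec(name, rng_seed=rng_seed + i)
        for i, name in enumerate(REGION_CALIBRATIONS)
    }
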