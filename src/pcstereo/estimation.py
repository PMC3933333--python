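"""Density, precision (Gundersen CE), and Cavalieri volume estimation.

Numerical density is the classic disector ratio: total somata counted in a
region divided by the summed volume of the counting boxes placed in it.
Precision of the systematic-uniform-random section series is summarised by
the Gundersen coefficient of error for smoothness class m = 1, combining a
Poisson "noise" term with a smoothed serial-covariance term over the
ordered per-section counts:

    noise = sum Q_i,  A = sum Q_i^2,  B = sum Q_i Q_{i+1},  C = sum Q_i Q_{i+2}
    Var_SURS = (3 (A - noise) - 4 B + C) / 240
    CE = sqrt(noise + Var_SURS) / sum Q_i
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sampling import RegionSample



class UndefinedDensityError(ValueError):
    """No counting boxes: the density ratio is undefined."""


class InsufficientSectionsError(ValueError):
    """The CE estimator needs at least three ordered sections."""


class ZeroVolumeError(ValueError):
    """All section areas are zero."""


@dataclass(frozen=True)
class DensityEstimate:
    """Per-region numerical density with its precision."""

    region: str
    q_total: int
    v_sampled_mm3: float
    density: float  # PC / mm^3
    ce: float  # nan when undefined (zero count)
    n_frames: int
    n_sections: int

    @property
    def log_density(self) -> float:
        return math.log(self.density) if self.density > 0 else math.nan


@dataclass(frozen=True)
class RegionalVolume:
    region: str
    volume_mm3: float


def gundersen_ce(per_section_counts: Sequence[int]) -> float:
    """Gundersen (m = 1) coefficient of error of a SURS count series.

    Counts must be in anatomical section order (the serial covariance terms
    are meaningless for sorted or shuffled counts).  Returns nan for an
    all-zero series.
    """
    q = np.asarray(per_section_counts, dtype=float)
    if q.ndim != 1 or len(q) < 3:
        raise InsufficientSectionsError(
            "Gundersen CE needs >= 3 ordered sections"
        )
    total = q.sum()
    if total == 0:
        return math.nan
    noise = total
    a = float(np.sum(q * q))
    b = float(np.sum(q[:-1] * q[1:]))
    c = float(np.sum(q[:-2] * q[2:]))
    var_surs = (3.0 * (a - noise) - 4.0 * b + c) / 240.0
    return math.sqrt(max(noise + var_surs, 0.0)) / total


def estimate_density(sample: RegionSample) -> DensityEstimate:
    """Disector density: sum of counts over summed counting-box volume."""
    if sample.n_frames == 0:
        raise UndefinedDensityError(
            f"no counting frames placed in {sample.region}"
        )
    v = sample.sampled_volume_mm3
    q = sample.q_total
    if sample.n_sections >= 3:
        ce = gundersen_ce(sample.per_section_counts)
    else:
        ce = math.nan
    return DensityEstimate(
        region=sample.region,
        q_total=q,
        v_sampled_mm3=v,
        density=q / v,
        ce=ce,
        n_frames=sample.n_frames,
        n_sections=sample.n_sections,
    )


def cavalieri_volume(
    section_areas_mm2: Sequence[float],
    thickness_mm: float,
    period: int,
    region: str = "",
) -> RegionalVolume:
    """Cavalieri estimator: volume = sum(area_i) * thickness * period."""
    areas = np.asarray(section_areas_mm2, dtype=float)
    if len(areas) == 0 or np.all(areas == 0):
        raise ZeroVolumeError("no section with positive area")
    if thickness_mm <= 0 or period < 1:
        raise ValueError("invalid thickness or period")
    return RegionalVolume(
        region=region, volume_mm3=float(areas.sum() * thickness_mm * period)
    )


def regional_volume_from_sample(sample: RegionSample) -> RegionalVolume:
    """Cavalieri volume from the planimetric areas recorded during
    density estimation (the same sections, as done in practice)."""
    return cavalieri_volume(
        sample.per_section_areas_mm2,
        sample.series.thickness / 1000.0,
        sample.series.period,
        region=sample.region,
    )


def overall_weighted_density(
    estimates: Iterable[DensityEstimate | float | None],
    volumes: Iterable[RegionalVolume | float],
) -> float:
    """Regional-volume-weighted composite density.

    sum(V_r * D_r) / sum(V_r) over regions with a usable estimate; regions
    with a missing estimate (None or nan) are excluded from both sums, so
    larger regions weigh more and incomplete regions drop out cleanly.
    """
    num = 0.0
    den = 0.0
    used = 0
    for est, vol in zip(estimates, volumes):
        if est is None:
            continue
        d = est.density if isinstance(est, DensityEstimate) else float(est)
        v = vol.volume_mm3 if isinstance(vol, RegionalVolume) else float(vol)
        if math.isnan(d) or math.isnan(v):
            continue
        if v < 0:
            raise ValueError("negative regional volume")
        num += v * d
        den += v
        used += 1
    if used == 0 or den == 0:
        raise ValueError("no usable region estimates for the composite")
    return num / den
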