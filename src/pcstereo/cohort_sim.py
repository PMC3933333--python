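"""Synthetic postmortem cohorts with planted regional density structure.

Generates 16-case (or larger) cohorts whose demographics follow the
published clinical table (8 autism / 8 control, 5 males / 3 females each;
38% mental retardation and 38% epilepsy among the autism cases) and whose
per-region Purkinje-cell densities encode the reported effect structure on
the log scale:

    log D[case, r] = log mu_r + 1[autism] log a_r + 1[male, r != lobule X]
                     log g + beta_age * age
                     + 1[r = lobule X] (gamma log(BW / BW_ref)
                                        + 1[autism male] log m_X)
                     + u_case + e[case, r]

with a case-level intercept u, correlated regional residuals e (crus I and
crus II strongly coupled), and multiplicative measurement noise whose CV
equals the assay's mean Gundersen CE.

Effects are *specified* as the raw cohort contrasts they should produce
(e.g. crus I autism/control density ratio 0.802 = a 19.8% deficit); the
model coefficients (a_r, g, gamma, m_X) are derived from those targets by
inverting the analytic expectation of each contrast under the cohort's
demographic cell distributions, so a planted 19.8% is recovered as a raw
19.8% despite the age and brain-weight confounds built into the
demographics.  The lobule X male deficits run partly through the
brain-weight path (gamma < 0: heavier brains, lower density) and partly
through a direct autism-male term; a "full" mediation switch forces the
whole effect through brain weight.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .estimation import overall_weighted_density
from .virtual_tissue import UM3_PER_MM3

REGIONS = ("lobulesIV_VI", "crusI", "crusII", "lobuleX")

_TABLE1_SHA256 = (
    "901cafcc79edeae0a26b229850860d61941c0bdc0a9f1d60fcd8ffe255c5bfdf"
)


class FixtureCorruptionError(RuntimeError):
    """Packaged clinical table does not match its recorded checksum."""


# ---------------------------------------------------------------------------
# case profiles
# ---------------------------------------------------------------------------


@dataclass
class CaseProfile:
    case_id: str
    diagnosis: str  # autism | control
    sex: str  # M | F
    age: float  # years
    brain_weight: float | None  # g, may be missing
    pmi: float  # h
    mr: bool = False
    epilepsy: bool = False
    regression: bool = False
    adir_q50: int | None = None  # ordinal 0-3, autism cases only
    adir_domains: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.diagnosis not in ("autism", "control"):
            raise ValueError(f"bad diagnosis {self.diagnosis!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"bad sex {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if self.brain_weight is not None and self.brain_weight <= 0:
            raise ValueError("brain weight must be > 0 when present")
        if self.adir_q50 is not None and self.adir_q50 not in (0, 1, 2, 3):
            raise ValueError("adir_q50 must be in {0,1,2,3}")


@dataclass
class CaseTruth:
    case_id: str
    true_density: dict  # region -> PC/mm^3
    measured_density: dict = field(default_factory=dict)
    overall_measured: float | None = None


def load_table1_fixture() -> list[CaseProfile]:
    """The 16 clinical cases exactly as tabulated (one control male has no
    brain weight on record)."""
    ref = resources.files("pcstereo").joinpath("data/table1_clinical.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureCorruptionError(
            f"table1_clinical.csv checksum mismatch: {digest}"
        )
    df = pd.read_csv(ref)
    profiles = []
    for row in df.itertuples(index=False):
        bw = None if pd.isna(row.brain_weight_g) else float(row.brain_weight_g)
        profiles.append(
            CaseProfile(
                case_id=row.case_id,
                diagnosis=row.diagnosis,
                sex=row.sex,
                age=float(row.age_years),
                brain_weight=bw,
                pmi=float(row.pmi_h),
                mr=str(row.mr) != "no",
                epilepsy=str(row.epilepsy) == "yes",
                regression=str(row.regression) == "yes",
            )
        )
    return profiles


def table1_dataframe() -> pd.DataFrame:
    """Fixture as a DataFrame (brain weight NaN where missing)."""
    rows = []
    for p in load_table1_fixture():
        rows.append(
            dict(
                case_id=p.case_id, diagnosis=p.diagnosis, sex=p.sex,
                age=p.age, brain_weight=p.brain_weight, pmi=p.pmi,
                mr=p.mr, epilepsy=p.epilepsy, regression=p.regression,
            )
        )
    return pd.DataFrame(rows)


def _cell_moments() -> dict:
    """Diagnosis x sex moments (mean, sd) of age and brain weight fitted to
    the clinical table; the missing brain weight is simply omitted."""
    df = table1_dataframe()
    out = {}
    for (dx, sex), grp in df.groupby(["diagnosis", "sex"]):
        bw = grp.brain_weight.dropna()
        out[(dx, sex)] = dict(
            age_mean=float(grp.age.mean()),
            age_sd=float(grp.age.std(ddof=1)),
            bw_mean=float(bw.mean()),
            bw_sd=float(bw.std(ddof=1)),
        )
    return out


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

#: nominal Cavalieri regional volumes, mm^3, used as composite weights in
#: surrogate mode.  crus I / crus II / lobule X are pinned by the assay
#: design (sampled area x 1.2 mm); the lobules IV-VI volume is calibrated so
#: the volume-weighted composite reproduces the reported 11% overall autism
#: deficit together with the regional deficits (see docs/methods.md).
DEFAULT_REGIONAL_VOLUMES = {
    "lobulesIV_VI": 13900.0,
    "crusI": 2830.0,
    "crusII": 2100.0,
    "lobuleX": 190.0,
}

#: baseline densities, PC/mm^3 (phantom calibration values)
DEFAULT_BASELINE_DENSITY = {
    "lobulesIV_VI": 181.2,
    "crusI": 276.8,
    "crusII": 374.3,
    "lobuleX": 219.9,
}

#: residual correlation across regions (order = REGIONS); the crus I-crus II
#: entry is calibrated so the measured cross-case correlation of their log
#: densities averages the reported 0.832 in 16-case cohorts
DEFAULT_REGION_CORR = np.array(
    [
        [1.00, 0.30, 0.30, 0.30],
        [0.30, 1.00, 0.52, 0.30],
        [0.30, 0.52, 1.00, 0.30],
        [0.30, 0.30, 0.30, 1.00],
    ]
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure plus raw-contrast effect targets.

    Multiplicative effects are raw cohort density ratios (affected group
    over reference group) matching the reported percent differences:
    0.802 = 19.8% lower, etc.
    """

    n_per_cell: tuple = (("autism", "M", 5), ("autism", "F", 3),
                         ("control", "M", 5), ("control", "F", 3))
    diagnosis_effect: tuple = (
        ("lobulesIV_VI", 0.95), ("crusI", 0.802), ("crusII", 0.783)
    )
    male_effect: float = 0.79  # raw M/F ratio outside lobule X
    lobx_autism_mf: float = 0.685  # autism M / autism F in lobule X
    lobx_autism_vs_control_m: float = 0.74  # autism M / control M, lobule X
    overall_autism_ratio: float = 0.89  # volume-weighted composite
    lobx_mediation: str = "partial"  # "partial" | "full"
    age_log_slope: float = -0.002  # per year, common to both groups
    case_sd: float = 0.10  # case-level log intercept SD
    region_sd: float = 0.12  # regional residual log SD
    region_corr: tuple = tuple(map(tuple, DEFAULT_REGION_CORR))
    measurement_cv: float = 0.053  # surrogate measurement CV (mean CE)
    adir_latent_sd: float = 0.75  # noise on the ADI-R eye-contact latent
    mr_rate: float = 0.38
    epilepsy_rate: float = 0.38
    regression_rate: float = 0.375
    baseline_density: tuple = tuple(DEFAULT_BASELINE_DENSITY.items())
    regional_volumes: tuple = tuple(DEFAULT_REGIONAL_VOLUMES.items())
    bw_ref: float = 1450.0  # g
    rng_seed: int = 0

    def __post_init__(self):
        corr = np.asarray(self.region_corr)
        if np.any(np.linalg.eigvalsh(corr) < -1e-9):
            raise ValueError("region correlation matrix is not PSD")
        for _, eff in self.diagnosis_effect:
            if eff <= 0:
                raise ValueError("multiplicative effects must be > 0")
        if self.male_effect <= 0 or self.lobx_autism_mf <= 0:
            raise ValueError("multiplicative effects must be > 0")
        if self.lobx_mediation not in ("partial", "full"):
            raise ValueError("lobx_mediation must be 'partial' or 'full'")

    @property
    def diagnosis_effect_map(self) -> dict:
        return dict(self.diagnosis_effect)

    @property
    def baseline_map(self) -> dict:
        return dict(self.baseline_density)

    @property
    def volume_map(self) -> dict:
        return dict(self.regional_volumes)


# ---------------------------------------------------------------------------
# model coefficients: invert raw-contrast targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelCoefficients:
    a: dict  # region -> autism coefficient (non-lobX)
    g: float  # male coefficient (non-lobX)
    gamma: float  # lobule X brain-weight coupling
    m_x: float  # direct autism-male lobule X coefficient
    beta_age: float
    log_bw_ref: float


def _log_moments(mean, sd):
    """Approximate (E log X, Var log X) for X ~ Normal(mean, sd)."""
    return math.log(mean) - sd**2 / (2 * mean**2), sd**2 / mean**2


def _age_factor(cell, beta):
    return math.exp(beta * cell["age_mean"]
                    + beta**2 * cell["age_sd"] ** 2 / 2.0)


def _bw_factor(cell, gamma, log_ref):
    elog, vlog = _log_moments(cell["bw_mean"], cell["bw_sd"])
    return math.exp(gamma * (elog - log_ref) + gamma**2 * vlog / 2.0)


def derive_model(spec: CohortSpec) -> ModelCoefficients:
    """Invert the raw-contrast targets to model coefficients.

    The age slope and the diagnosis x sex demographic structure confound
    every raw contrast; each coefficient is solved so that the *expected*
    raw contrast under the demographic cell normals equals its target.
    """
    cells = _cell_moments()
    beta = spec.age_log_slope
    log_ref = math.log(spec.bw_ref)
    fa = {k: _age_factor(c, beta) for k, c in cells.items()}

    counts = {(dx, sex): n for dx, sex, n in spec.n_per_cell}

    def cellmix(dx, vals):
        m, f = counts[(dx, "M")], counts[(dx, "F")]
        return (m * vals[(dx, "M")] + f * vals[(dx, "F")]) / (m + f)

    # male coefficient g (non-lobX): raw pooled M/F ratio target.
    # mixing weights: males pooled over diagnoses; autism coefficient a_r
    # multiplies both sexes identically within each diagnosis, and the
    # target is defined marginally, so a_r cancels at equal dx mixes;
    # for the (equal) default design we solve g directly from age factors.
    nm = counts[("autism", "M")] + counts[("control", "M")]
    nf = counts[("autism", "F")] + counts[("control", "F")]

    def male_ratio(g, a_r):
        num = (counts[("autism", "M")] * a_r * fa[("autism", "M")]
               + counts[("control", "M")] * fa[("control", "M")]) / nm * g
        den = (counts[("autism", "F")] * a_r * fa[("autism", "F")]
               + counts[("control", "F")] * fa[("control", "F")]) / nf
        return num / den

    # diagnosis coefficients a_r: raw autism/control ratio per region
    a = {}
    for region, target in spec.diagnosis_effect:
        age_ratio = cellmix("autism", fa) / cellmix("control", fa)
        a[region] = target / age_ratio

    # solve g against a representative region effect (weak coupling)
    a_rep = float(np.mean(list(a.values())))
    g = spec.male_effect / (male_ratio(1.0, a_rep))

    # lobule X: gamma and m_X from the two male contrasts
    am, af = fa[("autism", "M")], fa[("autism", "F")]
    cm = fa[("control", "M")]
    e_am, _ = _log_moments(cells[("autism", "M")]["bw_mean"],
                           cells[("autism", "M")]["bw_sd"])
    e_af, _ = _log_moments(cells[("autism", "F")]["bw_mean"],
                           cells[("autism", "F")]["bw_sd"])
    e_cm, _ = _log_moments(cells[("control", "M")]["bw_mean"],
                           cells[("control", "M")]["bw_sd"])

    def mf_ratio(gamma, m_x):
        return (_bw_factor(cells[("autism", "M")], gamma, log_ref) * m_x * am
                ) / (_bw_factor(cells[("autism", "F")], gamma, log_ref) * af)

    def m_ctl_ratio(gamma, m_x):
        return (_bw_factor(cells[("autism", "M")], gamma, log_ref) * m_x * am
                ) / (_bw_factor(cells[("control", "M")], gamma, log_ref) * cm)

    if spec.lobx_mediation == "full":
        # everything through brain weight: fit gamma to the M/F contrast
        def f(gamma):
            return mf_ratio(gamma, 1.0) - spec.lobx_autism_mf

        gamma = brentq(f, -8.0, 8.0)
        m_x = 1.0
    else:
        # two targets, two unknowns; exact in log space
        d1 = e_am - e_af  # autism M vs autism F log BW gap
        d2 = e_am - e_cm  # autism M vs control M log BW gap
        # ignore the small var terms for the closed-form seed, then polish
        t1 = math.log(spec.lobx_autism_mf * af / (am))
        t2 = math.log(spec.lobx_autism_vs_control_m * cm / (am))
        gamma = (t1 - t2) / (d1 - d2)

        def f(gam):
            m_trial = spec.lobx_autism_vs_control_m / m_ctl_ratio(gam, 1.0)
            return mf_ratio(gam, m_trial) - spec.lobx_autism_mf

        gamma = brentq(f, gamma - 2.0, gamma + 2.0)
        m_x = spec.lobx_autism_vs_control_m / m_ctl_ratio(gamma, 1.0)

    return ModelCoefficients(
        a=a, g=g, gamma=gamma, m_x=m_x, beta_age=beta, log_bw_ref=log_ref
    )


def expected_contrasts(spec: CohortSpec) -> dict:
    """Analytic expected raw contrasts (percent differences / ratios) under
    the derived model -- equal to the spec's targets by construction, up to
    the weak cross-coupling terms; used by the recovery tests."""
    coefs = derive_model(spec)
    cells = _cell_moments()
    counts = {(dx, sex): n for dx, sex, n in spec.n_per_cell}
    vols = spec.volume_map
    base = spec.baseline_map

    def cell_mean(region, dx, sex):
        c = cells[(dx, sex)]
        v = base[region] * _age_factor(c, coefs.beta_age)
        if region == "lobuleX":
            v *= _bw_factor(c, coefs.gamma, coefs.log_bw_ref)
            if dx == "autism" and sex == "M":
                v *= coefs.m_x
        else:
            if dx == "autism":
                v *= coefs.a[region]
            if sex == "M":
                v *= coefs.g
        return v

    def group_mean(region, dx=None, sex=None):
        tot, n = 0.0, 0
        for (d, s), cnt in counts.items():
            if dx is not None and d != dx:
                continue
            if sex is not None and s != sex:
                continue
            tot += cnt * cell_mean(region, d, s)
            n += cnt
        return tot / n

    def overall_mean(dx=None, sex=None):
        num = sum(vols[r] * group_mean(r, dx, sex) for r in REGIONS)
        return num / sum(vols[r] for r in REGIONS)

    pct = lambda ref, other: 100.0 * (ref - other) / ref
    return {
        "overall_autism_pct": pct(overall_mean("control"),
                                  overall_mean("autism")),
        "crusI_autism_pct": pct(group_mean("crusI", "control"),
                                group_mean("crusI", "autism")),
        "crusII_autism_pct": pct(group_mean("crusII", "control"),
                                 group_mean("crusII", "autism")),
        "overall_male_pct": pct(overall_mean(sex="F"),
                                overall_mean(sex="M")),
        "lobX_autism_mf_pct": pct(group_mean("lobuleX", "autism", "F"),
                                  group_mean("lobuleX", "autism", "M")),
        "lobX_autism_vs_control_m_pct": pct(
            group_mean("lobuleX", "control", "M"),
            group_mean("lobuleX", "autism", "M")),
    }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_demographics(
    spec: CohortSpec, rng: np.random.Generator | int | None = None
) -> list[CaseProfile]:
    """Draw a cohort's demographics from the clinical-table cell normals."""
    rng = np.random.default_rng(rng)
    cells = _cell_moments()
    profiles = []
    for dx, sex, n in spec.n_per_cell:
        if n < 1:
            raise ValueError("cell sizes must be >= 1")
        c = cells[(dx, sex)]
        for i in range(n):
            age = float(np.clip(rng.normal(c["age_mean"], c["age_sd"]),
                                2.0, 90.0))
            bw = float(np.clip(rng.normal(c["bw_mean"], c["bw_sd"]),
                               800.0, 2200.0))
            profiles.append(
                CaseProfile(
                    case_id=f"SIM-{dx[:3].upper()}-{sex}{i + 1:02d}",
                    diagnosis=dx,
                    sex=sex,
                    age=age,
                    brain_weight=bw,
                    pmi=float(np.clip(rng.normal(17.0, 11.0), 2.0, 60.0)),
                    mr=(dx == "autism" and rng.random() < spec.mr_rate),
                    epilepsy=(dx == "autism"
                              and rng.random() < spec.epilepsy_rate),
                    regression=(dx == "autism"
                                and rng.random() < spec.regression_rate),
                )
            )
    return profiles


def generate_case_truth(
    profile: CaseProfile,
    spec: CohortSpec,
    rng: np.random.Generator | int | None = None,
    coefs: ModelCoefficients | None = None,
) -> CaseTruth:
    """Planted per-region true densities for one case (log-linear model)."""
    rng = np.random.default_rng(rng)
    coefs = coefs or derive_model(spec)
    if profile.brain_weight is None:
        raise ValueError("brain weight required (impute before calling)")
    corr = np.asarray(spec.region_corr)
    cov = corr * spec.region_sd**2
    e = rng.multivariate_normal(np.zeros(len(REGIONS)), cov)
    u = rng.normal(0.0, spec.case_sd)
    base = spec.baseline_map
    dens = {}
    for i, r in enumerate(REGIONS):
        logd = math.log(base[r]) + coefs.beta_age * profile.age + u + e[i]
        if r == "lobuleX":
            logd += coefs.gamma * (math.log(profile.brain_weight)
                                   - coefs.log_bw_ref)
            if profile.diagnosis == "autism" and profile.sex == "M":
                logd += math.log(coefs.m_x)
        else:
            if profile.diagnosis == "autism":
                logd += math.log(coefs.a[r])
            if profile.sex == "M":
                logd += math.log(coefs.g)
        dens[r] = math.exp(logd)
    return CaseTruth(case_id=profile.case_id, true_density=dens)


#: fixed latent cutpoints for the ordinal eye-contact item (standard-normal
#: quantiles of the latent scale at 25/50/75%)
_ADIR_CUTS = (-0.6744897501960817, 0.0, 0.6744897501960817)


def generate_adir_scores(
    profiles: list[CaseProfile],
    truths: dict,
    spec: CohortSpec,
    rng: np.random.Generator | int | None = None,
) -> None:
    """Ordinal eye-contact scores (item Q50, 0-3, higher = more impaired)
    for the autism cases, negatively and monotonically linked to lobule X
    true density; one autism case per cohort is left without usable scores.
    Modifies the profiles in place."""
    rng = np.random.default_rng(rng)
    autism = [p for p in profiles if p.diagnosis == "autism"]
    if not autism:
        raise ValueError("no autism cases to score")
    logd = np.array([math.log(truths[p.case_id].true_density["lobuleX"])
                     for p in autism])
    z = (logd - logd.mean()) / max(logd.std(ddof=0), 1e-12)
    latent = -z + rng.normal(0.0, spec.adir_latent_sd, size=len(autism))
    scale = math.sqrt(1.0 + spec.adir_latent_sd**2)
    scores = np.digitize(latent / scale, _ADIR_CUTS)
    missing = rng.integers(len(autism))
    for i, p in enumerate(autism):
        p.adir_q50 = None if i == missing else int(scores[i])
        # domain totals: noisy sums unrelated to density
        p.adir_domains = {
            "communication": int(np.clip(rng.normal(16, 4), 8, 26)),
            "social": int(np.clip(rng.normal(20, 5), 10, 30)),
            "rrb": int(np.clip(rng.normal(6, 2), 2, 12)),
        }


class ResourceGuardError(RuntimeError):
    """Full-pipeline measurement would exceed the soma budget."""


def measure_cohort(
    truths: list[CaseTruth],
    spec: CohortSpec,
    rng: np.random.Generator | int | None = None,
    mode: str = "fast_surrogate",
    regions: tuple = REGIONS,
    soma_budget: float = 2e7,
    phantom_builder=None,
    design=None,
    series=None,
) -> None:
    """Attach measured densities (and the composite) to each CaseTruth.

    fast_surrogate multiplies truth by mean-one lognormal noise with
    CV = spec.measurement_cv (the desk-scale default, standing in for the
    sampling+estimation pipeline whose mean CE it matches); full_pipeline
    builds a phantom per case and region at the case's true density and
    runs the actual pipeline.
    """
    rng = np.random.default_rng(rng)
    vols = spec.volume_map
    if mode == "fast_surrogate":
        cv = spec.measurement_cv
        sig = math.sqrt(math.log1p(cv * cv))
        for t in truths:
            noise = np.exp(rng.normal(-sig * sig / 2.0, sig,
                                      size=len(regions)))
            for r, n in zip(regions, noise):
                t.measured_density[r] = t.true_density[r] * float(n)
    elif mode == "full_pipeline":
        from .defaults import (REGION_CALIBRATIONS, default_region_spec,
                               target_density)
        from .sampling import sample_region
        from .estimation import estimate_density
        from .virtual_tissue import assemble_region

        if phantom_builder is None:
            total = 0.0
            for t in truths:
                for r in regions:
                    cal = REGION_CALIBRATIONS[r]
                    total += t.true_density[r] * cal.n_frames_target \
                        * cal.grid_pitch**2 * 1200.0 / UM3_PER_MM3
            if total > soma_budget:
                raise ResourceGuardError(
                    f"full pipeline would simulate ~{total:.2e} somata "
                    f"(budget {soma_budget:.2e}); use fast_surrogate, fewer "
                    "regions, or a custom phantom_builder"
                )

        for t in truths:
            for r in regions:
                seed = int(rng.integers(2**31))
                if phantom_builder is not None:
                    reg = phantom_builder(r, t.true_density[r], seed)
                else:
                    cal = REGION_CALIBRATIONS[r]
                    scale = t.true_density[r] / target_density(cal)
                    reg = assemble_region(default_region_spec(
                        r, rng_seed=seed, density_scale=scale,
                    ))
                est = estimate_density(
                    sample_region(reg, series, design, rng)
                )
                t.measured_density[r] = est.density
    else:
        raise ValueError(f"unknown measurement mode {mode!r}")
    for t in truths:
        t.overall_measured = overall_weighted_density(
            [t.measured_density.get(r) for r in regions],
            [vols[r] for r in regions],
        )


# ---------------------------------------------------------------------------
# one-call cohort simulation and tidy output
# ---------------------------------------------------------------------------


def simulate_cohort(
    spec: CohortSpec | None = None,
    rng: np.random.Generator | int | None = None,
    mode: str = "fast_surrogate",
    with_adir: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort; returns (cases, densities) tidy DataFrames."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    coefs = derive_model(spec)
    profiles = generate_demographics(spec, rng)
    truths = [generate_case_truth(p, spec, rng, coefs) for p in profiles]
    tmap = {t.case_id: t for t in truths}
    if with_adir:
        generate_adir_scores(profiles, tmap, spec, rng)
    measure_cohort(truths, spec, rng, mode=mode)

    cases = pd.DataFrame(
        dict(
            case_id=p.case_id, diagnosis=p.diagnosis, sex=p.sex,
            age=p.age, brain_weight=p.brain_weight, pmi=p.pmi,
            mr=p.mr, epilepsy=p.epilepsy, regression=p.regression,
            adir_q50=(np.nan if p.adir_q50 is None else p.adir_q50),
            overall_density=tmap[p.case_id].overall_measured,
        )
        for p in profiles
    )
    dens_rows = []
    vols = spec.volume_map
    for p in profiles:
        t = tmap[p.case_id]
        for r in REGIONS:
            dens_rows.append(
                dict(
                    case_id=p.case_id, region=r,
                    true_density=t.true_density[r],
                    measured_density=t.measured_density[r],
                    log_density=math.log(t.measured_density[r]),
                    regional_volume=vols[r],
                )
            )
    return cases, pd.DataFrame(dens_rows)


def cohort_contrasts(cases: pd.DataFrame, dens: pd.DataFrame) -> dict:
    """The reported raw contrasts, computed from one simulated cohort."""
    merged = dens.merge(
        cases[["case_id", "diagnosis", "sex"]], on="case_id"
    )

    def region_mean(region, dx=None, sex=None):
        m = merged.region == region
        if dx:
            m &= merged.diagnosis == dx
        if sex:
            m &= merged.sex == sex
        return merged.loc[m, "measured_density"].mean()

    def overall_mean(dx=None, sex=None):
        m = np.ones(len(cases), dtype=bool)
        if dx:
            m &= (cases.diagnosis == dx).to_numpy()
        if sex:
            m &= (cases.sex == sex).to_numpy()
        return cases.loc[m, "overall_density"].mean()

    pct = lambda ref, other: 100.0 * (ref - other) / ref
    crus = merged[merged.region.isin(["crusI", "crusII"])].pivot(
        index="case_id", columns="region", values="log_density"
    )
    r_crus = float(np.corrcoef(crus["crusI"], crus["crusII"])[0, 1])

    aut = cases[cases.diagnosis == "autism"].dropna(subset=["adir_q50"])
    lobx = merged[merged.region == "lobuleX"].set_index("case_id")
    rho = np.nan
    if len(aut) >= 4:
        from scipy.stats import spearmanr
        rho = float(
            spearmanr(
                lobx.loc[aut.case_id, "measured_density"], aut.adir_q50
            ).statistic
        )
    return {
        "overall_autism_pct": pct(overall_mean("control"),
                                  overall_mean("autism")),
        "crusI_autism_pct": pct(region_mean("crusI", "control"),
                                region_mean("crusI", "autism")),
        "crusII_autism_pct": pct(region_mean("crusII", "control"),
                                 region_mean("crusII", "autism")),
        "overall_male_pct": pct(overall_mean(sex="F"),
                                overall_mean(sex="M")),
        "lobX_autism_mf_pct": pct(region_mean("lobuleX", "autism", "F"),
                                  region_mean("lobuleX", "autism", "M")),
        "lobX_autism_vs_control_m_pct": pct(
            region_mean("lobuleX", "control", "M"),
            region_mean("lobuleX", "autism", "M")),
        "crusI_crusII_corr": r_crus,
        "lobX_adir_spearman": rho,
    }
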