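"""Statistical battery for cohort density tables.

Implements the analysis pipeline applied to postmortem Purkinje-cell
density measures: Levene-gated two-sample t-tests with percent differences,
a random-intercept factorial model of log density with optional
regional-volume weights and a brain-weight covariate, Benjamini-Hochberg
FDR control, bootstrap Spearman correlations, and observed power of a 2x2
interaction from Cohen's f.

All tests are two-sided at alpha = 0.05 unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize

__all__ = [
    "ComparisonResult",
    "FactorialResult",
    "CorrelationResult",
    "levene_test",
    "two_group_compare",
    "weighted_factorial_analysis",
    "bh_fdr",
    "spearman_bootstrap",
    "interaction_power",
    "covariate_adjusted_comparison",
]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group contrast: t statistic, df, p, and the percent
    difference relative to the stated reference (larger-mean) group."""

    contrast: str
    n1: int
    n2: int
    flavor: str  # pooled_t | welch_t
    t: float
    df: float
    p: float
    percent_difference: float
    reference: str
    levene_w: float
    levene_p: float
    passed_fdr: bool | None = None


@dataclass(frozen=True)
class FactorialResult:
    """Per-term F tests of the factorial (mixed) model."""

    terms: dict  # term -> (F, df1, df2, p)
    weighting: str
    n_cases: int
    n_obs: int
    sigma_case: float
    sigma_resid: float
    coefficients: dict

    def f(self, term: str) -> float:
        return self.terms[term][0]

    def p(self, term: str) -> float:
        return self.terms[term][3]


@dataclass(frozen=True)
class CorrelationResult:
    variables: tuple
    rho: float
    p: float
    ci: tuple  # bootstrap 95% percentile interval
    n: int
    n_boot: int


class InsufficientDataError(ValueError):
    pass


class SingularDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Levene-gated t tests
# ---------------------------------------------------------------------------


def levene_test(x, y, center: str = "mean") -> tuple[float, float]:
    """Levene's test of equality of variances (center = mean, as in the
    classic formulation; median gives the Brown-Forsythe variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("Levene needs >= 2 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0, 1.0
    w, p = sps.levene(x, y, center=center)
    return float(w), float(p)


def two_group_compare(
    x,
    y,
    alpha: float = 0.05,
    labels: tuple = ("group1", "group2"),
    contrast: str | None = None,
) -> ComparisonResult:
    """Levene-gated two-sample comparison.

    Pooled t if Levene's p >= alpha, Welch's t otherwise.  The percent
    difference is (mean_ref - mean_other) / mean_ref * 100 with the
    larger-mean group as reference, which is how the deficits are quoted
    ("x% lower in <other group>").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("need >= 2 observations per group")
    w, lev_p = levene_test(x, y)
    pooled = lev_p >= alpha
    res = sps.ttest_ind(x, y, equal_var=pooled)
    mx, my = x.mean(), y.mean()
    if mx >= my:
        ref, pct = labels[0], 100.0 * (mx - my) / mx if mx != 0 else 0.0
    else:
        ref, pct = labels[1], 100.0 * (my - mx) / my
    return ComparisonResult(
        contrast=contrast or f"{labels[0]} vs {labels[1]}",
        n1=len(x),
        n2=len(y),
        flavor="pooled_t" if pooled else "welch_t",
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        percent_difference=float(pct),
        reference=ref,
        levene_w=w,
        levene_p=lev_p,
    )


# ---------------------------------------------------------------------------
# weighted random-intercept factorial model
# ---------------------------------------------------------------------------


def _sum_code(values, levels):
    """Deviation (sum-to-zero) coding: len(levels)-1 columns."""
    values = np.asarray(values)
    cols = []
    for lev in levels[:-1]:
        c = np.where(values == lev, 1.0, 0.0)
        c = c - np.where(values == levels[-1], 1.0, 0.0)
        cols.append(c)
    return np.column_stack(cols)


def _build_design(df, covariates):
    """Sum-coded full-factorial design for diagnosis x gender x region."""
    dx_levels = sorted(df["diagnosis"].unique())
    sex_levels = sorted(df["sex"].unique())
    reg_levels = sorted(df["region"].unique())
    if len(dx_levels) != 2 or len(sex_levels) != 2:
        raise SingularDesignError("need two diagnosis and two sex levels")
    d = _sum_code(df["diagnosis"], dx_levels)
    s = _sum_code(df["sex"], sex_levels)
    r = _sum_code(df["region"], reg_levels)
    blocks = [("Intercept", np.ones((len(df), 1)))]
    blocks.append(("diagnosis", d))
    blocks.append(("gender", s))
    blocks.append(("region", r))
    blocks.append(("diagnosis*gender", d * s))
    blocks.append(("diagnosis*region", d * r))
    blocks.append(("gender*region", s * r))
    blocks.append(("gender*diagnosis*region", d * s * r))
    for cov in covariates:
        vals = df[cov].to_numpy(dtype=float)
        blocks.append((cov, (vals - vals.mean())[:, None]))
    X = np.hstack([b for _, b in blocks])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "rank-deficient design (empty diagnosis x gender x region cell?)"
        )
    spans, i = {}, 0
    for name, b in blocks:
        spans[name] = list(range(i, i + b.shape[1]))
        i += b.shape[1]
    return X, spans


# terms whose variation is purely between cases (within-case constant)
_BETWEEN_TERMS = ("diagnosis", "gender", "diagnosis*gender", "brain_weight")


def weighted_factorial_analysis(
    data: pd.DataFrame,
    response: str = "log_density",
    weights: str | None = "regional_volume",
    covariates: tuple = (),
    cluster: str = "case_id",
) -> FactorialResult:
    """Random-intercept factorial model of log density.

    Fixed effects: diagnosis, gender, region and all their interactions
    (sum coding, Type III Wald F per term), optional centred covariates
    (e.g. brain weight); a random intercept per case; observation weights
    proportional to the regional volume each density measure came from
    (weights=None reproduces the unweighted fit).  Variances are estimated
    by maximum likelihood; denominator df follow the between/within (split
    plot) containment rule.
    """
    df = data.dropna(subset=[response] + list(covariates)).copy()
    y = df[response].to_numpy(dtype=float)
    X, spans = _build_design(df, covariates)
    cases, case_idx = np.unique(df[cluster], return_inverse=True)
    n_cases, n_obs, p = len(cases), len(y), X.shape[1]
    if weights is not None:
        w = df[weights].to_numpy(dtype=float)
        w = w / w.mean()
        weighting = f"obs weights ~ {weights}"
    else:
        w = np.ones(n_obs)
        weighting = "unweighted"

    blocks = [np.flatnonzero(case_idx == i) for i in range(n_cases)]

    def fit(theta):
        """Profiled ML: given variance components, GLS beta and loglik."""
        s2u, s2e = np.exp(theta)
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        logdet = 0.0
        vinvs = []
        for idx in blocks:
            Vi = s2u + np.where(
                np.eye(len(idx), dtype=bool), s2e / w[idx], 0.0
            )
            Vinv = np.linalg.inv(Vi)
            sign, ld = np.linalg.slogdet(Vi)
            logdet += ld
            Xi, yi = X[idx], y[idx]
            xtvx += Xi.T @ Vinv @ Xi
            xtvy += Xi.T @ Vinv @ yi
            vinvs.append(Vinv)
        beta = np.linalg.solve(xtvx, xtvy)
        quad = 0.0
        for idx, Vinv in zip(blocks, vinvs):
            r = y[idx] - X[idx] @ beta
            quad += r @ Vinv @ r
        ll = -0.5 * (logdet + quad + n_obs * math.log(2.0 * math.pi))
        return ll, beta, xtvx

    var_y = max(np.var(y), 1e-8)
    res = minimize(
        lambda th: -fit(th)[0],
        x0=np.log([var_y / 2.0, var_y / 2.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
    )
    ll, beta, xtvx = fit(res.x)
    s2u, s2e = np.exp(res.x)
    cov_beta = np.linalg.inv(xtvx)

    # containment denominator df
    p_between = 1 + sum(
        len(spans[t]) for t in spans if t in _BETWEEN_TERMS
    )
    p_within = p - p_between
    df_between = n_cases - p_between
    df_within = n_obs - n_cases - p_within
    if df_between <= 0 or df_within <= 0:
        raise SingularDesignError("not enough cases/observations for df")

    terms = {}
    for name, cols in spans.items():
        if name == "Intercept":
            continue
        c = np.array(cols)
        b = beta[c]
        vb = cov_beta[np.ix_(c, c)]
        q = len(c)
        fstat = float(b @ np.linalg.solve(vb, b)) / q
        df2 = df_between if name in _BETWEEN_TERMS else df_within
        pval = float(sps.f.sf(fstat, q, df2))
        terms[name] = (fstat, q, df2, pval)

    return FactorialResult(
        terms=terms,
        weighting=weighting,
        n_cases=n_cases,
        n_obs=n_obs,
        sigma_case=math.sqrt(s2u),
        sigma_resid=math.sqrt(s2e),
        coefficients={
            name: beta[cols].tolist() for name, cols in spans.items()
        },
    )


# ---------------------------------------------------------------------------
# false discovery rate
# ---------------------------------------------------------------------------


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up.

    Flags all p <= p_(k) where k is the largest rank with
    p_(k) <= k * q / m.  Returns (boolean flags, p-value cutoff); the
    cutoff is 0 when nothing is flagged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    thresh = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(order <= thresh)
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    cutoff = order[passing[-1]]
    return p <= cutoff, float(cutoff)


# ---------------------------------------------------------------------------
# Spearman correlation with bootstrap CI
# ---------------------------------------------------------------------------


def _spearman_exact_p(x, y, rho):
    """Exact permutation p (two-sided) for small n."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def spearman_bootstrap(
    x,
    y,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    exact_p_max_n: int = 8,
) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties) with a percentile
    bootstrap confidence interval.

    The p-value is an exact permutation p for n <= exact_p_max_n and the
    usual t approximation otherwise.  The CI is widened minimally to
    contain the point estimate if a heavily tied resample distribution
    fails to.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            ("x", "y"), math.nan, math.nan, (math.nan, math.nan),
            len(x), n_boot,
        )
    rng = np.random.default_rng(rng)
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= exact_p_max_n:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    boots = np.empty(n_boot)
    n = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            boots[b] = np.nan
            continue
        boots[b] = sps.spearmanr(xs, ys).statistic
    boots = boots[~np.isnan(boots)]
    if boots.size:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = rho
    lo, hi = min(lo, rho), max(hi, rho)
    return CorrelationResult(
        ("x", "y"), rho, float(p), (float(lo), float(hi)), n, n_boot
    )


# ---------------------------------------------------------------------------
# observed power of the 2x2 interaction
# ---------------------------------------------------------------------------


def interaction_noncentrality(
    f: float, n_total: int, design: tuple = (2, 2),
    convention: str = "cohen",
) -> float:
    """Noncentrality implied by an effect size f.

    'cohen': lambda = f^2 * N (the standard definition of Cohen's f);
    'spss' : lambda = f^2 * (df_error + df_hyp + 1), the convention behind
    SPSS's observed-power output, which is how published observed-power /
    f pairs from that software are internally consistent.
    """
    a, b = design
    df1 = (a - 1) * (b - 1)
    df2 = n_total - a * b
    if convention == "cohen":
        return f * f * n_total
    if convention == "spss":
        return f * f * (df2 + df1 + 1)
    raise ValueError(f"unknown convention {convention!r}")


def interaction_power(
    f: float,
    n_total: int,
    alpha: float = 0.05,
    design: tuple = (2, 2),
    convention: str = "cohen",
) -> float:
    """Power of the interaction F test in a balanced factorial ANOVA.

    P(F'(df1, df2, lambda) > F_crit) with df1 = (a-1)(b-1),
    df2 = N - a*b, and lambda from interaction_noncentrality.
    """
    if f < 0:
        raise ValueError("effect size f must be >= 0")
    a, b = design
    df1 = (a - 1) * (b - 1)
    df2 = n_total - a * b
    if df2 <= 0:
        raise ValueError("non-positive error df: need n_total > a*b")
    fcrit = sps.f.isf(alpha, df1, df2)
    lam = interaction_noncentrality(f, n_total, design, convention)
    if lam == 0:
        return float(alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


# ---------------------------------------------------------------------------
# covariate-adjusted group contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjustedComparison:
    contrast: str
    adjusted_p: float
    unadjusted_p: float
    adjusted_t: float
    group_coef: float
    n: int
    dropped: int


def covariate_adjusted_comparison(
    y, group, covariate, contrast: str = "group effect"
) -> AdjustedComparison:
    """Group contrast with and without a numeric covariate (linear model
    y ~ group + covariate); cases missing the covariate are dropped."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    cov = np.asarray(covariate, dtype=float)
    keep = ~np.isnan(cov) & ~np.isnan(y)
    dropped = int((~keep).sum())
    y, g, cov = y[keep], g[keep], cov[keep]
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("group must be binary")
    gi = np.where(g == levels[0], 1.0, 0.0)
    if np.ptp(cov) == 0:
        raise SingularDesignError("covariate has zero variance")
    # covariate collinear with the group indicator?
    resid = cov - np.polyval(np.polyfit(gi, cov, 1), gi)
    if np.allclose(resid, 0.0):
        raise SingularDesignError(
            "covariate is collinear with the group indicator"
        )

    def _ols_group_p(X):
        n, k = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2 = (r @ r) / (n - k)
        covb = s2 * np.linalg.inv(X.T @ X)
        t = beta[1] / math.sqrt(covb[1, 1])
        p = 2.0 * sps.t.sf(abs(t), n - k)
        return float(t), float(p), float(beta[1])

    ones = np.ones_like(gi)
    t_adj, p_adj, coef = _ols_group_p(np.column_stack([ones, gi, cov]))
    _, p_raw, _ = _ols_group_p(np.column_stack([ones, gi]))
    return AdjustedComparison(
        contrast=contrast,
        adjusted_p=p_adj,
        unadjusted_p=p_raw,
        adjusted_t=t_adj,
        group_coef=coef,
        n=len(y),
        dropped=dropped,
    )
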