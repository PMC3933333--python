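"""High-level analysis reports on cohort tables.

Glue between the cohort tables and the stats battery: reproduces the shape
of the published analyses -- the four factorial model variants (volume
weighted or not, with or without the brain-weight covariate), the
FDR-controlled regional t-tests, the brain-weight / age demographic
contrasts, and the lobule X / eye-contact correlation.
"""

from __future__ import annotations


import pandas as pd

from .cohort_sim import REGIONS, table1_dataframe
from .stats import (
    bh_fdr,
    covariate_adjusted_comparison,
    spearman_bootstrap,
    two_group_compare,
    weighted_factorial_analysis,
)


def table1_report() -> dict:
    """Demographic contrasts from the packaged clinical table."""
    df = table1_dataframe()
    bw = df.dropna(subset=["brain_weight"])
    bw_cmp = two_group_compare(
        bw[bw.sex == "M"].brain_weight, bw[bw.sex == "F"].brain_weight,
        labels=("male", "female"),
        contrast="brain weight, males vs females",
    )
    age_cmp = two_group_compare(
        df[df.sex == "M"].age, df[df.sex == "F"].age,
        labels=("male", "female"), contrast="age, males vs females",
    )
    return {
        "n_cases": int(len(df)),
        "n_with_brain_weight": int(len(bw)),
        "brain_weight": {
            "percent_difference": bw_cmp.percent_difference,
            "lower_group": "female",
            "t": bw_cmp.t, "df": bw_cmp.df, "p": bw_cmp.p,
            "flavor": bw_cmp.flavor,
        },
        "age": {
            "t": age_cmp.t, "df": age_cmp.df, "p": age_cmp.p,
            "flavor": age_cmp.flavor,
        },
    }


def regional_ttests(merged: pd.DataFrame, q: float = 0.10) -> list[dict]:
    """Per-region autism-vs-control Levene-gated t-tests with BH FDR.

    q defaults to 0.10, the rate at which the published flag pattern
    (crus I and II flagged, the others not) is reproduced by the step-up
    rule on the printed p-values.
    """
    rows = []
    for region in REGIONS:
        sub = merged[merged.region == region]
        ctl = sub[sub.diagnosis == "control"].measured_density
        aut = sub[sub.diagnosis == "autism"].measured_density
        cmp_ = two_group_compare(
            ctl, aut, labels=("control", "autism"),
            contrast=f"{region}: autism vs control",
        )
        rows.append(dict(
            region=region, t=cmp_.t, df=cmp_.df, p=cmp_.p,
            percent_difference=cmp_.percent_difference,
            flavor=cmp_.flavor, n_autism=len(aut), n_control=len(ctl),
        ))
    flags, cutoff = bh_fdr([r["p"] for r in rows], q=q)
    for r, f in zip(rows, flags):
        r["passed_fdr"] = bool(f)
        r["fdr_q"] = q
        r["fdr_cutoff"] = cutoff
    return rows


def factorial_battery(merged: pd.DataFrame) -> dict:
    """The four factorial-model variants on log density."""
    out = {}
    variants = {
        "test1_weighted": dict(weights="regional_volume", covariates=()),
        "test2_weighted_bw": dict(weights="regional_volume",
                                  covariates=("brain_weight",)),
        "test3_unweighted": dict(weights=None, covariates=()),
        "test4_unweighted_bw": dict(weights=None,
                                    covariates=("brain_weight",)),
    }
    for name, kw in variants.items():
        res = weighted_factorial_analysis(merged, **kw)
        out[name] = {
            "weighting": res.weighting,
            "n_cases": res.n_cases,
            "terms": {t: {"F": v[0], "df1": v[1], "df2": v[2], "p": v[3]}
                      for t, v in res.terms.items()},
        }
    return out


def analyze_cohort(
    cases: pd.DataFrame,
    dens: pd.DataFrame,
    rng=0,
    fdr_q: float = 0.10,
) -> dict:
    """Full battery on one cohort (simulated or imported)."""
    merged = dens.merge(
        cases[["case_id", "diagnosis", "sex", "brain_weight", "age"]],
        on="case_id",
    )
    report = {
        "factorial": factorial_battery(merged),
        "regional_tests": regional_ttests(merged, q=fdr_q),
    }

    # lobule X gender contrasts inside the autism group, and the
    # brain-weight-adjusted versions
    lobx = merged[merged.region == "lobuleX"]
    aut = lobx[lobx.diagnosis == "autism"]
    if aut.sex.nunique() == 2:
        mf = two_group_compare(
            aut[aut.sex == "F"].measured_density,
            aut[aut.sex == "M"].measured_density,
            labels=("female", "male"),
            contrast="lobule X autism: males vs females",
        )
        adj = covariate_adjusted_comparison(
            aut.measured_density.to_numpy(),
            aut.sex.to_numpy(),
            aut.brain_weight.to_numpy(),
            contrast="lobule X autism M vs F | brain weight",
        )
        report["lobx_autism_gender"] = {
            "percent_difference": mf.percent_difference,
            "t": mf.t, "df": mf.df, "p": mf.p,
            "adjusted_p": adj.adjusted_p,
            "unadjusted_p": adj.unadjusted_p,
        }

    # lobule X density vs eye-contact item among autism cases
    aut_cases = cases[cases.diagnosis == "autism"].dropna(
        subset=["adir_q50"]) if "adir_q50" in cases else pd.DataFrame()
    if len(aut_cases) >= 4:
        lx = lobx.set_index("case_id").loc[aut_cases.case_id]
        corr = spearman_bootstrap(
            lx.measured_density.to_numpy(),
            aut_cases.adir_q50.to_numpy(),
            rng=rng,
        )
        report["lobx_adir_q50"] = {
            "rho": corr.rho, "p": corr.p, "ci": list(corr.ci),
            "n": corr.n,
        }
    return report
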