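"""Levene-gated t-tests, the factorial mixed model, FDR, Spearman,
and observed power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcstereo.cohort_sim import (
    CohortSpec,
    simulate_cohort,
    table1_dataframe,
)
from pcstereo.stats import (
    InsufficientDataError,
    SingularDesignError,
    bh_fdr,
    covariate_adjusted_comparison,
    interaction_power,
    levene_test,
    spearman_bootstrap,
    two_group_compare,
    weighted_factorial_analysis,
)


def neutral_cohort_spec():
    return CohortSpec(
        diagnosis_effect=(("lobulesIV_VI", 1.0), ("crusI", 1.0),
                          ("crusII", 1.0)),
        male_effect=1.0, lobx_autism_mf=1.0,
        lobx_autism_vs_control_m=1.0, overall_autism_ratio=1.0,
        age_log_slope=0.0,
    )


def merged_cohort(spec, rng):
    cases, dens = simulate_cohort(spec, rng=rng, with_adir=False)
    return dens.merge(
        cases[["case_id", "diagnosis", "sex", "brain_weight"]], on="case_id"
    )


class TestLevene:
    def test_identical_groups_give_zero_statistic(self):
        w, p = levene_test([3.0, 3.0, 3.0], [7.0, 7.0, 7.0])
        assert w == 0.0 and p == 1.0

    def test_textbook_formula_oracle(self):
        """Independent hand computation of W on a small example."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        zx = np.abs(x - x.mean())
        zy = np.abs(y - y.mean())
        zbar = np.concatenate([zx, zy]).mean()
        num = 4 * (zx.mean() - zbar) ** 2 + 4 * (zy.mean() - zbar) ** 2
        den = ((zx - zx.mean()) ** 2).sum() + ((zy - zy.mean()) ** 2).sum()
        w_hand = (8 - 2) / (2 - 1) * num / den
        w, p = levene_test(x, y)
        assert w == pytest.approx(w_hand, rel=1e-12)
        assert 0.0 <= p <= 1.0

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=12),
        st.lists(st.floats(-100, 100), min_size=3, max_size=12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_value_always_in_unit_interval(self, x, y):
        w, p = levene_test(x, y)
        assert w >= 0.0
        assert 0.0 <= p <= 1.0


class TestTwoGroupCompare:
    def test_brain_weight_contrast_with_hand_pooled_t(self):
        """13.5% lower female brain weight; pooled t from the explicit
        two-sample formula."""
        df = table1_dataframe().dropna(subset=["brain_weight"])
        m = df[df.sex == "M"].brain_weight.to_numpy()
        f = df[df.sex == "F"].brain_weight.to_numpy()
        res = two_group_compare(m, f, labels=("male", "female"))
        assert res.percent_difference == pytest.approx(13.5, abs=0.05)
        assert res.reference == "male"
        # independent pooled-t computation
        sp2 = (
            (len(m) - 1) * m.var(ddof=1) + (len(f) - 1) * f.var(ddof=1)
        ) / (len(m) + len(f) - 2)
        t_hand = (m.mean() - f.mean()) / math.sqrt(
            sp2 * (1 / len(m) + 1 / len(f))
        )
        assert res.flavor == "pooled_t"
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.t == pytest.approx(2.87, abs=0.01)
        assert res.df == 13

    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0]
        res = two_group_compare(x, x)
        assert res.t == 0.0
        assert res.percent_difference == 0.0

    def test_welch_branch_on_unequal_variances(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.1, 40)
        y = rng.normal(0.5, 30.0, 40)
        res = two_group_compare(x, y)
        assert res.flavor == "welch_t"
        assert res.df != pytest.approx(78.0)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_group_compare([1.0], [2.0, 3.0])

    def test_type_one_error_of_gated_procedure(self):
        """Null simulation: rejection rate of the Levene-gated t at
        alpha=.05 stays within the binomial envelope."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 600
        for _ in range(n_sim):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            rejections += two_group_compare(x, y).p < 0.05
        rate = rejections / n_sim
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert rate < 0.05 + 3 * se


class TestFactorialModel:
    def test_equal_weights_match_unweighted_fit(self):
        spec = CohortSpec()
        tab = merged_cohort(spec, rng=3)
        tab["regional_volume"] = 1.0
        a = weighted_factorial_analysis(tab, weights="regional_volume")
        b = weighted_factorial_analysis(tab, weights=None)
        for term in a.terms:
            assert a.terms[term][0] == pytest.approx(
                b.terms[term][0], rel=1e-3
            )

    def test_unweighted_fit_matches_statsmodels_mixedlm(self):
        """Independent route: same random-intercept model via MixedLM."""
        import statsmodels.formula.api as smf

        tab = merged_cohort(CohortSpec(), rng=5)
        ours = weighted_factorial_analysis(tab, weights=None)
        md = smf.mixedlm(
            "log_density ~ C(diagnosis, Sum) * C(sex, Sum) "
            "* C(region, Sum)",
            tab, groups=tab["case_id"],
        ).fit(reml=False)
        assert ours.sigma_case**2 == pytest.approx(
            float(md.cov_re.iloc[0, 0]), rel=0.05, abs=1e-4
        )
        assert ours.sigma_resid**2 == pytest.approx(md.scale, rel=0.05)
        # diagnosis fixed effect (1 column, sum coding) matches
        ours_dx = ours.coefficients["diagnosis"][0]
        sm_dx = [v for k, v in md.params.items()
                 if "diagnosis" in k and "sex" not in k
                 and "region" not in k][0]
        assert ours_dx == pytest.approx(sm_dx, rel=0.02, abs=1e-3)

    def test_null_type_one_error_per_term(self):
        """All effects 1: term rejection rates at alpha=.05 stay inside
        the binomial envelope (120 null cohorts)."""
        spec = neutral_cohort_spec()
        rng = np.random.default_rng(21)
        rej = {"diagnosis": 0, "gender*diagnosis*region": 0}
        n_sim = 120
        for _ in range(n_sim):
            tab = merged_cohort(spec, rng)
            res = weighted_factorial_analysis(tab)
            for term in rej:
                rej[term] += res.p(term) < 0.05
        se = math.sqrt(0.05 * 0.95 / n_sim)
        for term, k in rej.items():
            assert k / n_sim < 0.05 + 3.5 * se, (term, k / n_sim)

    def test_planted_diagnosis_effect_detected(self):
        """Cohorts with only a diagnosis effect planted (20% in the three
        hemispheric regions): the diagnosis term is significant in over
        half of runs for the unweighted fit, while interaction terms
        without planted structure stay at null rates.  (Volume weighting
        concentrates the fit on the largest region and is less powerful;
        it still detects the effect well above the null rate.)"""
        spec = CohortSpec(
            diagnosis_effect=(("lobulesIV_VI", 0.8), ("crusI", 0.8),
                              ("crusII", 0.8)),
            male_effect=1.0, lobx_autism_mf=1.0,
            lobx_autism_vs_control_m=1.0, overall_autism_ratio=1.0,
            age_log_slope=0.0,
        )
        rng = np.random.default_rng(22)
        n_sim, dx_unw, dx_w, int_hits = 80, 0, 0, 0
        for _ in range(n_sim):
            tab = merged_cohort(spec, rng)
            res_u = weighted_factorial_analysis(tab, weights=None)
            res_w = weighted_factorial_analysis(tab)
            dx_unw += res_u.p("diagnosis") < 0.05
            dx_w += res_w.p("diagnosis") < 0.05
            int_hits += res_u.p("diagnosis*gender") < 0.05
        assert dx_unw / n_sim > 0.5
        assert dx_w / n_sim > 0.25
        assert int_hits / n_sim < 0.15

    def test_invariance_to_factor_relabeling(self):
        tab = merged_cohort(CohortSpec(), rng=7)
        res1 = weighted_factorial_analysis(tab)
        relabeled = tab.copy()
        relabeled["diagnosis"] = relabeled["diagnosis"].map(
            {"autism": "zz_case", "control": "aa_ref"}
        )
        relabeled["region"] = relabeled["region"].map(
            {"lobulesIV_VI": "r4", "crusI": "r1", "crusII": "r2",
             "lobuleX": "r3"}
        )
        res2 = weighted_factorial_analysis(relabeled)
        for term in res1.terms:
            assert res1.terms[term][0] == pytest.approx(
                res2.terms[term][0], rel=1e-6
            )

    def test_empty_cell_raises_singular_design(self):
        tab = merged_cohort(CohortSpec(), rng=9)
        broken = tab[~((tab.diagnosis == "autism") & (tab.sex == "F"))]
        with pytest.raises(SingularDesignError):
            weighted_factorial_analysis(broken)


class TestBHFDR:
    def test_step_up_flags_all_three(self):
        flags, cutoff = bh_fdr([0.01, 0.02, 0.04], q=0.05)
        assert flags.all()
        assert cutoff == 0.04

    def test_reported_regional_pattern(self):
        """On the published regional p-values the step-up rule flags
        exactly the two crus regions at q=0.10 and nothing at q=0.05."""
        ps = [0.512, 0.039, 0.032, 0.173]  # IV-VI, crus I, crus II, X
        flags10, _ = bh_fdr(ps, q=0.10)
        assert list(flags10) == [False, True, True, False]
        flags05, _ = bh_fdr(ps, q=0.05)
        assert not flags05.any()

    def test_all_ones_flag_nothing(self):
        flags, cutoff = bh_fdr([1.0, 1.0, 1.0])
        assert not flags.any() and cutoff == 0.0

    def test_empty_input(self):
        flags, cutoff = bh_fdr([])
        assert flags.size == 0

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(2, 12))
            ours, _ = bh_fdr(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=10),
        st.integers(0, 9),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotonicity_in_p_values(self, ps, idx):
        """Decreasing any p-value never unflags a hypothesis."""
        ps = list(ps)
        idx = idx % len(ps)
        before, _ = bh_fdr(ps, q=0.05)
        ps2 = list(ps)
        ps2[idx] = ps2[idx] / 2.0
        after, _ = bh_fdr(ps2, q=0.05)
        unchanged = [i for i in range(len(ps)) if i != idx]
        assert int(before.sum()) <= int(after.sum())
        for i in unchanged:
            if before[i] and ps[i] <= ps2[idx]:
                assert after[i]


class TestSpearman:
    def test_perfect_monotone_association(self):
        x = np.arange(10.0)
        res = spearman_bootstrap(x, np.exp(x), rng=1)
        assert res.rho == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = spearman_bootstrap(x, y, n_boot=10, rng=1).rho
        r2 = spearman_bootstrap(np.exp(3 * x), y, n_boot=10, rng=1).rho
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_seven_point_rank_formula_oracle(self):
        """rho = 1 - 6 sum d^2 / (n(n^2-1)) for untied data."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([2.0, 0.5, 6.0, 1.0, 4.0, 8.0, 3.0])
        from scipy.stats import rankdata

        d = rankdata(x) - rankdata(y)
        rho_hand = 1 - 6 * (d**2).sum() / (7 * 48)
        res = spearman_bootstrap(x, y, rng=5)
        assert res.rho == pytest.approx(rho_hand, rel=1e-12)
        assert res.ci[0] <= res.rho <= res.ci[1]

    def test_constant_input_flagged(self):
        res = spearman_bootstrap([1.0] * 6, [1, 2, 3, 4, 5, 6], rng=1)
        assert math.isnan(res.rho)

    def test_exact_permutation_p_for_small_n(self):
        """Exact p for n=5 equals brute-force enumeration."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        res = spearman_bootstrap(x, y, n_boot=10, rng=1)
        # rho = 0.8; of 120 permutations, count |rho| >= 0.8
        from itertools import permutations
        from scipy.stats import spearmanr

        count = sum(
            abs(spearmanr(x, np.array(p)).statistic) >= 0.8 - 1e-12
            for p in permutations(y)
        )
        assert res.p == pytest.approx(count / 120.0, rel=1e-12)


class TestInteractionPower:
    def test_zero_effect_gives_alpha(self):
        assert interaction_power(0.0, 16) == pytest.approx(0.05)

    def test_monotone_in_effect_size_and_sample_size(self):
        fs = [0.1, 0.2, 0.4, 0.8]
        powers = [interaction_power(f, 16) for f in fs]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        ns = [8, 16, 32, 64]
        powers_n = [interaction_power(0.36, n) for n in ns]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))

    def test_nonpositive_error_df_rejected(self):
        with pytest.raises(ValueError):
            interaction_power(0.36, 4)

    def test_monte_carlo_anova_cross_check(self):
        """20,000-replicate 2x2 ANOVA simulation agrees with the
        noncentral-F power within 0.02."""
        rng = np.random.default_rng(20_24)
        n_cell, n_sim = 4, 20_000
        f = 0.36
        n_total = 4 * n_cell
        delta = f  # interaction pattern +-delta, sigma=1 -> lambda = f^2 N
        signs = np.array([1.0, -1.0, -1.0, 1.0])
        y = rng.normal(size=(n_sim, 4, n_cell)) + (delta * signs)[None, :,
                                                                  None]
        cell_means = y.mean(axis=2)
        inter = (cell_means * signs[None, :]).sum(axis=1) / 4.0
        ss_int = n_cell * 4 * inter**2
        ss_err = ((y - cell_means[:, :, None]) ** 2).sum(axis=(1, 2))
        f_stat = ss_int / (ss_err / (n_total - 4))
        from scipy.stats import f as fdist

        crit = fdist.isf(0.05, 1, n_total - 4)
        emp = float((f_stat > crit).mean())
        assert emp == pytest.approx(
            interaction_power(f, n_total, convention="cohen"), abs=0.02
        )


class TestCovariateAdjusted:
    def test_uncorrelated_covariate_leaves_p_nearly_unchanged(self):
        rng = np.random.default_rng(30)
        deltas = []
        for _ in range(200):
            g = np.repeat(["a", "b"], 10)
            y = rng.normal(size=20) + (g == "a") * 0.5
            cov = rng.normal(size=20)
            res = covariate_adjusted_comparison(y, g, cov)
            deltas.append(abs(res.adjusted_p - res.unadjusted_p))
        assert np.median(deltas) < 0.08

    def test_fully_mediated_effect_nullified_by_adjustment(self):
        """Outcome depends on group only through the covariate: adjusted
        rejection rate falls to ~alpha."""
        rng = np.random.default_rng(31)
        n_sim, rejected = 200, 0
        for _ in range(n_sim):
            g = np.repeat(["a", "b"], 12)
            cov = rng.normal(size=24) + (g == "a") * 2.0
            y = 0.8 * cov + rng.normal(scale=0.5, size=24)
            res = covariate_adjusted_comparison(y, g, cov)
            rejected += res.adjusted_p < 0.05
        rate = rejected / n_sim
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert rate < 0.05 + 3.5 * se

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(SingularDesignError):
            covariate_adjusted_comparison(
                [1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"],
                [5.0, 5.0, 5.0, 5.0],
            )

    def test_missing_covariate_rows_dropped_and_reported(self):
        res = covariate_adjusted_comparison(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            ["a", "a", "a", "b", "b", "b"],
            [1.0, 2.0, np.nan, 1.5, 2.5, 3.0],
        )
        assert res.dropped == 1
        assert res.n == 5
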