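"""Response building, LRT/bootstrap, BIC elimination, post-hoc, 1:1 test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wingcrypsis.behavior import (
    FULL_FIXED,
    backward_select_bic,
    build_activity_response,
    build_preference_response,
    fit_glmm,
    lmm_term_ftests,
    lrt,
    parametric_bootstrap_p,
    posthoc_pairwise,
)
from wingcrypsis.behavior import test_vs_even as even_ratio_test
from wingcrypsis.model import MixedModelSpec
from wingcrypsis.simulate import CohortSimParams, generate_cohort_series


def _pref(seed, n_per_cell=2, **kw):
    return build_preference_response(
        generate_cohort_series(CohortSimParams(seed=seed, n_cohorts_per_cell=n_per_cell, **kw))
    )


class TestResponseBuilders:
    def test_direct_mapping_and_t1_exclusion(self, small_cohorts):
        pref = build_preference_response(small_cohorts)
        assert (pref.timepoint >= 2).all()
        merged = pref.merge(
            small_cohorts.rename(columns={"cohort_id": "cohort", "sex": "Sex"}),
            on=["cohort", "timepoint", "Td", "Ta", "Sex"],
        )
        assert (merged.successes == merged.arrivals_brown).all()
        assert (merged.failures == merged.arrivals_green).all()

    def test_row_count_bound(self, small_cohorts):
        n_cohorts = small_cohorts.cohort_id.nunique()
        n_t = small_cohorts.timepoint.max()
        pref = build_preference_response(small_cohorts)
        assert len(pref) <= n_cohorts * (n_t - 1)

    def test_zero_trial_rows_dropped_and_counted(self):
        df = generate_cohort_series(
            CohortSimParams(seed=9, n_cohorts_per_cell=1, mean_relocations_per_photo=1.0)
        )
        pref = build_preference_response(df)
        later = df[df.timepoint > 1]
        n_zero = int(((later.arrivals_brown + later.arrivals_green) == 0).sum())
        assert pref.attrs["n_zero_trial_dropped"] == n_zero
        assert len(pref) == len(later) - n_zero

    def test_activity_totals_conserved(self, small_cohorts):
        act = build_activity_response(small_cohorts)
        later = small_cohorts[small_cohorts.timepoint > 1]
        assert act.successes.sum() == later.relocated.sum()
        assert act.failures.sum() == later.stationary.sum()

    def test_invariant_violation_lists_rows(self, small_cohorts):
        bad = small_cohorts.copy()
        bad.loc[bad.timepoint == 3, "arrivals_brown"] = 99
        with pytest.raises(ValueError, match="invariant violated at rows"):
            build_preference_response(bad)


class TestLrt:
    def test_identical_specs_give_zero_statistic(self):
        data = _pref(seed=30)
        spec = MixedModelSpec(fixed=(("Td",),), random=("cohort",))
        fit = fit_glmm(data, spec)
        result = lrt(fit, fit)
        assert result.statistic == 0.0
        assert result.p_lrt == 1.0

    def test_reported_chi2_tail_is_significant(self):
        """A chi-square statistic of 20.66 on 1 df lies far in the tail."""
        data = _pref(seed=31)
        full = fit_glmm(data, MixedModelSpec(fixed=(("Td",),), random=()))
        reduced = fit_glmm(data, MixedModelSpec(fixed=(), random=()))
        base = lrt(full, reduced)
        assert base.p_lrt == pytest.approx(stats.chi2.sf(base.statistic, 1), abs=1e-12)
        assert stats.chi2.sf(20.66, 1) < 0.001

    def test_non_nested_rejected(self):
        data = _pref(seed=32)
        fit_a = fit_glmm(data, MixedModelSpec(fixed=(("Td",),), random=()))
        fit_b = fit_glmm(data, MixedModelSpec(fixed=(("Sex",),), random=()))
        with pytest.raises(ValueError, match="nested"):
            lrt(fit_a, fit_b)


class TestParametricBootstrap:
    def test_zero_statistic_gives_p_one(self):
        data = _pref(seed=33)
        spec = MixedModelSpec(fixed=(("Td",),), random=())
        fit = fit_glmm(data, spec)
        result = parametric_bootstrap_p(fit, fit, nsim=19, seed=1)
        assert result.p_boot == 1.0

    def test_add_one_formula_bounds(self):
        data = _pref(seed=34, preference_effects={"Td[19]": 2.5}, sigma_cohort=0.0)
        full = fit_glmm(data, MixedModelSpec(fixed=(("Td",),), random=()))
        reduced = fit_glmm(data, MixedModelSpec(fixed=(), random=()))
        result = parametric_bootstrap_p(full, reduced, nsim=99, seed=2)
        assert result.p_boot >= 1.0 / (result.nsim + 1)
        assert result.p_boot <= 1.0
        # strong effect, no null simulation should beat the observed statistic
        assert result.p_boot == pytest.approx(1.0 / (result.nsim + 1))

    def test_deterministic_under_seed(self):
        data = _pref(seed=35)
        full = fit_glmm(data, MixedModelSpec(fixed=(("Td",),), random=()))
        reduced = fit_glmm(data, MixedModelSpec(fixed=(), random=()))
        r1 = parametric_bootstrap_p(full, reduced, nsim=39, seed=7)
        r2 = parametric_bootstrap_p(full, reduced, nsim=39, seed=7)
        assert r1.p_boot == r2.p_boot


class TestBackwardSelection:
    def test_single_beneficial_term_retained(self):
        data = _pref(seed=36, n_per_cell=6, preference_effects={"Td[19]": 1.5},
                     sigma_cohort=0.0, sigma_timepoint=0.0)
        full = MixedModelSpec(fixed=(("Td",),), random=())
        selected, trace = backward_select_bic(data, full)
        assert selected.spec.fixed == (("Td",),)
        assert len(trace) == 1  # no drops

    def test_strong_interaction_structure_retained(self):
        data = _pref(seed=37, n_per_cell=20,
                     preference_effects={"Sex[F]": 1.0, "Ta[19]:Sex[F]": 1.2},
                     sigma_cohort=0.1, sigma_timepoint=0.0)
        full = MixedModelSpec(fixed=FULL_FIXED, random=("cohort",))
        selected, trace = backward_select_bic(data, full)
        assert ("Ta", "Sex") in selected.spec.fixed
        assert ("Ta",) in selected.spec.fixed and ("Sex",) in selected.spec.fixed

    def test_trace_bic_strictly_decreasing(self):
        data = _pref(seed=38, n_per_cell=4)
        full = MixedModelSpec(fixed=FULL_FIXED, random=("cohort", "timepoint"))
        _, trace = backward_select_bic(data, full)
        bics = [step["bic"] for step in trace if "bic" in step]
        assert all(b2 < b1 for b1, b2 in zip(bics, bics[1:]))


class TestPosthoc:
    def test_two_groups_adjusted_equals_unadjusted(self):
        data = _pref(seed=39, n_per_cell=4)
        fit = fit_glmm(data, MixedModelSpec(fixed=(("Td",),), random=("cohort",)))
        ph = posthoc_pairwise(fit, ["Td"])
        assert len(ph) == 1
        assert ph.p_adj.iloc[0] == ph.p_unadj.iloc[0]

    def test_adjustment_monotone(self):
        data = _pref(seed=40, n_per_cell=6)
        fit = fit_glmm(
            data, MixedModelSpec(fixed=(("Td",), ("Sex",)), random=("cohort",))
        )
        ph = posthoc_pairwise(fit, ["Td", "Sex"])
        assert (ph.p_adj >= ph.p_unadj - 1e-12).all()

    def test_null_groups_share_a_letter(self):
        data = _pref(seed=41, n_per_cell=30, preference_effects={},
                     sigma_cohort=0.0, sigma_timepoint=0.0)
        fit = fit_glmm(data, MixedModelSpec(fixed=(("Td",), ("Ta",)), random=()))
        ph = posthoc_pairwise(fit, ["Td", "Ta"])
        letters = set(ph.attrs["letters"].values())
        assert letters == {"a"}

    def test_missing_factor_rejected(self):
        data = _pref(seed=42)
        fit = fit_glmm(data, MixedModelSpec(fixed=(("Td",),), random=()))
        with pytest.raises(ValueError, match="not in the fitted model"):
            posthoc_pairwise(fit, ["Sex"])


class TestEvenTest:
    def test_perfectly_even(self):
        assert even_ratio_test(5, 5) == 1.0

    def test_one_sided_extreme(self):
        assert even_ratio_test(10, 0) == pytest.approx(2 * 0.5**10)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            even_ratio_test(0, 0)


class TestLmmFtests:
    def test_matches_classical_anova(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            {
                "Td": ["19"] * 10 + ["27"] * 10,
                "Ta": "27",
                "Sex": "F",
                "score": np.r_[rng.normal(0.5, 0.1, 10), rng.normal(0.7, 0.1, 10)],
            }
        )
        spec = MixedModelSpec(response="score", fixed=(("Td",),), random=(), family="gaussian")
        ft = lmm_term_ftests(data, spec)
        oracle = stats.f_oneway(data.score[:10], data.score[10:])
        assert ft.F.iloc[0] == pytest.approx(oracle.statistic, rel=1e-10)
        assert ft.p.iloc[0] == pytest.approx(oracle.pvalue, rel=1e-10)

    def test_constant_response_gives_zero_f(self):
        data = pd.DataFrame(
            {"Td": ["19"] * 6 + ["27"] * 6, "Ta": "27", "Sex": "F", "score": 0.3}
        )
        spec = MixedModelSpec(response="score", fixed=(("Td",),), random=(), family="gaussian")
        ft = lmm_term_ftests(data, spec)
        assert ft.F.iloc[0] == 0.0
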