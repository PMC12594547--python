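"""Rank tests, effect sizes and power calculations against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from dermoct.phantom import CohortDesign, generate_cohort
from dermoct.stats import (
    Comparison,
    StudyPlan,
    bonferroni,
    hedges_g,
    hodges_lehmann_paired,
    hodges_lehmann_two_sample,
    mann_whitney_u,
    minimum_detectable_difference,
    pooled_sd,
    run_study_analysis,
    sample_size_two_sample,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_p(diffs):
    """Exact two-sided p by enumerating all sign patterns of the ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(itertools.compress(ranks, signs))
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def mann_whitney_enumeration_p(x, y):
    """Exact two-sided p by enumerating all group assignments of the ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = []
    for comb in itertools.combinations(range(n1 + n2), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
    us = np.array(us)
    lower = np.mean(us <= u_obs + 1e-9)
    upper = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxonSignedRank:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_antisymmetric_pair(self):
        _, p = wilcoxon_signed_rank([-1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_warn(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank([0.0, 0.0])
        assert p == 1.0

    @pytest.mark.parametrize("n", range(3, 9))
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.normal(size=n)
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = rng.normal(size=12)
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(sps.wilcoxon(d, method="exact").pvalue, abs=1e-12)

    def test_exact_and_normal_branches_agree_at_crossover(self):
        # at n = 25 the exact enumeration and the continuity-corrected
        # normal approximation agree closely for every attainable W
        from dermoct.stats import _signed_rank_pmf

        n = 25
        pmf = _signed_rank_pmf(n)
        cdf = np.cumsum(pmf)
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        for w in range(len(pmf)):
            p_exact = min(1.0, 2.0 * min(cdf[w], 1.0 - cdf[w] + pmf[w]))
            z = max((abs(w - mu) - 0.5) / sigma, 0.0)
            p_norm = min(1.0, 2.0 * sps.norm.sf(z))
            assert abs(p_exact - p_norm) < 0.02

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        rej = sum(
            wilcoxon_signed_rank(rng.normal(size=15))[1] <= 0.05 for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07


class TestMannWhitneyU:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 5), (4, 4), (2, 6)])
    def test_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mann_whitney_enumeration_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=9)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(
                sps.mannwhitneyu(x, y, method="exact").pvalue, abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        st_.lists(st_.integers(-500, 500), min_size=6, max_size=14, unique=True),
        st_.integers(3, 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, values, n1):
        # ranks are preserved by any strictly increasing map, so U and p
        # are unchanged (values kept globally unique to avoid new ties)
        n1 = min(n1, len(values) - 3)
        x, y = values[:n1], values[n1:]
        u1, p1 = mann_whitney_u(x, y)
        fx = [v**3 / 1e4 for v in x]
        fy = [v**3 / 1e4 for v in y]
        u2, p2 = mann_whitney_u(fx, fy)
        assert u1 == pytest.approx(u2)
        assert p1 == pytest.approx(p2)


class TestBonferroni:
    def test_scaling_and_clipping(self):
        out = bonferroni([0.01, 0.5], m=6)
        assert out[0] == pytest.approx(0.06)
        assert out[1] == 1.0

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestHodgesLehmann:
    def test_two_sample_enumeration(self):
        # pairwise differences of y={3,5} minus x={1,2}: {1,2,3,4} -> median 2.5
        res = hodges_lehmann_two_sample([1.0, 2.0], [3.0, 5.0])
        assert res.estimate == pytest.approx(2.5)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=10), rng.normal(size=10)
        base = hodges_lehmann_two_sample(x, y)
        shifted = hodges_lehmann_two_sample(x, y + 3.5)
        assert shifted.estimate == pytest.approx(base.estimate + 3.5)
        assert shifted.ci_low == pytest.approx(base.ci_low + 3.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=8), rng.normal(size=9)
        ab = hodges_lehmann_two_sample(x, y)
        ba = hodges_lehmann_two_sample(y, x)
        assert ab.estimate == pytest.approx(-ba.estimate)
        assert ab.ci_low == pytest.approx(-ba.ci_high)
        assert ab.ci_high == pytest.approx(-ba.ci_low)

    def test_ci_coverage_near_nominal(self):
        cover = 0
        n_rep = 400
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            res = hodges_lehmann_two_sample(
                rng.normal(size=15), rng.normal(loc=1.0, size=15)
            )
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert 0.92 <= cover / n_rep <= 0.98

    def test_paired_walsh_median(self):
        # Walsh averages of {1, 3}: {1, 2, 3} -> median 2
        res = hodges_lehmann_paired([1.0, 3.0])
        assert res.estimate == pytest.approx(2.0)

    def test_tiny_sample_warns_widest_interval(self):
        with pytest.warns(UserWarning):
            res = hodges_lehmann_paired([1.0, 2.0], conf=0.99)
        assert res.ci_low <= res.estimate <= res.ci_high


class TestEffectSizeAndPower:
    def test_pilot_summary_effect_size(self):
        assert hedges_g(1.6, 0.3, 6, 1.2, 0.2, 6) == pytest.approx(1.45, abs=0.005)

    def test_equal_means_zero(self):
        assert hedges_g(1.0, 0.3, 6, 1.0, 0.2, 6) == 0.0

    def test_correction_vanishes_asymptotically(self):
        d_like = hedges_g(1.0, 1.0, 100000, 0.0, 1.0, 100000)
        assert d_like == pytest.approx(1.0, rel=1e-4)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(1.0, 0.0, 6, 2.0, 0.0, 6)

    def test_sample_size_at_pilot_effect(self):
        g = hedges_g(1.6, 0.3, 6, 1.2, 0.2, 6)
        assert sample_size_two_sample(g) == 8

    def test_sample_size_moderate_effect(self):
        assert sample_size_two_sample(0.5) == 63

    def test_sample_size_large_effect_limit(self):
        assert sample_size_two_sample(50.0) == 1

    def test_nct_solver_close_to_normal(self):
        g = hedges_g(1.6, 0.3, 6, 1.2, 0.2, 6)
        n_norm = sample_size_two_sample(g, method="normal")
        n_nct = sample_size_two_sample(g, method="nct")
        assert n_norm <= n_nct <= n_norm + 2

    def test_minimum_detectable_difference_printed_values(self):
        sd = pooled_sd(0.3, 6, 0.2, 6)
        mdd = minimum_detectable_difference(15, sd)
        assert round(mdd, 2) == 0.26
        assert mdd / 1.6 == pytest.approx(0.16, abs=0.01)

    def test_mdd_vanishes_with_sd(self):
        assert minimum_detectable_difference(15, 1e-9) < 1e-8


class TestStudyAnalysis:
    def _cohort(self, seed=0, shift=0.0, n=8):
        cells = {}
        for g in ("G1", "G2"):
            for d in (0, 28):
                mean = 1.2 + (shift if (g == "G2" and d == 28) else 0.0)
                cells[(g, "velocity_m_s", d)] = (mean, 0.2)
        design = CohortDesign(
            groups=("G1", "G2"), n_per_group=n, days=(0, 28),
            sites=("top", "bottom"), cell_means=cells,
        )
        return generate_cohort(design, seed=seed)

    def test_single_cell_plan_single_row(self):
        plan = StudyPlan(
            comparisons=(
                Comparison(metric="velocity_m_s", kind="paired_days",
                           group="G1", days=(0, 28)),
            )
        )
        out = run_study_analysis(self._cohort(), plan)
        assert len(out) == 1
        assert out.iloc[0].method == "wilcoxon_signed_rank"

    def test_detects_strong_shift(self):
        plan = StudyPlan.within_groups("velocity_m_s", ("G1", "G2"))
        out = run_study_analysis(self._cohort(seed=3, shift=1.6, n=15), plan)
        g2 = out[out.comparison.str.contains("G2")].iloc[0]
        g1 = out[out.comparison.str.contains("G1")].iloc[0]
        assert g2.p_adjusted < 0.05
        assert g2.hl_estimate == pytest.approx(1.6, abs=0.35)
        assert g1.p_adjusted > 0.05

    def test_between_groups_hl_direction(self):
        plan = StudyPlan.between_groups("velocity_m_s", [("G1", "G2")], day=28)
        out = run_study_analysis(self._cohort(seed=4, shift=1.0, n=12), plan)
        assert out.iloc[0].hl_estimate > 0  # G2 minus G1

    def test_familywise_error_controlled_under_null(self):
        hits = 0
        n_rep = 150
        for i in range(n_rep):
            plan = StudyPlan.within_groups("velocity_m_s", ("G1", "G2"))
            out = run_study_analysis(self._cohort(seed=5000 + i), plan)
            hits += (out.p_adjusted < 0.05).any()
        assert hits / n_rep <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_missing_pairs_marked_not_raised(self):
        cohort = self._cohort()
        cohort = cohort[~((cohort.group == "G2") & (cohort.day == 28))]
        plan = StudyPlan.within_groups("velocity_m_s", ("G1", "G2"))
        out = run_study_analysis(cohort, plan)
        g2 = out[out.comparison.str.contains("G2")].iloc[0]
        assert g2.note == "missing pairs"
        assert np.isnan(g2.p_raw) or g2.p_raw is None

    def test_duplicate_records_rejected(self):
        import pandas as pd

        cohort = self._cohort()
        doubled = pd.concat([cohort, cohort.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            run_study_analysis(doubled, StudyPlan.within_groups("velocity_m_s", ("G1",)))

    def test_reproducible(self):
        plan = StudyPlan.within_groups("velocity_m_s", ("G1", "G2"))
        a = run_study_analysis(self._cohort(seed=77), plan)
        b = run_study_analysis(self._cohort(seed=77), plan)
        assert a.equals(b)
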