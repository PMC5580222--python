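"""Statistics primitives against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from radr.datatypes import SurvivalRecord
from radr.errors import ValidationError
from radr.stats import (
    adjust_pvalues,
    anova_group_effect,
    cox_fit,
    kaplan_meier,
    kruskal_wallis,
    logrank_test,
    mann_whitney,
    paired_wilcoxon,
    pearson,
)


def signed_rank_enumeration_p(diffs):
    """Oracle: exact two-sided p by enumerating all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(diffs))
    observed = ranks[diffs > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.array(stats)
    p_le = np.mean(stats <= observed + 1e-9)
    p_ge = np.mean(stats >= observed - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = paired_wilcoxon([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0 and res.statistic == 0.0 and res.degenerate

    def test_extreme_shift_matches_enumeration(self):
        a = np.arange(1.0, 7.0)
        b = a + 10
        res = paired_wilcoxon(a, b)
        assert res.p_value == pytest.approx(signed_rank_enumeration_p(a - b))
        # all 6 differences tied at -10: most extreme assignment, p = 2/2^6
        assert res.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_sample_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.8, 1, 10)
        b = rng.normal(0, 1, 10)
        res = paired_wilcoxon(a, b)
        assert res.p_value == pytest.approx(signed_rank_enumeration_p(a - b))

    def test_normal_approx_close_to_exact_at_n30(self):
        # above the exact switch point; compare against the enumeration-grade
        # exact distribution computed here by convolution (independent route)
        rng = np.random.default_rng(5)
        d = rng.normal(0.45, 1, 30)
        ranks = sps.rankdata(np.abs(d))
        doubled = np.rint(2 * ranks).astype(int)
        dist = np.array([1.0])
        for r in doubled:
            new = np.zeros(dist.size + r)
            new[: dist.size] += dist
            new[r:] += dist
            dist = new
        dist /= dist.sum()
        t2 = int(round(2 * ranks[d > 0].sum()))
        exact = min(1.0, 2 * min(dist[: t2 + 1].sum(), dist[t2:].sum()))
        res = paired_wilcoxon(d + 1, np.ones_like(d))
        assert res.p_value == pytest.approx(exact, rel=0.10)

    def test_missing_pairs_dropped(self):
        res = paired_wilcoxon([1, 2, np.nan, 4], [0, 1, 5, np.nan])
        assert res.statistic >= 0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1], [2])


class TestMannWhitney:
    def test_identical_values_degenerate(self):
        res = mann_whitney([2, 2, 2], [2, 2])
        assert res.p_value == 1.0 and res.degenerate

    def test_exact_enumeration_small(self):
        # all C(4,2)=6 rank arrangements; U=0 is one of two extremes
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(1, 1, 5)
        assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(b, a).p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_consistent_with_mann_whitney(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(0.5, 1, 12)
        kw = kruskal_wallis([a, b])
        mw = mann_whitney(a, b)
        assert kw.p_value == pytest.approx(mw.p_value, rel=0.15)

    def test_hand_computed_h(self):
        # ranks: a={1,2}, b={3,4}, c={5,6}; no ties
        groups = [[10, 20], [30, 40], [50, 60]]
        n, k = 6, 3
        rank_sums = [3, 7, 11]
        h = 12 / (n * (n + 1)) * sum(rs**2 / 2 for rs in rank_sums) - 3 * (n + 1)
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])


class TestAnovaGroupEffect:
    def test_constant_values_degenerate(self):
        res = anova_group_effect([5.0] * 8, ["a", "a", "b", "b"] * 2,
                                 ["x", "y"] * 4)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_group_degenerate(self):
        res = anova_group_effect([1, 2, 3, 4], ["a"] * 4, ["x", "y", "x", "y"])
        assert res.p_value == 1.0

    def test_matches_closed_form_sums_of_squares(self):
        # balanced 2x2 design, 4 per cell: group shift 2.0, block shift 0.5
        rng = np.random.default_rng(11)
        rows = []
        for g in (0, 1):
            for b in (0, 1):
                for _ in range(4):
                    rows.append((2.0 * g + 0.5 * b + rng.normal(0, 0.3), g, b))
        y = np.array([r[0] for r in rows])
        g = np.array([r[1] for r in rows])
        b = np.array([r[2] for r in rows])
        # oracle: explicit type-II SS in a balanced additive design
        n = y.size
        grand = y.mean()
        ss_group = sum((y[g == lv].mean() - grand) ** 2 * (g == lv).sum()
                       for lv in (0, 1))
        ss_block = sum((y[b == lv].mean() - grand) ** 2 * (b == lv).sum()
                       for lv in (0, 1))
        ss_tot = ((y - grand) ** 2).sum()
        ss_res = ss_tot - ss_group - ss_block
        f_oracle = (ss_group / 1) / (ss_res / (n - 3))
        res = anova_group_effect(y, g, b)
        assert res.statistic == pytest.approx(f_oracle)
        assert res.p_value == pytest.approx(float(sps.f.sf(f_oracle, 1, n - 3)))

    def test_block_level_renaming_invariance(self):
        rng = np.random.default_rng(4)
        g = np.repeat([0, 1], 6)
        b = np.tile([0, 1, 2], 4)
        y = rng.normal(size=12) + g * 1.5
        base = anova_group_effect(y, g, b).statistic
        # renaming the block levels (bijection) must not change the group F
        renamed = np.array([{0: 2, 1: 0, 2: 1}[v] for v in b])
        assert anova_group_effect(y, g, renamed).statistic == pytest.approx(base)

    def test_interaction_option_runs(self):
        rng = np.random.default_rng(9)
        g = np.repeat([0, 1], 6)
        b = np.tile([0, 1], 6)
        y = rng.normal(size=12)
        res = anova_group_effect(y, g, b, interaction=True)
        assert 0 <= res.p_value <= 1


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson(x, y).statistic == pytest.approx(r_oracle)

    def test_zero_variance_degenerate(self):
        res = pearson([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.degenerate and res.p_value == 1.0


class TestAdjustPvalues:
    def test_single_unchanged(self):
        assert adjust_pvalues([0.03]) == [0.03]

    def test_holm_hand_computed(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "holm") == pytest.approx(
            [0.03, 0.04, 0.04])

    def test_all_ones(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
           st.sampled_from(["holm", "bh"]))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_capped(self, pvals, method):
        adj = adjust_pvalues(pvals, method)
        for raw, a in zip(pvals, adj):
            assert raw <= a + 1e-12
            assert a <= 1.0

    def test_bh_hand_computed(self):
        # sorted p (0.01, 0.04, 0.03): bh = min over j>=i of m/j p_(j)
        assert adjust_pvalues([0.01, 0.04, 0.03], "bh") == pytest.approx(
            [0.03, 0.04, 0.04])


def _records(times, events, **kw):
    return [SurvivalRecord(f"S{i}", t, e, **kw)
            for i, (t, e) in enumerate(zip(times, events))]


def cox_partial_loglik(beta, times, events, x):
    """Oracle: Cox partial log-likelihood, no ties (Breslow = Efron)."""
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCoxFit:
    def test_tiny_dataset_matches_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        fit = cox_fit(_records(times, events), {"x": x})
        grid = np.arange(-5, 5, 1e-4)
        lls = [cox_partial_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.coefficients["x"] == pytest.approx(best, abs=2e-4)

    def test_null_covariate_within_2se(self):
        rng = np.random.default_rng(42)
        n = 300
        times = rng.exponential(10, n)
        events = np.ones(n, dtype=int)
        x = rng.normal(size=n)
        fit = cox_fit(_records(times, events), {"x": x})
        assert abs(fit.coefficients["x"]) < 2 * fit.standard_errors["x"]

    def test_reparameterization_consistency(self):
        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.5 * x))
        events = np.ones(n, dtype=int)
        f1 = cox_fit(_records(times, events), {"x": x})
        f2 = cox_fit(_records(times, events), {"x": 10 * x})
        assert f1.coefficients["x"] == pytest.approx(10 * f2.coefficients["x"],
                                                     abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit(_records([1, 2, 3], [0, 0, 0]), {"x": [1, 2, 3]})

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(_records([1, 2, 3, 4], [1, 1, 0, 1]), {"x": [2, 2, 2, 2]})

    def test_collinear_covariates_rejected(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValidationError, match="collinear"):
            cox_fit(_records([1, 2, 3, 4], [1, 1, 1, 0]),
                    {"x": x, "y": [2 * v for v in x]})


class TestKaplanMeier:
    def test_all_censored_flat(self):
        km = kaplan_meier(_records([3, 5, 7], [0, 0, 0]))
        assert km(10) == 1.0

    def test_product_limit_by_hand(self):
        km = kaplan_meier(_records([1, 2], [1, 1]))
        assert km(0.5) == 1.0
        assert km(1) == pytest.approx(0.5)
        assert km(2) == pytest.approx(0.0)

    def test_censoring_no_step(self):
        # event at 1 (n=3 at risk), censor at 2, event at 3 (1 at risk)
        km = kaplan_meier(_records([1, 2, 3], [1, 0, 1]))
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(2 / 3)
        assert km(3) == pytest.approx(0.0)

    def test_order_invariance(self):
        recs = _records([5, 1, 3, 2, 4], [1, 0, 1, 1, 0])
        km1 = kaplan_meier(recs)
        km2 = kaplan_meier(recs[::-1])
        grid = np.linspace(0, 6, 20)
        assert np.allclose(km1(grid), km2(grid))


class TestLogrank:
    def test_identical_groups(self):
        recs = _records([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        res = logrank_test(recs, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_observed_expected(self):
        # groups a={1,3}, b={2,4}, all events, distinct times
        recs = _records([1, 3, 2, 4], [1, 1, 1, 1])
        labels = ["a", "a", "b", "b"]
        # oracle: O-E and variance accumulated at each event time
        times = np.array([1, 3, 2, 4]); group_a = np.array([1, 1, 0, 0])
        events_order = np.argsort(times)
        o_minus_e, var = 0.0, 0.0
        for idx in events_order:
            at_risk = times >= times[idx]
            n, n_a = at_risk.sum(), group_a[at_risk].sum()
            o_minus_e += group_a[idx] - n_a / n
            if n > 1:
                var += (n_a / n) * (1 - n_a / n)
        chi2 = o_minus_e**2 / var
        res = logrank_test(recs, labels)
        assert res.statistic == pytest.approx(chi2)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        recs = _records(rng.exponential(5, 20), rng.integers(0, 2, 20) | 1)
        labels = ["a"] * 10 + ["b"] * 10
        swapped = ["b" if l == "a" else "a" for l in labels]
        assert logrank_test(recs, labels).p_value == pytest.approx(
            logrank_test(recs, swapped).p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_records([1, 2], [1, 1]), ["a", "a"])


class TestRankInvariance:
    """Rank tests are invariant under strictly increasing transforms."""

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(0.5, 1, 8)
        t = lambda v: np.exp(3 * np.asarray(v))  # strictly increasing
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(t(a), t(b)).p_value)
        assert kruskal_wallis([a, b]).p_value == pytest.approx(
            kruskal_wallis([t(a), t(b)]).p_value)
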