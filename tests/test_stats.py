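import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timeprox import (bh_adjust, cox_fit, km_logrank, kruskal_dunn,
                      mann_whitney, roc_auc, screened_multivariate)
from timeprox.errors import StatisticalDegeneracyError


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        # U = 0; 2/20 arrangements as extreme -> two-sided p = 0.1
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "exact"

    def test_identical_multisets_p_one(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_constant_data(self):
        r = mann_whitney([5, 5, 5], [5, 5])
        assert r.p_value == 1.0
        assert r.degenerate

    def test_switches_to_asymptotic(self):
        rng = np.random.default_rng(0)
        r = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert r.method == "asymptotic"

    def test_direction_reports_larger_median_group(self):
        r = mann_whitney([10, 11, 12], [1, 2, 3], group_names=("hi", "lo"))
        assert r.direction == "hi"

    def test_empty_group_rejected(self):
        with pytest.raises(StatisticalDegeneracyError):
            mann_whitney([], [1.0])


class TestBH:
    def test_textbook_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_repeated_p_rank_m_of_m(self):
        assert bh_adjust([0.5] * 6) == pytest.approx([0.5] * 6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=30))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestKruskalDunn:
    def test_extreme_pair_has_smallest_p(self):
        r = kruskal_dunn([[1, 2], [3, 4], [5, 6]], names=["a", "b", "c"])
        pw = r.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_value"] == pw["p_value"].min()
        assert r.direction == "c"

    def test_identical_groups_h_zero(self):
        r = kruskal_dunn([[1, 2], [1, 2], [1, 2]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_degenerate(self):
        r = kruskal_dunn([[3, 3], [3, 3], [3, 3]])
        assert r.degenerate and r.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatisticalDegeneracyError):
            kruskal_dunn([[1, 2], [], [3]])

    def test_two_groups_rejected(self):
        with pytest.raises(StatisticalDegeneracyError):
            kruskal_dunn([[1], [2]])


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 4], [False, False, True, True])
        assert r.auc == 1.0

    def test_identical_distributions_half(self):
        r = roc_auc([1, 1, 1, 1], [True, False, True, False])
        assert r.auc == 0.5

    def test_tie_half_credit_example(self):
        # responders {2,3}, non-responders {1,2}: 3 wins + 1 tie of 4 pairs
        r = roc_auc([1, 2, 2, 3], [False, False, True, True])
        assert r.auc == pytest.approx(0.875)

    def test_u_statistic_duality(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=60)
        flags = rng.random(60) < 0.4
        u = mann_whitney(vals[flags], vals[~flags]).statistic
        r = roc_auc(vals, flags)
        assert r.auc == pytest.approx(u / (r.n_positive * r.n_negative), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.1, 10, size=40)
        flags = rng.random(40) < 0.5
        if flags.all() or not flags.any():
            flags[0] = ~flags[0]
        assert roc_auc(np.log(vals), flags).auc == roc_auc(vals, flags).auc

    def test_missing_dropped_pairwise(self):
        r = roc_auc([1, 2, np.nan, 4], [False, False, True, True])
        assert r.n_positive == 1 and r.n_negative == 2

    def test_one_class_empty_rejected(self):
        with pytest.raises(StatisticalDegeneracyError):
            roc_auc([1, 2], [True, True])


class TestKMLogrank:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_logrank([1, 2, 3, 4], [1, 1, 1, 1], ["a"] * 4)
        curve = km.curves["a"]
        assert curve["survival"].tolist() == pytest.approx([1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flagged(self):
        km = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert km.flagged and np.isnan(km.p_value)
        assert (km.curves["a"]["survival"] == 1.0).all()

    def test_identical_groups_p_one(self):
        t = [1, 2, 3, 4, 5] * 2
        km = km_logrank(t, [1] * 10, ["a"] * 5 + ["b"] * 5)
        assert km.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # A fails at t=1 (both at risk: E=0.5, V=0.25), B fails alone at t=2
        # chi2 = (1 - 0.5)^2 / 0.25 = 1.0
        km = km_logrank([1, 2], [1, 1], ["A", "B"])
        assert km.statistic == pytest.approx(1.0)

    def test_single_group_flagged(self):
        km = km_logrank([1, 2], [1, 1], np.array(["a", "a"]))
        assert km.flagged and np.isnan(km.p_value)


def _ph_data(rng, n, beta, cens_scale=2.0):
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1 / np.exp(beta * x))
    c = rng.exponential(cens_scale, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestCox:
    def test_agrees_with_lifelines_efron(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(5)
        n = 250
        X = pd.DataFrame({"a": rng.normal(size=n),
                          "b": rng.binomial(1, 0.4, n).astype(float)})
        t = np.round(rng.exponential(1 / np.exp(0.6 * X["a"] - 0.5 * X["b"])), 1)
        c = rng.exponential(2.0, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        mine = cox_fit(times, events, X, ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": times, "e": events, **X}), "t", "e")
        assert mine.summary["coef"].to_numpy() == pytest.approx(
            cph.params_.to_numpy(), abs=1e-5)
        assert mine.summary["se"].to_numpy() == pytest.approx(
            cph.standard_errors_.to_numpy(), abs=1e-5)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(6)
        times, events, x = _ph_data(rng, 150, 0.7)
        rb = cox_fit(times, events, x[:, None], ties="breslow")
        re = cox_fit(times, events, x[:, None], ties="efron")
        assert rb.summary["coef"].iloc[0] == pytest.approx(
            re.summary["coef"].iloc[0], abs=1e-9)

    def test_recovers_planted_hr(self):
        rng = np.random.default_rng(7)
        times, events, x = _ph_data(rng, 800, np.log(2.0))
        r = cox_fit(times, events, x[:, None])
        assert r.converged
        assert 1.6 < r.hr() < 2.5
        assert r.summary["ci_lower"].iloc[0] < r.hr() < r.summary["ci_upper"].iloc[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(StatisticalDegeneracyError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 1], np.zeros((3, 1)))

    def test_too_few_events_rejected(self):
        with pytest.raises(StatisticalDegeneracyError, match="events"):
            cox_fit([1, 2, 3], [1, 0, 0], np.array([[1.0], [2.0], [0.5]]))

    def test_complete_separation_flagged(self):
        # covariate perfectly orders the event times -> monotone likelihood
        t = np.arange(1.0, 21.0)
        x = t[::-1].copy()
        r = cox_fit(t, np.ones(20, int), x[:, None])
        assert r.flagged


class TestScreenedCox:
    def test_null_covariate_screened_out(self):
        kept_null = 0
        dropped_strong = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 150
            strong = rng.binomial(1, 0.5, n).astype(float)
            null = rng.normal(size=n)
            t = rng.exponential(1 / np.exp(np.log(3.0) * strong))
            c = rng.exponential(2.0, n)
            res = screened_multivariate(
                np.minimum(t, c), (t <= c).astype(int),
                pd.DataFrame({"strong": strong, "null": null}))
            kept_null += "null" in res.retained
            dropped_strong += "strong" not in res.retained
        assert dropped_strong <= 2       # the planted effect survives the screen
        assert kept_null <= 5            # ~alpha = 0.1 false-inclusion rate

    def test_empty_retained_set_flagged(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(1.0, 120)
        c = rng.exponential(2.0, 120)
        res = screened_multivariate(
            np.minimum(t, c), (t <= c).astype(int),
            pd.DataFrame({"u": rng.normal(size=120), "v": rng.normal(size=120)}))
        assert res.retained == []
        assert res.flagged and res.multivariate is None
        assert len(res.univariate) == 2  # univariate stage still reported

    def test_single_strong_candidate_multivariate_equals_univariate(self):
        rng = np.random.default_rng(9)
        times, events, x = _ph_data(rng, 200, np.log(2.5))
        res = screened_multivariate(times, events, pd.DataFrame({"x": x}))
        assert res.retained == ["x"]
        uni = res.univariate.set_index("covariate").loc["x", "coef"]
        assert res.multivariate.summary["coef"].iloc[0] == pytest.approx(uni)


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=20, derandomize=True)
def test_auc_mann_whitney_duality_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    vals = np.round(rng.normal(size=n), 1)  # ties likely
    flags = rng.random(n) < 0.5
    if flags.all() or not flags.any():
        flags[0] = ~flags[0]
    u = mann_whitney(vals[flags], vals[~flags]).statistic
    r = roc_auc(vals, flags)
    assert r.auc == pytest.approx(u / (r.n_positive * r.n_negative), abs=1e-12)
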