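"""Threshold selection, product-limit estimation, log-rank, stratification."""

import numpy as np
import pytest

from svdstrat.survival import (
    kaplan_meier,
    logrank_test,
    stratified_analysis,
    threshold_select,
)


class TestThresholdSelect:
    def test_perfectly_separated_marker(self):
        marker = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        outcome = np.array([False, False, False, True, True, True])
        rep = threshold_select(marker, outcome, grid=np.arange(0.0, 10.5, 0.5))
        assert rep.selected_j == pytest.approx(1.0)
        assert 3.0 < rep.selected <= 7.0
        # smallest threshold in the gap wins the tie
        assert rep.selected == 3.5

    def test_eight_point_fixture_matches_exhaustive_counting(self):
        marker = np.arange(1.0, 9.0)
        outcome = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=bool)
        grid = np.arange(1.0, 9.0)
        rep = threshold_select(marker, outcome, grid)
        for gi, thr in enumerate(grid):
            sens = sum(1 for m, o in zip(marker, outcome) if o and m >= thr) / 4
            spec = sum(1 for m, o in zip(marker, outcome) if not o and m < thr) / 4
            assert rep.sensitivity[gi] == pytest.approx(sens)
            assert rep.specificity[gi] == pytest.approx(spec)

    def test_sens_decreases_spec_increases_with_threshold(self, rng):
        marker = rng.random(50) * 10
        outcome = rng.random(50) > 0.5
        rep = threshold_select(marker, outcome, np.linspace(0, 10, 21))
        assert (np.diff(rep.sensitivity) <= 1e-12).all()
        assert (np.diff(rep.specificity) >= -1e-12).all()

    def test_independent_marker_has_near_zero_j(self, rng):
        marker = rng.random(4000)
        outcome = rng.random(4000) > 0.7
        rep = threshold_select(marker, outcome, np.linspace(0.05, 0.95, 19))
        assert rep.selected_j < 0.08

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            threshold_select([1.0, 1.0, 1.0], [True, False, True])


class TestKaplanMeier:
    def test_uncensored_events_closed_form(self):
        curve = kaplan_meier([1.0, 2.0, 3.0, 4.0], [True] * 4)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2.0

    def test_all_censored_is_flat_with_undefined_median(self):
        curve = kaplan_meier([1.0, 2.0, 3.0], [False] * 3)
        assert (curve.survival == 1.0).all()
        assert np.isnan(curve.median)

    def test_mixed_censoring_fixture_matches_hand_computation(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, False, True, False, True, True]
        curve = kaplan_meier(times, events)
        # hand product-limit: S(1)=5/6, S(3)=5/6*3/4, S(5)=.../2, S(6)=0
        expected = {1.0: 5 / 6, 3.0: 5 / 6 * 3 / 4, 5.0: 5 / 6 * 3 / 4 * 1 / 2, 6.0: 0.0}
        for t, s in expected.items():
            assert curve.at(t) == pytest.approx(s, abs=1e-10)
        assert curve.median == 5.0

    def test_uncensored_km_equals_empirical_survival(self, rng):
        t = rng.exponential(2.0, 50)
        curve = kaplan_meier(t, np.ones(50, dtype=bool))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert curve.at(q) == pytest.approx((t > q).mean(), abs=1e-10)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [True, True])


def _hand_logrank_two_groups(times, events, groups):
    """Event-by-event hypergeometric O-E computation (oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g1 = np.asarray(groups) == np.asarray(groups)[0]
    O1 = E1 = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [True] * 8
        g = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_ten_subject_fixture_matches_hand_computation(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        e = [True] * 10
        g = ["a"] * 5 + ["b"] * 5
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(_hand_logrank_two_groups(t, e, g), abs=1e-10)

    def test_invariant_to_group_label_swap(self, rng):
        t = rng.exponential(3.0, 30)
        e = rng.random(30) > 0.3
        g = np.where(rng.random(30) > 0.5, "a", "b")
        if not e.any():
            e[0] = True
        chi2_1, _ = logrank_test(t, e, g)
        swap = np.where(g == "a", "b", "a")
        chi2_2, _ = logrank_test(t, e, swap)
        assert chi2_1 == pytest.approx(chi2_2, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [True, True], ["a", "a"])


class TestStratifiedAnalysis:
    def test_event_free_negative_strata_have_zero_conversion(self):
        # all convertors predicted positive: both negative strata are
        # censoring-only and their 5-year conversion probability is 0
        pred = np.array([True] * 6 + [False] * 6)
        svdp = np.array([5.0, 5.0, 5.0, 2.0, 2.0, 2.0] * 2)
        times = np.array([1.0, 2.0, 1.5, 2.5, 3.0, 1.2] + [5.0] * 6)
        flags = np.array([True] * 6 + [False] * 6)
        out = stratified_analysis(pred, svdp, 4.0, times, flags)
        assert out["conversion_5y"]["negative/high-burden"] == 0.0
        assert out["conversion_5y"]["negative/low-burden"] == 0.0
        assert out["conversion_5y"]["positive/high-burden"] == 1.0

    def test_threshold_at_marker_maximum_leaves_empty_stratum(self):
        pred = np.array([True, True, False, False])
        svdp = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([1.0, 2.0, 5.0, 5.0])
        flags = np.array([True, True, False, False])
        with pytest.warns(UserWarning, match="empty stratum"):
            out = stratified_analysis(pred, svdp, 4.0, times, flags)
        assert np.isnan(out["conversion_5y"]["positive/high-burden"])

    def test_planted_hazard_ordering_recovered_at_n2000(self, rng):
        hazards = {
            ("positive", "high"): 0.5, ("positive", "low"): 0.3,
            ("negative", "high"): 0.12, ("negative", "low"): 0.04,
        }
        pred, svdp, times, flags = [], [], [], []
        for (p_, b), h in hazards.items():
            n = 500
            t = rng.exponential(1 / h, n)
            event = t <= 5.0
            times.append(np.where(event, t, 5.0))
            flags.append(event)
            pred.append(np.full(n, p_ == "positive"))
            svdp.append(np.full(n, 6.0 if b == "high" else 2.0))
        out = stratified_analysis(np.concatenate(pred), np.concatenate(svdp), 4.0,
                                  np.concatenate(times), np.concatenate(flags))
        c = out["conversion_5y"]
        assert c["positive/high-burden"] > c["positive/low-burden"] > \
            c["negative/high-burden"] > c["negative/low-burden"]

    def test_threshold_outside_marker_range_rejected(self):
        with pytest.raises(ValueError):
            stratified_analysis([True, False], [1.0, 2.0], 9.0,
                                [1.0, 2.0], [True, False])


def test_km_median_converges_to_exponential_median(rng):
    lam = 0.3
    t = rng.exponential(1 / lam, 2000)
    event = t <= 5.0
    curve = kaplan_meier(np.where(event, t, 5.0), event)
    assert curve.median == pytest.approx(np.log(2) / lam, rel=0.05)
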