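"""Response classification, CR rates, Kaplan-Meier and log-rank."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from rptdose import (
    KMCurve,
    ResponseCall,
    SurvivalDataset,
    TumorGrowthRecord,
    classify_response,
    cr_rate,
    kaplan_meier,
    logrank_test,
    survival_summary,
)


def _rec(times, volumes, aid="m1", group="g"):
    return TumorGrowthRecord(aid, group, tuple(times), tuple(volumes), end_of_study_d=times[-1])


class TestClassifyResponse:
    def test_progression_with_interpolated_crossing(self):
        rec = _rec([0, 3, 6, 9], [200, 450, 800, 1200])
        call = classify_response(rec, limit_mm3=1000.0)
        assert call.state == "progression"
        # crossing between 800 (day 6) and 1200 (day 9): 6 + 3*(200/400)
        assert call.limit_day == pytest.approx(7.5)

    def test_first_measurement_rule(self):
        rec = _rec([0, 3, 6, 9], [200, 450, 800, 1200])
        call = classify_response(rec, limit_mm3=1000.0, limit_rule="first_measurement")
        assert call.limit_day == pytest.approx(9.0)

    def test_complete_response_sustained_to_study_end(self):
        rec = _rec([0, 7, 14, 21, 28], [150, 60, 0, 0, 0])
        call = classify_response(rec)
        assert call.state == "complete_response"
        assert call.cr_day == pytest.approx(14.0)
        assert call.limit_day is None

    def test_regrowth_after_cr_without_limit(self):
        rec = _rec([0, 7, 14, 21, 28, 35], [150, 60, 0, 0, 80, 300])
        call = classify_response(rec)
        assert call.state == "regrowth_after_cr"
        assert call.cr_day == pytest.approx(14.0)
        assert call.limit_day is None

    def test_single_unconfirmed_zero_is_stable(self):
        rec = _rec([0, 7, 14], [150, 60, 0])
        assert classify_response(rec, confirm_n=2).state == "stable"
        assert classify_response(rec, confirm_n=1).state == "complete_response"

    def test_regrown_tumor_reaching_limit_is_progression(self):
        rec = _rec([0, 7, 14, 21, 28, 35], [150, 0, 0, 200, 700, 1400])
        call = classify_response(rec)
        assert call.state == "progression"
        assert call.cr_day == pytest.approx(7.0)
        assert call.limit_day is not None

    def test_invariant_to_post_limit_measurements(self):
        base = _rec([0, 3, 6, 9], [200, 450, 800, 1200])
        extended = _rec([0, 3, 6, 9, 12, 15], [200, 450, 800, 1200, 0, 0])
        a = classify_response(base)
        b = classify_response(extended)
        assert (a.state, a.limit_day) == (b.state, b.limit_day)

    def test_validation(self):
        with pytest.raises(ValueError):
            classify_response(_rec([0, 3], [1, 2]), limit_mm3=0.0)
        with pytest.raises(ValueError):
            classify_response(_rec([0, 3], [1, 2]), confirm_n=0)
        with pytest.raises(ValueError, match="empty"):
            TumorGrowthRecord("a", "g", (), ())


class TestCRRate:
    @pytest.mark.parametrize(
        "n_cr,n,expected",
        [(6, 8, 75.0), (4, 5, 80.0), (3, 10, 30.0), (1, 4, 25.0)],
    )
    def test_printed_group_compositions(self, n_cr, n, expected):
        calls = [ResponseCall(f"a{i}", "g", "complete_response") for i in range(n_cr)]
        calls += [
            ResponseCall(f"b{i}", "g", "regrowth_after_cr", cr_day=10.0)
            for i in range(n - n_cr)
        ]
        rate = cr_rate(calls)
        assert rate.percent == pytest.approx(expected)
        assert f"{n_cr}/{n}" in str(rate)

    def test_adding_progression_strictly_decreases(self):
        calls = [ResponseCall("a", "g", "complete_response")]
        before = cr_rate(calls).fraction
        calls.append(ResponseCall("b", "g", "progression", limit_day=5.0))
        assert cr_rate(calls).fraction < before

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            cr_rate([])


def _surv(rows):
    return SurvivalDataset(tuple((f"a{i}", g, float(t), int(e)) for i, (g, t, e) in enumerate(rows)))


class TestKaplanMeier:
    def test_all_censored(self):
        km = kaplan_meier(_surv([("g", 10, 0), ("g", 12, 0)]), "g")
        assert np.allclose(km.survival, 1.0)
        assert km.median_d is None and not km.median_defined

    def test_hand_product_limit(self):
        km = kaplan_meier(_surv([("g", 5, 1), ("g", 7, 1), ("g", 10, 0), ("g", 12, 0)]), "g")
        assert km.survival_at(4.9) == pytest.approx(1.0)
        assert km.survival_at(5.0) == pytest.approx(0.75)
        assert km.survival_at(7.0) == pytest.approx(0.5)
        assert km.median_d == pytest.approx(7.0)

    def test_ties_aggregate_like_sequential_processing(self):
        # S after a tied death time equals the product-limit value computed
        # by brute force over unique times
        rows = [("g", 5, 1), ("g", 5, 1), ("g", 8, 1), ("g", 9, 0), ("g", 11, 1)]
        km = kaplan_meier(_surv(rows), "g")
        times = np.array([t for _, t, _ in rows], dtype=float)
        events = np.array([e for _, _, e in rows])
        s = 1.0
        expected = {}
        for t in np.unique(times[events == 1]):
            n_i = (times >= t).sum()
            d_i = ((times == t) & (events == 1)).sum()
            s *= 1 - d_i / n_i
            expected[t] = s
        for t, sv in expected.items():
            assert km.survival_at(t) == pytest.approx(sv, rel=1e-12)

    @given(
        times=st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=12)
    )
    def test_equals_empirical_survival_without_censoring(self, times):
        rows = [("g", t, 1) for t in times]
        km = kaplan_meier(_surv(rows), "g")
        arr = np.asarray(times, dtype=float)
        for t in np.unique(arr):
            empirical = (arr > t).mean()
            assert km.survival_at(float(t)) == pytest.approx(empirical, abs=1e-12)


def _brute_force_logrank(ta, ea, tb, eb):
    """O/E/V tabulation over shared risk sets, aggregated ties."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return chi2, float(chi2_dist.sf(chi2, 1))


class TestLogrank:
    def test_identical_groups(self):
        rows = [("a", 5, 1), ("a", 8, 1), ("a", 10, 0), ("b", 5, 1), ("b", 8, 1), ("b", 10, 0)]
        res = logrank_test(_surv(rows), "a", "b")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_tabulation(self):
        ta, ea = np.array([3.0, 6.0, 9.0]), np.array([1, 1, 0])
        tb, eb = np.array([4.0, 8.0, 12.0]), np.array([1, 1, 1])
        rows = [("a", t, e) for t, e in zip(ta, ea)] + [("b", t, e) for t, e in zip(tb, eb)]
        res = logrank_test(_surv(rows), "a", "b")
        chi2, p = _brute_force_logrank(ta, ea, tb, eb)
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_matches_brute_force_with_ties(self):
        ta, ea = np.array([3.0, 3.0, 7.0, 9.0]), np.array([1, 1, 1, 0])
        tb, eb = np.array([3.0, 8.0, 8.0, 12.0]), np.array([1, 1, 0, 1])
        rows = [("a", t, e) for t, e in zip(ta, ea)] + [("b", t, e) for t, e in zip(tb, eb)]
        res = logrank_test(_surv(rows), "a", "b")
        chi2, _ = _brute_force_logrank(ta, ea, tb, eb)
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)

    def test_symmetric_in_group_labels(self):
        rows = [("a", 3, 1), ("a", 6, 1), ("b", 9, 1), ("b", 12, 0)]
        ab = logrank_test(_surv(rows), "a", "b")
        ba = logrank_test(_surv(rows), "b", "a")
        assert ab.chi2 == pytest.approx(ba.chi2, rel=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)

    def test_no_events_anywhere(self):
        res = logrank_test(_surv([("a", 5, 0), ("b", 6, 0)]), "a", "b")
        assert res.chi2 == 0.0 and res.p_value == 1.0


class TestSurvivalSummary:
    def _curve(self, group, median):
        if median is None:
            return KMCurve(group, (0.0, 10.0), (1.0, 0.9), (5, 5), None)
        return KMCurve(group, (0.0, median), (1.0, 0.4), (5, 5), median)

    def test_fourfold_median_increase(self):
        curves = {"treated": self._curve("treated", 68.0), "placebo": self._curve("placebo", 17.0)}
        df = survival_summary(curves, "placebo").set_index("group")
        assert df.loc["treated", "fold_vs_reference"] == pytest.approx(4.0)

    def test_reference_fold_is_one(self):
        curves = {"placebo": self._curve("placebo", 17.0)}
        df = survival_summary(curves, "placebo")
        assert df["fold_vs_reference"].iloc[0] == pytest.approx(1.0)

    def test_undefined_median_flagged_not_infinite(self):
        curves = {"treated": self._curve("treated", None), "placebo": self._curve("placebo", 17.0)}
        df = survival_summary(curves, "placebo").set_index("group")
        assert not df.loc["treated", "median_defined"]
        assert np.isnan(df.loc["treated", "fold_vs_reference"])

    def test_undefined_reference_is_an_error(self):
        curves = {"placebo": self._curve("placebo", None)}
        with pytest.raises(ValueError, match="undefined"):
            survival_summary(curves, "placebo")
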