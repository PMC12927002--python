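"""ANOVA, Dunnett post hoc, calibration fitting and QC metrics."""

import numpy as np
import pytest
import scipy.stats as sps

from corticomap import stats


class TestAnova:
    def test_worked_example(self):
        res = stats.oneway_anova([[1, 2, 3], [2, 3, 4], [5, 6, 7]])
        assert res.F == pytest.approx(13.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_zero_F(self):
        res = stats.oneway_anova([[1, 2], [1, 2], [1, 2]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        res = stats.oneway_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_shift_and_scale_invariance(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0, 1, 2)]
        base = stats.oneway_anova(groups).F
        shifted = stats.oneway_anova([g + 100 for g in groups]).F
        scaled = stats.oneway_anova([g * 7.5 for g in groups]).F
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            stats.oneway_anova([[1.0], [1, 2]])


class TestDunnett:
    def test_identical_treatment_near_one(self, rng):
        ctrl = rng.normal(0, 1, 6)
        res = stats.dunnett([ctrl.copy()], ctrl)
        assert res.comparisons[0].p_adjusted > 0.99

    def test_single_comparison_reduces_to_t_test(self, rng):
        g1, g0 = rng.normal(1, 1, 6), rng.normal(0, 1, 7)
        res = stats.dunnett([g1], g0)
        t = sps.ttest_ind(g1, g0, equal_var=True)
        assert abs(res.comparisons[0].p_adjusted - t.pvalue) < 1e-6

    def test_adjusted_at_least_unadjusted(self, rng):
        ctrl = rng.normal(0, 1, 6)
        groups = [rng.normal(d, 1, 6) for d in (0.5, 1.0, 2.0)]
        res = stats.dunnett(groups, ctrl)
        for comp in res.comparisons:
            # unadjusted p from the same pooled-error t statistic
            raw = 2 * sps.t.sf(abs(comp.t), res.df)
            assert comp.p_adjusted >= raw - 1e-12

    def test_monotone_in_t(self, rng):
        ctrl = rng.normal(0, 1, 6)
        groups = [rng.normal(d, 1, 6) for d in (0.2, 0.8, 1.6)]
        res = stats.dunnett(groups, ctrl)
        order_t = np.argsort([abs(c.t) for c in res.comparisons])
        order_p = np.argsort([-c.p_adjusted for c in res.comparisons])
        np.testing.assert_array_equal(order_t, order_p)

    def test_strong_separation_significant(self, rng):
        ctrl = rng.normal(0, 1, 6)
        near = rng.normal(0, 1, 6)
        far = rng.normal(10, 1, 6)
        res = stats.dunnett([near, far], ctrl)
        assert res.comparisons[1].p_adjusted < 0.01

    def test_agrees_with_scipy(self, rng):
        ctrl = rng.normal(0, 1, 7)
        groups = [rng.normal(d, 1, n) for d, n in ((0.6, 6), (1.4, 5), (0.1, 8))]
        mine = stats.dunnett(groups, ctrl)
        ref = sps.dunnett(*groups, control=ctrl, random_state=12345)
        for comp, p_ref in zip(mine.comparisons, ref.pvalue):
            assert comp.p_adjusted == pytest.approx(p_ref, abs=5e-3)

    def test_agrees_with_monte_carlo_oracle(self, rng):
        """Adjusted p matches an empirical max-|t| null within simulation error."""
        n0, ns = 6, [6, 6]
        ctrl = rng.normal(0, 1, n0)
        groups = [rng.normal(1.2, 1, n) for n in ns]
        mine = stats.dunnett(groups, ctrl)

        n_mc = 100_000
        mc = np.random.default_rng(7)
        draws0 = mc.normal(size=(n_mc, n0))
        draws = [mc.normal(size=(n_mc, n)) for n in ns]
        ss = np.sum((draws0 - draws0.mean(1, keepdims=True)) ** 2, axis=1) + sum(
            np.sum((d - d.mean(1, keepdims=True)) ** 2, axis=1) for d in draws
        )
        df = n0 + sum(ns) - (len(ns) + 1)
        s2 = ss / df
        tmax = np.max(
            np.abs(
                np.stack(
                    [
                        (d.mean(1) - draws0.mean(1)) / np.sqrt(s2 * (1 / n + 1 / n0))
                        for d, n in zip(draws, ns)
                    ]
                )
            ),
            axis=0,
        )
        for comp in mine.comparisons:
            emp = float(np.mean(tmax >= abs(comp.t)))
            se = np.sqrt(max(emp * (1 - emp), 1e-6) / n_mc)
            assert comp.p_adjusted == pytest.approx(emp, abs=max(4 * se, 2e-3))

    def test_missing_control_group_too_small(self):
        with pytest.raises(ValueError):
            stats.dunnett([[1, 2, 3]], [1.0])


class TestRatio:
    def test_examples(self):
        assert stats.active_inactive_ratio(10, 5) == 2.0
        assert stats.active_inactive_ratio(3.3, 3.3) == 1.0

    def test_nonpositive_denominator_undefined(self):
        assert np.isnan(stats.active_inactive_ratio(5, 0))
        out = stats.active_inactive_ratio([10, 10], [5, -1])
        assert out[0] == 2.0 and np.isnan(out[1])


class TestCalibration:
    def test_perfect_line_any_weighting(self):
        pts = [(x, 2 * x + 1) for x in (0.5, 1, 2, 4, 8)]
        for w in ("1/x", "none"):
            c = stats.fit_calibration(pts, weighting=w)
            assert c.slope == pytest.approx(2.0, abs=1e-10)
            assert c.intercept == pytest.approx(1.0, abs=1e-10)
            assert c.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_weighted_closed_form(self):
        c = stats.fit_calibration([(1, 2), (2, 3), (4, 6)], weighting="1/x")
        assert c.slope == pytest.approx(17 / 13, abs=1e-12)
        assert c.intercept == pytest.approx(8 / 13, abs=1e-12)

    def test_unweighted_is_ols(self, rng):
        x = rng.uniform(1, 10, 8)
        y = 3 * x + rng.normal(0, 0.5, 8)
        c = stats.fit_calibration(list(zip(x, y)), weighting="none")
        slope, intercept = np.polyfit(x, y, 1)
        assert c.slope == pytest.approx(slope, rel=1e-9)
        assert c.intercept == pytest.approx(intercept, rel=1e-6)

    def test_weighted_normal_equations(self, rng):
        # 1/x fit equals the explicit weighted normal-equation solution
        x = rng.uniform(0.1, 10, 9)
        y = 1.3 * x + 0.2 + rng.normal(0, 0.3, 9)
        c = stats.fit_calibration(list(zip(x, y)), weighting="1/x")
        w = 1 / x
        A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        b = np.array([(w * y).sum(), (w * x * y).sum()])
        intercept, slope = np.linalg.solve(A, b)
        assert c.slope == pytest.approx(slope, rel=1e-9)
        assert c.intercept == pytest.approx(intercept, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stats.fit_calibration([(1, 1), (2, 2)])
        with pytest.raises(ValueError):
            stats.fit_calibration([(0.0, 1), (2, 2), (3, 3)], weighting="1/x")

    def test_back_calculate_flags(self):
        curve = stats.CalibrationCurve(
            analyte="aldosterone", slope=2.0, intercept=0.5,
            weighting="1/x", valid_range=(0.05, 2.5), r_squared=1.0,
        )
        conc, flag = stats.back_calculate(curve, 4.5)
        assert conc == pytest.approx(2.0) and flag == "ok"
        conc, flag = stats.back_calculate(curve, 0.55)
        assert conc == pytest.approx(0.025) and flag == "below_range"
        conc, flag = stats.back_calculate(curve, 0.5)
        assert conc == 0.0 and flag == "below_range"
        _, flag = stats.back_calculate(curve, 100.0)
        assert flag == "above_range"

    def test_round_trip_on_exact_line(self):
        pts = [(x, 1.7 * x + 0.3) for x in (0.05, 0.5, 1.0, 2.5)]
        c = stats.fit_calibration(pts)
        for x, y in pts:
            conc, _ = stats.back_calculate(c, y)
            assert conc == pytest.approx(x, rel=1e-9)


class TestCV:
    def test_examples(self):
        assert stats.cv_percent([10, 10, 10]) == 0.0
        assert stats.cv_percent([8, 12]) == pytest.approx(28.28, abs=0.01)

    def test_scale_invariance(self, rng):
        v = rng.uniform(1, 5, 10)
        assert stats.cv_percent(3.7 * v) == pytest.approx(stats.cv_percent(v), rel=1e-12)

    def test_zero_mean_undefined(self):
        assert np.isnan(stats.cv_percent([-1.0, 1.0]))


class TestGroupStatistics:
    def test_report_structure_and_stars(self, rng):
        import pandas as pd

        rows = []
        for g, mu in (("control", 0.8), ("low", 1.6), ("high", 0.2)):
            for v in rng.normal(mu, 0.08, 6):
                rows.append({"group": g, "analyte": "aldosterone", "value": v})
        rep = stats.group_statistics(pd.DataFrame(rows), control_label="control")
        assert set(rep["group"]) == {"control", "low", "high"}
        high = rep.set_index("group").loc["high"]
        assert high["dunnett_p"] < 0.01 and high["stars"] == "**"
        assert rep.set_index("group").loc["control", "stars"] == ""

    def test_missing_control_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"group": ["a"] * 3, "analyte": ["x"] * 3, "value": [1.0, 2, 3]}
        )
        with pytest.raises(ValueError):
            stats.group_statistics(df, control_label="control")
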