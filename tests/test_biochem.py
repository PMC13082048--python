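"""Roadblock-efficiency math, decay fitting, and comparison statistics."""

import numpy as np
import pytest

from rnapcollide.biochem import (
    DecayCurve,
    LaneQuant,
    TitrationSeries,
    compare_conditions,
    compute_erb,
    fit_biexponential,
    fraction_intact,
    normalize_erb,
    rescale_titration,
)


def lane(roadblock, scaffold, background=0.0, salt=300.0, condition="x"):
    return LaneQuant(condition, salt, roadblock, scaffold, background)


class TestComputeErb:
    def test_roadblock_at_background_is_zero(self):
        assert compute_erb(lane(10.0, 110.0, background=10.0)) == 0.0

    def test_equal_bands_give_unity(self):
        assert compute_erb(lane(80.0, 80.0)) == 1.0

    def test_background_subtraction(self):
        # (60 - 10) / (110 - 10)
        assert compute_erb(lane(60.0, 110.0, background=10.0)) == pytest.approx(0.5)

    def test_floor_at_zero(self):
        assert compute_erb(lane(5.0, 110.0, background=10.0)) == 0.0

    def test_nonpositive_scaffold_rejected(self):
        with pytest.raises(ValueError, match="scaffold"):
            compute_erb(lane(60.0, 10.0, background=10.0))


class TestRescaleTitration:
    def _series(self, ratios_by_salt, anchor=50.0):
        lanes = tuple(
            lane(100.0 * v, 100.0, salt=s) for s, v in ratios_by_salt.items()
        )
        return TitrationSeries(lanes, anchor_salt=anchor)

    def test_anchor_lane_maps_to_one(self):
        series = self._series({50.0: 0.8, 300.0: 0.4})
        values = dict(rescale_titration(series))
        assert values[50.0] == pytest.approx(1.0)

    def test_half_ratio_maps_to_half(self):
        series = self._series({50.0: 0.8, 300.0: 0.4})
        assert dict(rescale_titration(series))[300.0] == pytest.approx(0.5)

    def test_monotone_titration_preserved(self):
        truth = {50.0: 1.0, 100.0: 0.8, 200.0: 0.5, 300.0: 0.3, 500.0: 0.05}
        series = self._series({s: 0.8 * v for s, v in truth.items()})
        values = rescale_titration(series)
        erbs = [v for _, v in values]
        assert all(a >= b for a, b in zip(erbs, erbs[1:]))
        for (s, v), expected in zip(values, truth.values()):
            assert v == pytest.approx(expected)

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            TitrationSeries((lane(1, 2, salt=300.0),), anchor_salt=50.0)


class TestNormalizeErb:
    def test_reference_mean_is_exactly_one(self):
        out = normalize_erb(
            {"EcoRI*": [0.9, 1.1, 1.0], "NusA": [1.2, 1.3]}, "EcoRI*"
        )
        assert out["EcoRI*"][0] == pytest.approx(1.0, abs=1e-15)

    def test_double_reference_maps_to_two(self):
        out = normalize_erb({"ref": [1.0, 1.0], "double": [2.0, 2.0]}, "ref")
        assert out["double"] == (pytest.approx(2.0), pytest.approx(0.0))

    def test_matches_hand_computation(self, rng):
        values = {
            "ref": list(rng.uniform(0.5, 1.5, 6)),
            "other": list(rng.uniform(0.2, 2.0, 6)),
        }
        out = normalize_erb(values, "ref")
        scale = np.mean(values["ref"])
        for cond in values:
            arr = np.array(values[cond]) / scale
            assert out[cond][0] == pytest.approx(arr.mean(), abs=1e-12)
            assert out[cond][1] == pytest.approx(arr.std(ddof=1), abs=1e-12)

    def test_scale_invariance(self, rng):
        values = {
            "ref": list(rng.uniform(0.5, 1.5, 5)),
            "a": list(rng.uniform(0.2, 2.0, 5)),
        }
        scaled = {k: [37.5 * x for x in v] for k, v in values.items()}
        out1 = normalize_erb(values, "ref")
        out2 = normalize_erb(scaled, "ref")
        for cond in values:
            assert out1[cond][0] == pytest.approx(out2[cond][0], abs=1e-12)
            assert out1[cond][1] == pytest.approx(out2[cond][1], abs=1e-12)

    def test_absent_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_erb({"a": [1.0]}, "missing")


class TestFractionIntact:
    def _curve(self, signal):
        return DecayCurve(
            timepoints=np.arange(len(signal), dtype=float),
            signal=np.asarray(signal, dtype=float),
            no_ntp_control=1000.0,
            pk_control=100.0,
        )

    def test_controls_map_to_unit_interval(self):
        frac = fraction_intact(self._curve([1000.0, 550.0, 100.0]))
        np.testing.assert_allclose(frac, [1.0, 0.5, 0.0])

    def test_out_of_range_clipped(self):
        frac = fraction_intact(self._curve([1100.0, 50.0]))
        np.testing.assert_allclose(frac, [1.0, 0.0])

    def test_affine_invariance(self):
        base = self._curve([900.0, 500.0, 200.0])
        scaled = DecayCurve(
            timepoints=base.timepoints,
            signal=3.0 * base.signal + 40.0,
            no_ntp_control=3.0 * 1000.0 + 40.0,
            pk_control=3.0 * 100.0 + 40.0,
        )
        np.testing.assert_allclose(
            fraction_intact(base), fraction_intact(scaled), atol=1e-12
        )

    def test_decreasing_controls_rejected(self):
        with pytest.raises(ValueError, match="control"):
            DecayCurve(np.array([0.0, 1.0]), np.array([1.0, 1.0]), 100.0, 1000.0)


TIMEPOINTS = np.array([0, 2, 5, 10, 20, 40, 60, 90, 120, 180, 240, 300], float)


class TestFitBiexponential:
    def test_single_exponential_half_life(self):
        k = np.log(2) / 6.0
        t = np.array([0, 1, 2, 4, 6, 9, 12, 18, 24], float)
        fit = fit_biexponential(t, np.exp(-k * t), seed=0, n_boot=50)
        assert fit.half_life == pytest.approx(6.0, rel=0.01)

    def test_biexponential_parameter_recovery(self):
        a1, k1, a2, k2 = 0.7, 0.1, 0.3, 0.005
        y = a1 * np.exp(-k1 * TIMEPOINTS) + a2 * np.exp(-k2 * TIMEPOINTS)
        fit = fit_biexponential(TIMEPOINTS, y, seed=1, n_boot=50)
        assert fit.a1 == pytest.approx(a1, abs=1e-4)
        assert fit.a2 == pytest.approx(a2, abs=1e-4)
        assert fit.k1 == pytest.approx(k1, abs=1e-4)
        assert fit.k2 == pytest.approx(k2, abs=1e-4)
        # independent bisection on the true curve
        from scipy.optimize import brentq

        truth = brentq(
            lambda t: a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) - 0.5 * (a1 + a2),
            0.0,
            1000.0,
        )
        assert fit.half_life == pytest.approx(truth, abs=0.1)

    def test_single_exponential_input_yields_negligible_second_component(self):
        t = np.array([0, 1, 2, 4, 6, 9, 12, 18, 24], float)
        y = np.exp(-0.2 * t)
        fit = fit_biexponential(t, y, seed=2, n_boot=10)
        assert fit.a2 < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_biexponential([0, 1, 2, 3], [1.0, 0.8, 0.6, 0.5], seed=0)

    def test_ci_brackets_estimate_on_noisy_data(self):
        rng = np.random.default_rng(7)
        a1, k1, a2, k2 = 0.6, 0.08, 0.4, 0.004
        y = a1 * np.exp(-k1 * TIMEPOINTS) + a2 * np.exp(-k2 * TIMEPOINTS)
        y = np.clip(y + rng.normal(0, 0.03, y.size), 0, 1)
        fit = fit_biexponential(TIMEPOINTS, y, seed=3, n_boot=200)
        assert fit.ci95[0] <= fit.half_life <= fit.ci95[1]
        assert fit.ci95[0] < fit.ci95[1]


class TestCompareConditions:
    def test_identical_groups(self):
        res = compare_conditions(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, correct=False
        )[0]
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_welch_matches_hand_formulas(self):
        """{1,2,3} vs {2,3,4}: t = -sqrt(3/2), Satterthwaite df = 4."""
        res = compare_conditions({"a": [1, 2, 3], "b": [2, 3, 4]}, correct=False)[0]
        se = np.sqrt(1.0 / 3 + 1.0 / 3)  # both sample variances are 1, n = 3
        assert res["t"] == pytest.approx((2.0 - 3.0) / se, abs=1e-12)
        assert res["df"] == pytest.approx(4.0, abs=1e-12)
        from scipy.stats import t as t_dist

        p_hand = 2 * t_dist.sf(abs(res["t"]), 4.0)
        assert res["p"] == pytest.approx(p_hand, abs=1e-12)

    def test_benjamini_hochberg_step_up(self):
        """Raw p .01...05 over 5 tests all adjust to .05 (step-up by hand)."""
        rng = np.random.default_rng(0)
        groups = {f"g{i}": list(rng.normal(i, 1, 10)) for i in range(5)}
        res = compare_conditions(groups, correct=True,
                                 pairs=[("g0", "g1"), ("g0", "g2")])
        from statsmodels.stats.multitest import multipletests

        # library-independent check of the step-up rule on fixed p values
        raw = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        adj_hand = np.minimum.accumulate((raw * 5 / np.arange(1, 6))[::-1])[::-1]
        np.testing.assert_allclose(adj_hand, [0.05] * 5)
        np.testing.assert_allclose(
            multipletests(raw, method="fdr_bh")[1], adj_hand, atol=1e-12
        )
        # and the pipeline output carries adjusted values for each pair
        assert all("p_adjusted" in r for r in res)
        assert all(r["p_adjusted"] >= r["p"] for r in res)

    def test_zero_variance_pair_handled(self):
        res = compare_conditions(
            {"a": [1.0, 1.0], "b": [2.0, 2.0]}, correct=False
        )[0]
        assert not np.isfinite(res["t"]) or abs(res["t"]) > 0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_conditions({"a": [1.0], "b": [1.0, 2.0]}, correct=False)
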