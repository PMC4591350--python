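"""Kinetic-curve parameters, sigmoid fits, activity and categorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from conftest import quadrature_auc
from straincomp.models import MODELS
from straincomp.pm_kinetics import (
    ACTIVITY_LEVELS,
    KineticCurve,
    activity,
    best_fit,
    categorize_activities,
    curve_parameters,
    fit_sigmoid,
    normalize_heatmap,
    read_kinetics,
    write_kinetics,
)
from straincomp.synthetic import simulate_pm_curve


class TestIO:
    def test_round_trip(self, tmp_path):
        curves = [
            simulate_pm_curve("gompertz", (100, 10, 5, 2), strain_id="a",
                              well_id=f"w{i:02d}", substrate=f"s{i}", replicate=r,
                              noise_sd=3, seed=i * 10 + r)
            for i in range(3) for r in (1, 2)
        ]
        write_kinetics(curves, tmp_path / "k.csv", tmp_path / "m.tsv")
        back = read_kinetics(tmp_path / "k.csv", tmp_path / "m.tsv")
        assert len(back) == len(curves)
        for x, y in zip(curves, back):
            assert (x.strain_id, x.well_id, x.substrate, x.replicate) == (
                y.strain_id, y.well_id, y.substrate, y.replicate
            )
            assert np.allclose(x.signals, y.signals)

    def test_shape_96_wells(self, tmp_path):
        curves = [
            simulate_pm_curve("logistic", (50, 5, 3, 1), well_id=f"w{i:02d}")
            for i in range(96)
        ]
        write_kinetics(curves, tmp_path / "k.csv")
        back = read_kinetics(tmp_path / "k.csv")
        assert len(back) == 96 and all(len(c.times) == 289 for c in back)

    def test_header_only_file(self, tmp_path):
        (tmp_path / "k.csv").write_text("time_h\n")
        assert read_kinetics(tmp_path / "k.csv") == []

    def test_non_monotone_time_raises(self, tmp_path):
        (tmp_path / "k.csv").write_text("time_h,w1\n0,1\n2,2\n1,3\n")
        with pytest.raises(ValueError, match="increasing"):
            read_kinetics(tmp_path / "k.csv")

    def test_negative_signals_clipped_and_counted(self, tmp_path):
        (tmp_path / "k.csv").write_text("time_h,w1\n0,-1\n1,2\n2,-3\n")
        warnings = {}
        (curve,) = read_kinetics(tmp_path / "k.csv", warning_counts=warnings)
        assert warnings["negative_signals_clipped"] == 2
        assert np.all(curve.signals >= 0)


class TestCurveParameters:
    def test_constant_signal_degenerate(self):
        c = KineticCurve("s", "p", "w", "sub", 1, np.arange(20.0), np.full(20, 7.0))
        cp = curve_parameters(c)
        assert cp.span == 0 and cp.max_slope_mu == 0 and cp.auc == 0
        assert cp.plateau == 7.0 and cp.lag_lambda == 19.0

    def test_has_exactly_nine_parameters(self):
        c = simulate_pm_curve("gompertz", (100, 10, 5, 0))
        assert len(curve_parameters(c).as_dict()) == 9

    def test_noiseless_gompertz_recovery(self):
        c = simulate_pm_curve("gompertz", (200, 20, 5, 0))
        cp = curve_parameters(c)
        assert cp.max_slope_mu == pytest.approx(20, rel=0.10)
        assert cp.lag_lambda == pytest.approx(5, abs=0.5)
        oracle = quadrature_auc("gompertz", 200, 20, 5, 0)
        assert cp.auc == pytest.approx(oracle, rel=0.01)

    def test_auc_invariant_to_baseline_shift(self):
        c = simulate_pm_curve("logistic", (150, 15, 6, 0))
        shifted = KineticCurve("s", "p", "w", "sub", 1, c.times, c.signals + 40.0)
        a0 = curve_parameters(c).auc
        a1 = curve_parameters(shifted).auc
        assert a1 == pytest.approx(a0, rel=1e-6)

    def test_too_short_curve_raises(self):
        c = KineticCurve("s", "p", "w", "sub", 1, np.arange(3.0), np.zeros(3))
        with pytest.raises(ValueError, match="short"):
            curve_parameters(c)


class TestSigmoidFits:
    @pytest.mark.parametrize(
        "model,params",
        [
            ("logistic", (200, 20, 5, 10)),
            ("gompertz", (200, 20, 5, 10)),
            ("richards", (200, 20, 5, 10, 2.0)),
        ],
    )
    def test_self_fit_near_zero_rss_and_best_fit_selects(self, model, params):
        c = simulate_pm_curve(model, params)
        fit = fit_sigmoid(c, model)
        assert fit.converged and fit.rss < 1e-6
        assert best_fit(c).model == model

    def test_logistic_data_logistic_beats_gompertz(self):
        c = simulate_pm_curve("logistic", (150, 12, 4, 0))
        assert fit_sigmoid(c, "logistic").rss <= fit_sigmoid(c, "gompertz").rss

    def test_constant_curve_best_fit_still_returns(self):
        c = KineticCurve("s", "p", "w", "sub", 1, np.arange(50.0), np.full(50, 3.0))
        fit = best_fit(c)
        assert fit.model in MODELS
        if fit.converged:
            assert fit.params["A"] == pytest.approx(0, abs=1e-3)


class TestActivity:
    def test_identical_replicates(self):
        c = simulate_pm_curve("gompertz", (100, 10, 5, 0), substrate="s")
        rec = activity([c, c])
        assert rec.activity == pytest.approx(curve_parameters(c).auc)
        assert rec.consistent

    def test_inconsistent_replicates_flagged(self):
        # AUC ratio engineered to 100 vs 160: spread/mean = 60/130 = 0.462 > 0.25
        t = np.arange(0, 11.0)
        c1 = KineticCurve("s", "p", "w", "sub", 1, t, np.full(11, 10.0))
        c2 = KineticCurve("s", "p", "w", "sub", 2, t, np.full(11, 16.0))
        c1.signals[0] = c2.signals[0] = 0.0  # mean-of-first-3 baseline below plateau
        a1 = curve_parameters(c1).auc
        a2 = curve_parameters(c2).auc
        rec = activity([c1, c2])
        assert (max(a1, a2) - min(a1, a2)) / np.mean([a1, a2]) > 0.25
        assert not rec.consistent

    def test_single_replicate(self):
        c = simulate_pm_curve("logistic", (80, 8, 3, 0), substrate="s")
        rec = activity([c])
        assert rec.activity == pytest.approx(curve_parameters(c).auc)
        assert rec.consistent


class TestCategorize:
    def test_worked_levels(self):
        acts = {"w1": 100.0, "w2": 80.0, "w3": 60.0, "w4": 30.0, "w5": 10.0}
        levels = categorize_activities(acts)
        assert levels == {
            "w1": "high", "w2": "high", "w3": "upper-middle",
            "w4": "lower-middle", "w5": "low",
        }

    def test_all_zero_plate_all_low(self):
        levels = categorize_activities({"w1": 0.0, "w2": 0.0})
        assert set(levels.values()) == {"low"}

    def test_level_domain_has_four_levels(self):
        assert len(ACTIVITY_LEVELS) == 4
        rng = np.random.default_rng(0)
        acts = {f"w{i}": float(v) for i, v in enumerate(rng.uniform(0, 100, 200))}
        assert set(categorize_activities(acts).values()) <= set(ACTIVITY_LEVELS)


class TestNormalize:
    def test_linear_map(self):
        assert np.allclose(normalize_heatmap([0, 50, 100]), [0, 0.5, 1])

    def test_constant_maps_to_zero(self):
        assert np.allclose(normalize_heatmap([7, 7]), [0, 0])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=50))
    def test_output_in_unit_interval(self, values):
        out = normalize_heatmap(values)
        assert np.all(out >= 0) and np.all(out <= 1)
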