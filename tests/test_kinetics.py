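"""FRAP normalized-difference fitting and spot-bleach estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from extruderquant import kinetics as kin
from extruderquant.synthetic import FrapGroundTruth, gen_frap_curve, gen_spotbleach_trace


class TestNormalizedDifference:
    def test_constant_regions_give_unity(self):
        curve = kin.normalized_difference(np.full(10, 10.0), np.full(10, 4.0))
        np.testing.assert_allclose(curve.values, 1.0)

    def test_equilibration_drives_difference_to_zero(self):
        t = np.arange(50, dtype=float)
        f_ub = np.full(50, 10.0)
        f_b = 10.0 - 6.0 * np.exp(-0.5 * t)
        curve = kin.normalized_difference((t, f_ub), (t, f_b))
        assert curve.values[-1] == pytest.approx(0.0, abs=1e-9)

    def test_two_region_construction_matches_model(self):
        """Regions built from bound pools + shared soluble term reduce to the model."""
        t = np.arange(30, dtype=float) * 20
        a, koff, soluble = 0.3, 0.01, 2.0
        model = kin.recovery_model(t, a, koff)
        f_ub = soluble + 5.0 * (1 + model)   # unbleached bound pool
        f_b = soluble + 5.0 * (1 - model)    # bleached pool recovering
        curve = kin.normalized_difference((t, f_ub), (t, f_b))
        np.testing.assert_allclose(curve.values, model, rtol=1e-12)

    def test_zero_initial_difference_rejected(self):
        with pytest.raises(ValueError, match="bleach"):
            kin.normalized_difference(np.full(5, 3.0), np.full(5, 3.0))


class TestFitRecovery:
    def test_exact_on_noiseless_curve(self):
        # CTCF G1: 48.8% stable fraction, 139 s residence time
        curve = gen_frap_curve(FrapGroundTruth(a_immobile=0.488, koff=1 / 139.0))
        fit = kin.fit_recovery(curve)
        assert fit.fit_ok
        assert fit.a_immobile == pytest.approx(0.488, rel=1e-6)
        assert fit.residence_time == pytest.approx(139.0, rel=1e-6)

    def test_constant_curve_is_flagged(self):
        curve = kin.RecoveryCurve(np.arange(10.0), np.ones(10))
        fit = kin.fit_recovery(curve)
        assert not fit.fit_ok

    def test_increasing_curve_is_flagged(self):
        curve = kin.RecoveryCurve(np.arange(10.0), np.linspace(0.2, 1.0, 10))
        fit = kin.fit_recovery(curve)
        assert not fit.fit_ok and "increasing" in fit.message

    def test_monte_carlo_recovery_stag1_early_g1(self):
        """STAG1 eG1 truth (27% stable, 244 s) at realistic noise."""
        a_err, taus = [], []
        for seed in range(100):
            truth = FrapGroundTruth(a_immobile=0.27, koff=1 / 244.0, noise_sd=0.02,
                                    n_frames=30, frame_interval=20.0, seed=seed)
            fit = kin.fit_recovery(gen_frap_curve(truth))
            assert fit.fit_ok
            a_err.append(abs(fit.a_immobile - 0.27))
            taus.append(fit.residence_time)
        assert np.mean(a_err) < 0.05
        assert abs(np.median(taus) - 244.0) / 244.0 < 0.10

    @pytest.mark.parametrize("a", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("tau", [60.0, 120.0, 240.0])
    def test_parameter_recovery_grid(self, a, tau):
        """Median relative error < 10% for both parameters at noise_sd=0.02.

        The recording (45 frames at 20 s) spans >= 2.5 lifetimes of the
        slowest grid cell so that the test measures estimator quality, not
        the information limit of a truncated recording: at 30 frames the
        Cramer-Rao bound alone puts the a=0.1/tau=240 s cell above 10%.
        """
        errs_a, errs_k = [], []
        for seed in range(200):
            truth = FrapGroundTruth(a_immobile=a, koff=1 / tau, noise_sd=0.02,
                                    n_frames=45, frame_interval=20.0, seed=seed)
            fit = kin.fit_recovery(gen_frap_curve(truth))
            if fit.fit_ok:
                errs_a.append(abs(fit.a_immobile - a) / a)
                errs_k.append(abs(fit.koff - 1 / tau) * tau)
        assert len(errs_a) > 180
        assert np.median(errs_a) < 0.10
        assert np.median(errs_k) < 0.10


class TestSpotbleach:
    def test_direct_formula(self):
        trace = kin.DepletionTrace(np.linspace(0, 30, 61),
                                   np.concatenate([np.full(31, 100.0), np.full(30, 60.0)]))
        assert kin.spotbleach_bound_fraction(trace).raw_pct == pytest.approx(40.0, rel=0.01)

    def test_flat_trace_zero_percent(self):
        trace = kin.DepletionTrace(np.linspace(0, 30, 61), np.full(61, 100.0))
        assert kin.spotbleach_bound_fraction(trace).raw_pct == 0.0

    def test_generator_closed_form_oracle(self):
        """Window means evaluated on the noiseless model match the estimator."""
        bound, rate = 0.4, 1.0
        trace = gen_spotbleach_trace(bound, rate, duration=30.0, dt=0.05)
        t = trace.times
        model = (1 - bound) + bound * np.exp(-rate * t)
        pre = model[t <= t[0] + 0.5].mean()
        post = model[t >= t[-1] - 0.5].mean()
        expected = 100.0 * (pre - post) / pre
        got = kin.spotbleach_bound_fraction(trace).raw_pct
        assert got == pytest.approx(expected, abs=1e-9)

    def test_plateau_contrast_recovers_bound_fraction(self):
        """With instantaneous endpoints the contrast equals the planted fraction."""
        trace = gen_spotbleach_trace(0.4, 1.0, duration=30.0, dt=0.05)
        got = kin.spotbleach_bound_fraction(trace, window_s=0.0).raw_pct
        assert got == pytest.approx(40.0, abs=0.5)

    def test_scale_invariance(self):
        trace = gen_spotbleach_trace(0.3, 0.5, seed=1)
        scaled = kin.DepletionTrace(trace.times, trace.intensities * 123.4)
        assert kin.spotbleach_bound_fraction(scaled).raw_pct == pytest.approx(
            kin.spotbleach_bound_fraction(trace).raw_pct)

    def test_nonpositive_prebleach_rejected(self):
        trace = kin.DepletionTrace(np.linspace(0, 2, 10), np.zeros(10))
        with pytest.raises(ValueError):
            kin.spotbleach_bound_fraction(trace)


class TestCalibration:
    def test_reference_endpoints(self):
        assert kin.calibrate_bound_fraction(8.0, 8.0, 95.0).calibrated_pct == 0.0
        assert kin.calibrate_bound_fraction(95.0, 8.0, 95.0).calibrated_pct == 100.0

    def test_midpoint(self):
        bf = kin.calibrate_bound_fraction(51.5, 8.0, 95.0)
        assert bf.calibrated_pct == pytest.approx(50.0)

    def test_inverted_references_rejected(self):
        with pytest.raises(ValueError):
            kin.calibrate_bound_fraction(50.0, 95.0, 8.0)

    @given(raw=st.floats(-20, 120), free=st.floats(0, 40),
           h2b=st.floats(50, 120))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unique_affine_map(self, raw, free, h2b):
        """Calibration is the affine map sending free -> 0 and h2b -> 100, clipped."""
        got = kin.calibrate_bound_fraction(raw, free, h2b).calibrated_pct
        expected = np.clip(100.0 * (raw - free) / (h2b - free), 0.0, 100.0)
        assert got == pytest.approx(expected)


class TestHalfbleach:
    def test_nothing_soluble_lost(self):
        assert kin.halfbleach_bound_fraction(10.0, 8.0, 10.0, 5.0) == 1.0

    def test_half_lost(self):
        assert kin.halfbleach_bound_fraction(10.0, 8.0, 5.0, 4.0) == pytest.approx(0.5)

    def test_two_pool_simulation(self, rng):
        """40% bound with instant soluble mixing across both halves."""
        bound, total = 0.4, 1000.0
        half = total / 2
        soluble_half = half * (1 - bound)
        pre_ub = pre_b = half
        # soluble pool fully bleached; bound pool of unbleached half untouched
        post_ub = half * bound + rng.normal(0, 2)
        post_b = 0.0 * soluble_half + rng.normal(0, 2)
        got = kin.halfbleach_bound_fraction(pre_ub, pre_b, post_ub, post_b)
        assert got == pytest.approx(0.40, abs=0.02)
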