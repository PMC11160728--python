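"""Generator ground-truth and reproducibility checks."""

import numpy as np
import pytest

from extruderquant import synthetic as syn
from extruderquant.kinetics import recovery_model


class TestFrapGenerator:
    def test_noiseless_curve_lies_on_model(self):
        truth = syn.FrapGroundTruth(a_immobile=0.3, koff=0.01, noise_sd=0.0)
        curve = syn.gen_frap_curve(truth)
        assert curve.values[0] == pytest.approx(1.0)
        np.testing.assert_allclose(curve.values, recovery_model(curve.times, 0.3, 0.01),
                                   rtol=1e-12)

    def test_fully_immobile_is_constant(self):
        curve = syn.gen_frap_curve(syn.FrapGroundTruth(a_immobile=1.0, koff=0.5))
        np.testing.assert_allclose(curve.values, 1.0)

    def test_longtime_limit_is_stable_fraction(self):
        # CTCF in G1: 48.8% stably bound, 139 s residence time
        truth = syn.FrapGroundTruth(a_immobile=0.488, koff=1 / 139.0,
                                    n_frames=200, frame_interval=20.0)
        curve = syn.gen_frap_curve(truth)
        assert curve.values[-1] == pytest.approx(0.488, abs=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(a_immobile=-0.1, koff=0.01),
        dict(a_immobile=1.2, koff=0.01),
        dict(a_immobile=0.5, koff=0.0),
        dict(a_immobile=0.5, koff=0.01, n_frames=2),
    ])
    def test_parameter_validation(self, bad):
        with pytest.raises(ValueError):
            syn.FrapGroundTruth(**bad)

    def test_seed_reproducibility(self):
        t = dict(a_immobile=0.3, koff=0.01, noise_sd=0.05)
        a = syn.gen_frap_curve(syn.FrapGroundTruth(seed=7, **t))
        b = syn.gen_frap_curve(syn.FrapGroundTruth(seed=7, **t))
        c = syn.gen_frap_curve(syn.FrapGroundTruth(seed=8, **t))
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestSpotbleachGenerator:
    def test_unbound_trace_is_flat(self):
        tr = syn.gen_spotbleach_trace(0.0, bleach_rate=1.0)
        np.testing.assert_allclose(tr.intensities, 1.0)

    def test_fully_bound_fast_bleach_drops_to_zero(self):
        tr = syn.gen_spotbleach_trace(1.0, bleach_rate=50.0)
        assert tr.intensities[-1] == pytest.approx(0.0, abs=1e-12)

    def test_plateau_equals_unbound_fraction(self):
        tr = syn.gen_spotbleach_trace(0.4, bleach_rate=1.0, duration=30.0)
        assert tr.intensities[-1] == pytest.approx(0.6, abs=1e-6)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            syn.gen_spotbleach_trace(0.4, 1.0, duration=-1.0)
        with pytest.raises(ValueError):
            syn.gen_spotbleach_trace(1.4, 1.0)


class TestFcsGenerator:
    def test_zero_lag_amplitude_is_inverse_n(self):
        curve = syn.gen_fcs_acf(10.0, tau_d=1e-3, lags=np.array([0.0, 1e-3, 1e-2]))
        assert curve.values[0] == pytest.approx(0.1)

    def test_2d_limit_half_amplitude_at_tau_d(self):
        curve = syn.gen_fcs_acf(10.0, tau_d=1e-3, kappa=1e6,
                                lags=np.array([0.0, 1e-3]))
        assert curve.values[1] == pytest.approx(0.05, rel=1e-6)

    def test_empty_lags_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_fcs_acf(10.0, 1e-3, lags=np.array([]))


class TestStedGenerator:
    def test_image_side_from_field_area(self):
        p = syn.StedSimParams(n_spots=0)
        # ceil(sqrt(200 um^2) * 1000 / 18.88 nm)
        assert p.side_px == 750

    def test_zero_spots_gives_pure_background(self):
        p = syn.StedSimParams(n_spots=0, background_noise_sd=0.0, seed=1)
        img, truth = syn.gen_sted_image(p)
        assert len(truth) == 0
        np.testing.assert_allclose(img, p.background_mean)

    def test_truth_table_matches_spot_count_and_bounds(self):
        p = syn.StedSimParams(n_spots=40, seed=2)
        img, truth = syn.gen_sted_image(p)
        assert len(truth) == 40
        assert truth["row"].between(0, p.side_px - 1).all()
        assert truth["col"].between(0, p.side_px - 1).all()

    def test_peak_sits_gain_fold_over_background(self):
        p = syn.StedSimParams(n_spots=1, background_noise_sd=0.0,
                              min_separation=0, seed=3)
        img, truth = syn.gen_sted_image(p)
        r, c = int(truth.row[0]), int(truth.col[0])
        if 30 < r < 720 and 30 < c < 720:  # away from the cropped field edge
            expected = p.background_mean * (1 + p.intensity_gain)
            assert img[r, c] == pytest.approx(expected, rel=1e-6)

    def test_dimers_double_the_peak_amplitude(self):
        p = syn.StedSimParams(n_spots=60, dimer_fraction=0.5, seed=4)
        _, truth = syn.gen_sted_image(p)
        mono = truth.loc[~truth.is_dimer, "peak_amplitude"]
        dim = truth.loc[truth.is_dimer, "peak_amplitude"]
        assert dim.iloc[0] == pytest.approx(2 * mono.iloc[0])

    def test_second_channel_copies_coloc_fraction(self):
        p = syn.StedSimParams(n_spots=50, coloc_fraction=1.0, seed=5)
        _, t1, _, t2 = syn.gen_sted_image(p, second_channel=True)
        shared = set(map(tuple, t1[["row", "col"]].to_numpy())) \
            & set(map(tuple, t2[["row", "col"]].to_numpy()))
        assert len(shared) == 50

    def test_reproducible_per_seed(self):
        p = syn.StedSimParams(n_spots=20, seed=9)
        a, _ = syn.gen_sted_image(p)
        b, _ = syn.gen_sted_image(p)
        np.testing.assert_array_equal(a, b)


class TestTraceGenerator:
    def test_crossing_loops_rejected_before_output(self):
        with pytest.raises(ValueError, match="cross"):
            syn.TraceSimParams(loops=[(10, 60, 0.5), (40, 80, 0.5)])

    def test_nested_and_disjoint_loops_accepted(self):
        syn.TraceSimParams(loops=[(10, 60, 0.5), (20, 40, 0.5), (70, 90, 0.5)])

    def test_random_walk_msd_scaling(self):
        p = syn.TraceSimParams(n_traces=800, n_bins=60, loc_noise_sd=0.0,
                               missing_fraction=0.0, seed=21)
        df = syn.gen_traces(p)
        xyz = df.sort_values(["trace_id", "bin_index"])[["x", "y", "z"]].to_numpy()
        xyz = xyz.reshape(800, 60, 3)
        for k in (5, 20):
            msd = np.mean(np.sum((xyz[:, k:] - xyz[:, :-k]) ** 2, axis=-1))
            assert msd == pytest.approx(3 * k * p.step_sd**2, rel=0.1)

    def test_loop_compacts_intraloop_distances(self):
        pl = syn.TraceSimParams(n_traces=500, loops=[(10, 60, 0.3)],
                                loc_noise_sd=0.0, missing_fraction=0.0, seed=22)
        p0 = syn.TraceSimParams(n_traces=500, loc_noise_sd=0.0,
                                missing_fraction=0.0, seed=22)
        for p, label in ((pl, "loop"), (p0, "noloop")):
            df = syn.gen_traces(p)
            xyz = df.sort_values(["trace_id", "bin_index"])[["x", "y", "z"]]
            arr = xyz.to_numpy().reshape(500, 100, 3)
            d = np.median(np.linalg.norm(arr[:, 55] - arr[:, 15], axis=-1))
            if label == "loop":
                d_loop = d
            else:
                d_free = d
        assert d_loop < 0.5 * d_free

    def test_high_missing_fraction_starves_traces(self):
        df = syn.gen_traces(syn.TraceSimParams(n_traces=200, missing_fraction=0.9,
                                               seed=23))
        sizes = df.groupby("trace_id").size()
        # Binomial(100, 0.1): P(>= 20 points) is tiny
        assert (sizes < 20).mean() > 0.95


class TestCalibrationCells:
    def test_zero_concentration_gives_background(self):
        df = syn.gen_calibration_cells(2.0, 5.0, [0.0])
        assert df["intensity"].iloc[0] == pytest.approx(5.0)

    def test_known_point(self):
        df = syn.gen_calibration_cells(2.0, 5.0, [100.0])
        assert df["intensity"].iloc[0] == pytest.approx(55.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            syn.gen_calibration_cells(-1.0, 5.0, [1.0])
        with pytest.raises(ValueError):
            syn.gen_calibration_cells(2.0, 5.0, [])
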