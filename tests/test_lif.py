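import numpy as np
import pytest

from transdentin.lif import (
    CalibrationCurve,
    IntensityStack,
    RegionOfInterest,
    fit_calibration,
    mean_frame,
    read_stack,
    run_synthetic_profile_experiment,
    synthesize_stack,
    to_concentration,
    write_stack,
)

SLOPE = 1000.0  # a.u. per mg/L
INTERCEPT = 5.0  # a.u. background
STANDARDS = (0.05, 0.025, 0.0)  # mg/L


def make_standards(noise_sigma, seed=0, n_frames=20):
    rng = np.random.default_rng(seed)
    return [
        (
            c,
            synthesize_stack(
                c, SLOPE, INTERCEPT, n_frames=n_frames, noise_sigma=noise_sigma,
                seed=int(rng.integers(2**31)),
            ),
        )
        for c in STANDARDS
    ]


class TestStackBasics:
    def test_mean_of_identical_frames_is_that_frame(self):
        stack = synthesize_stack(0.03, SLOPE, INTERCEPT, n_frames=7, noise_sigma=0.0)
        np.testing.assert_array_equal(mean_frame(stack), stack.frames[0])

    def test_single_frame_mean_is_identity(self):
        stack = synthesize_stack(0.01, SLOPE, INTERCEPT, n_frames=1, noise_sigma=0.0)
        np.testing.assert_array_equal(mean_frame(stack), stack.frames[0])

    def test_frame_averaging_suppresses_noise_like_sqrt_n(self):
        sigma = 2.0
        stack = synthesize_stack(
            0.03, SLOPE, INTERCEPT, n_frames=20, noise_sigma=sigma, seed=11,
            shape=(100, 100),
        )
        residual = mean_frame(stack) - (SLOPE * 0.03 + INTERCEPT)
        measured = residual.std()
        assert measured == pytest.approx(sigma / np.sqrt(20), rel=0.1)

    def test_fixed_seed_is_bit_identical(self):
        a = synthesize_stack(0.02, SLOPE, INTERCEPT, noise_sigma=1.0, seed=123)
        b = synthesize_stack(0.02, SLOPE, INTERCEPT, noise_sigma=1.0, seed=123)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_invalid_stacks_rejected(self):
        with pytest.raises(ValueError):
            IntensityStack(frames=np.zeros((4, 4)))  # not 3-D
        with pytest.raises(ValueError):
            IntensityStack(frames=-np.ones((2, 4, 4)))
        with pytest.raises(ValueError):
            synthesize_stack(0.01, SLOPE, INTERCEPT, noise_sigma=-1.0)

    def test_axial_profile_must_match_width(self):
        with pytest.raises(ValueError, match="width"):
            synthesize_stack(np.linspace(0, 0.05, 7), SLOPE, INTERCEPT, shape=(10, 8))


class TestRegionOfInterest:
    def test_default_roi_is_full_standard_field(self):
        rows, cols = RegionOfInterest().to_slices(10.0, (58, 30))
        assert (rows.start, rows.stop) == (0, 58)
        assert (cols.start, cols.stop) == (0, 30)

    def test_floors_to_enclosed_pixels(self):
        roi = RegionOfInterest(x0=5.0, y0=5.0, width=100.0, height=100.0)
        rows, cols = roi.to_slices(10.0, (58, 30))
        assert rows.start == 1 and rows.stop == 10  # 5..105 um -> pixels 1..9
        assert cols.start == 1 and cols.stop == 10

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(x0=0, y0=0, width=5.0, height=5.0).to_slices(10.0, (58, 30))


class TestCalibration:
    def test_exact_recovery_at_zero_noise(self):
        curve = fit_calibration(make_standards(0.0))
        assert curve.slope == pytest.approx(SLOPE, rel=1e-9)
        assert curve.intercept == pytest.approx(INTERCEPT, rel=1e-9)
        assert curve.residual == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered_within_5_percent_at_2_percent_noise(self):
        noise_sigma = 0.02 * SLOPE * max(STANDARDS)  # 2% of dynamic range
        curve = fit_calibration(make_standards(noise_sigma, seed=7))
        assert curve.slope == pytest.approx(SLOPE, rel=0.05)

    def test_intercept_matches_background_standard(self):
        noise_sigma = 1.0
        standards = make_standards(noise_sigma, seed=3)
        curve = fit_calibration(standards)
        background = standards[-1]
        assert background[0] == 0.0
        roi_mean = mean_frame(background[1]).mean()
        assert curve.intercept == pytest.approx(roi_mean, abs=3 * noise_sigma)

    def test_degenerate_standards_rejected(self):
        stack = synthesize_stack(0.05, SLOPE, INTERCEPT)
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration([(0.05, stack), (0.05, stack)])
        with pytest.raises(ValueError):
            fit_calibration([(0.05, stack)])


class TestRecovery:
    def test_standard_concentration_recovered(self):
        curve = fit_calibration(make_standards(1.0, seed=5))
        stack = synthesize_stack(0.025, SLOPE, INTERCEPT, noise_sigma=1.0, seed=99)
        measurement = to_concentration(stack, curve)
        assert measurement.roi_mean == pytest.approx(0.025, rel=0.05)
        assert not measurement.out_of_range

    def test_background_recovers_to_zero(self):
        curve = fit_calibration(make_standards(1.0, seed=5))
        stack = synthesize_stack(0.0, SLOPE, INTERCEPT, noise_sigma=1.0, seed=100)
        assert to_concentration(stack, curve).roi_mean == pytest.approx(0.0, abs=2e-3 * 0.05)

    def test_above_calibrated_range_is_flagged(self):
        curve = fit_calibration(make_standards(0.0))
        stack = synthesize_stack(0.2, SLOPE, INTERCEPT, noise_sigma=0.0)
        assert to_concentration(stack, curve).out_of_range

    def test_invalid_curve_rejected(self):
        stack = synthesize_stack(0.01, SLOPE, INTERCEPT)
        bad = CalibrationCurve(slope=-1.0, intercept=0.0, residual=0.0)
        with pytest.raises(ValueError, match="slope"):
            to_concentration(stack, bad)


class TestEndToEnd:
    def test_known_profile_recovered_within_10_percent(self):
        """Synthesize -> calibrate -> recover on a decaying axial profile at
        2% noise with 20-frame bursts stays inside the 10% agreement level."""
        truth = np.linspace(0.048, 0.008, 13)  # mg/L at 13 axial locations
        recovered, curve = run_synthetic_profile_experiment(truth, seed=17)
        max_rel_error = np.max(np.abs(recovered - truth)) / truth.max()
        assert max_rel_error <= 0.10

    def test_recovery_error_decreases_with_frame_count(self):
        truth = np.array([0.04, 0.02, 0.01])
        errors = {}
        for n_frames in (2, 8, 32):
            per_seed = []
            for seed in range(20):
                recovered, _ = run_synthetic_profile_experiment(
                    truth, n_frames=n_frames, seed=seed, shape=(20, 12)
                )
                per_seed.append(np.max(np.abs(recovered - truth)) / truth.max())
            errors[n_frames] = np.mean(per_seed)
        assert errors[32] < errors[8] < errors[2]


def test_tiff_roundtrip(tmp_path):
    stack = synthesize_stack(0.03, SLOPE, INTERCEPT, noise_sigma=1.0, seed=8)
    path = tmp_path / "stack.tif"
    write_stack(path, stack)
    loaded = read_stack(path)
    assert loaded.frames.shape == stack.frames.shape
    np.testing.assert_allclose(loaded.frames, stack.frames, atol=1e-3)
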