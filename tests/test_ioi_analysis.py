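"""Correctness of the activation-map analysis chain."""

import numpy as np
import pytest

from fiberlight.ioi_analysis import (
    ActivationMap,
    NormalizedStack,
    activation_area,
    average_and_normalize,
    fit_intensity_response,
    halfmax_recovery_area,
    mask_centroid,
    peak_amplitude,
    response_map,
    spatial_filter,
    t_map,
)
from fiberlight.ioi_synth import (
    AcquisitionProtocol,
    GroundTruthActivation,
    generate_trials,
    halfmax_footprint_area,
    noise_sigma_for_snr,
    spatial_profile,
)


def noise_free_stack(protocol, truth):
    return average_and_normalize(generate_trials(protocol, truth, seed=0), "stim")


class TestAverageNormalize:
    def test_constant_stack_becomes_all_ones(self, small_protocol):
        truth = GroundTruthActivation(center=(32, 32), peak_amplitude=0.0,
                                      noise_sigma=0.0, baseline=7.3)
        stack = noise_free_stack(small_protocol, truth)
        assert np.allclose(stack.data, 1.0, atol=1e-12)

    def test_center_minimum_matches_amplitude(self, small_protocol):
        truth = GroundTruthActivation(center=(32.0, 32.0), spatial_sigma=8.0,
                                      peak_amplitude=-2.2e-4, noise_sigma=0.0)
        stack = noise_free_stack(small_protocol, truth)
        assert stack.data[:, 32, 32].min() == pytest.approx(0.99978, abs=1e-9)

    def test_prestim_mean_is_exactly_one(self, small_protocol, centered_truth):
        stack = average_and_normalize(
            generate_trials(small_protocol, centered_truth, seed=3), "stim")
        pre = stack.data[:8].mean(axis=0)
        assert np.allclose(pre, 1.0, atol=1e-12)

    def test_idempotent_on_normalized_single_trial(self, centered_truth):
        proto = AcquisitionProtocol(image_shape=(16, 16), n_trials_stim=1, n_trials_blank=1)
        truth = GroundTruthActivation(center=(8, 8), spatial_sigma=3.0, noise_sigma=1e-3)
        trials = generate_trials(proto, truth, seed=2)
        once = average_and_normalize(trials, "stim")
        trials.data[trials.labels == "stim"] = once.data[None]
        twice = average_and_normalize(trials, "stim")
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_trial_averaging_reduces_prestim_variance(self, small_protocol):
        truth = GroundTruthActivation(center=(32, 32), peak_amplitude=0.0, noise_sigma=1e-3)
        trials = generate_trials(small_protocol, truth, seed=4)
        single = trials.data[0, :8] / trials.data[0, :8].mean(axis=0)
        averaged = average_and_normalize(trials, "stim").data[:8]
        ratio = single.var() / averaged.var()
        assert ratio == pytest.approx(20, rel=0.25)


class TestSpatialFilter:
    def _stack(self, frame, protocol):
        data = np.ones((protocol.n_frames, *protocol.image_shape))
        data[10] = frame
        return NormalizedStack(data=data, protocol=protocol)

    def test_sigma_zero_is_identity(self, small_protocol, centered_truth, rng):
        trials = generate_trials(small_protocol, centered_truth, seed=5)
        stack = average_and_normalize(trials, "stim")
        assert np.array_equal(spatial_filter(stack, 0.0).data, stack.data)

    def test_constant_frames_unchanged(self, small_protocol):
        stack = self._stack(np.full(small_protocol.image_shape, 1.0), small_protocol)
        out = spatial_filter(stack, 4.0)
        assert np.allclose(out.data, 1.0, atol=1e-12)

    def test_impulse_response_peak(self):
        proto = AcquisitionProtocol(image_shape=(65, 65))
        frame = np.ones((65, 65))
        frame[32, 32] += 1.0
        data = np.ones((proto.n_frames, 65, 65))
        data[10] = frame
        out = spatial_filter(NormalizedStack(data=data, protocol=proto), 4.0)
        # unit impulse -> kernel peak 1/(2*pi*sigma^2)
        assert out.data[10, 32, 32] - 1.0 == pytest.approx(1 / (2 * np.pi * 16), rel=1e-3)

    def test_negative_sigma_rejected(self, small_protocol):
        stack = self._stack(np.ones(small_protocol.image_shape), small_protocol)
        with pytest.raises(ValueError):
            spatial_filter(stack, -1.0)


class TestTMap:
    def test_null_type_i_rate_calibrated(self):
        """Blank data, no filtering: significant fraction ≈ α within the
        binomial 99% CI (pixels are independent)."""
        proto = AcquisitionProtocol(image_shape=(128, 128))
        truth = GroundTruthActivation(center=(64, 64), peak_amplitude=0.0, noise_sigma=1e-3)
        stack = average_and_normalize(generate_trials(proto, truth, seed=6), "blank")
        amap = t_map(stack, alpha=0.05)
        n = amap.mask.size
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(amap.mask.mean() - 0.05) < ci + 0.003

    def test_noise_free_activation_is_significant_everywhere(self, small_protocol):
        """Without noise every pixel carries a deterministic response, so the
        whole field is significant.  p at the centre is bounded by the HRF's
        own within-window variance (the t statistic is scale-free in the
        noise-free limit), not by machine precision."""
        truth = GroundTruthActivation(center=(32.0, 32.0), spatial_sigma=8.0, noise_sigma=0.0)
        stack = noise_free_stack(small_protocol, truth)
        amap = t_map(stack, alpha=0.05)
        assert amap.p[32, 32] < 1e-3
        assert amap.mask.all()

    def test_alpha_monotonicity(self, small_protocol, centered_truth):
        truth = GroundTruthActivation(center=(32, 32), spatial_sigma=8.0, noise_sigma=5e-4)
        stack = average_and_normalize(generate_trials(small_protocol, truth, seed=8), "stim")
        m1 = t_map(stack, alpha=0.01).mask
        m5 = t_map(stack, alpha=0.05).mask
        assert np.all(m5[m1])    # mask(0.01) ⊆ mask(0.05)

    def test_window_validation(self, small_protocol, centered_truth):
        stack = noise_free_stack(small_protocol,
                                 GroundTruthActivation(center=(32, 32), noise_sigma=0.0))
        for window in [(4, 24), (8, 9), (70, 90)]:
            with pytest.raises(ValueError):
                t_map(stack, response_window=window)


class TestAreaAndAmplitude:
    def _map(self, n_px, shape=(300, 300), pixel_size=0.01):
        mask = np.zeros(shape, bool)
        mask.flat[:n_px] = True
        return ActivationMap(t=np.zeros(shape), p=np.where(mask, 0.0, 1.0),
                             mask=mask, alpha=0.05, pixel_size=pixel_size)

    def test_area_arithmetic(self):
        assert activation_area(self._map(0)) == 0.0
        assert activation_area(self._map(450)) == pytest.approx(0.045)
        assert activation_area(self._map(300 * 300)) == pytest.approx(9.0)

    def test_all_ones_stack_has_zero_amplitude(self, small_protocol):
        data = np.ones((small_protocol.n_frames, *small_protocol.image_shape))
        stack = NormalizedStack(data=data, protocol=small_protocol)
        assert peak_amplitude(stack, np.ones(small_protocol.image_shape, bool)) == 0.0

    def test_halfmax_mask_amplitude_bounds(self, small_protocol):
        """Averaging over the half-maximum footprint dilutes the peak by at
        most 2: the result lies between A and A/2 (in percent)."""
        truth = GroundTruthActivation(center=(32.0, 32.0), spatial_sigma=8.0,
                                      peak_amplitude=-2.2e-4, noise_sigma=0.0)
        stack = noise_free_stack(small_protocol, truth)
        mask = spatial_profile(small_protocol, truth) >= 0.5
        amp = peak_amplitude(stack, mask)
        assert -0.022 < amp < -0.011
        assert np.sign(amp) == np.sign(truth.peak_amplitude)

    def test_empty_mask_rejected(self, small_protocol):
        data = np.ones((small_protocol.n_frames, *small_protocol.image_shape))
        stack = NormalizedStack(data=data, protocol=small_protocol)
        with pytest.raises(ValueError):
            peak_amplitude(stack, np.zeros(small_protocol.image_shape, bool))


class TestFits:
    def test_exact_linear_fit(self):
        x = np.array([1.4, 2.2, 3.2, 5.0, 8.9])
        y = 0.3 + 0.45 * x
        res = fit_intensity_response(x, y, "linear")
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.3, abs=1e-10)
        assert res.slope == pytest.approx(0.45, abs=1e-10)

    def test_exact_logarithmic_fit(self):
        x = np.array([1.4, 2.2, 3.2, 5.0, 8.9])
        y = -0.01 - 0.006 * np.log(x)
        res = fit_intensity_response(x, y, "logarithmic")
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.slope == pytest.approx(-0.006, abs=1e-10)
        assert np.allclose(res.predict(x), y, atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_intensity_response([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_intensity_response([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_intensity_response([-1, 1, 2], [1, 2, 3], "logarithmic")


class TestRecovery:
    def test_footprint_and_centroid_recovery_at_snr5(self, small_protocol):
        """At SNR 5 the measured half-max footprint matches the closed form
        and the significant-mask centroid stays near the true centre."""
        base = GroundTruthActivation(center=(30.0, 34.0), spatial_sigma=8.0)
        ns = noise_sigma_for_snr(small_protocol, base, 5.0)
        truth = GroundTruthActivation(center=(30.0, 34.0), spatial_sigma=8.0,
                                      noise_sigma=ns)
        expected = halfmax_footprint_area(truth, small_protocol)
        for seed in range(5):
            trials = generate_trials(small_protocol, truth, seed=seed)
            stack = average_and_normalize(trials, "stim")
            area = halfmax_recovery_area(stack)
            assert area == pytest.approx(expected, rel=0.25)
            amap = t_map(spatial_filter(stack, 4.0), alpha=0.01)
            cy, cx = mask_centroid(amap.mask)
            assert np.hypot(cy - 30.0, cx - 34.0) < 2 * truth.spatial_sigma

    def test_response_map_matches_truth_profile(self, small_protocol):
        truth = GroundTruthActivation(center=(32.0, 32.0), spatial_sigma=8.0,
                                      noise_sigma=0.0)
        stack = noise_free_stack(small_protocol, truth)
        r = response_map(stack)
        g = spatial_profile(small_protocol, truth)
        # response is proportional to the spatial profile
        ratio = r[g > 0.2] / g[g > 0.2]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-6)
        assert ratio.mean() < 0  # reflectance decrease
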