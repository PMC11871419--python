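"""Activity maps, blob detection, trace extraction, background."""

import numpy as np
import pytest

import synflux as sf
from synflux import simkit
from synflux.imagio import StimulusProtocol
from synflux.puncta import NoPunctaError

from _synthutil import grid_centers as _grid_centers
from _synthutil import match_rate
from _synthutil import stamp_field as _stamp_field


def _protocol(n_frames=30):
    return StimulusProtocol(
        frame_rate_hz=1.0, n_frames=n_frames, baseline_frames=(1, 5),
        activity_baseline=(1, 5), activity_response=(10, n_frames),
    )


class TestActivityMap:
    def test_static_stack_gives_zero_map(self):
        stack = sf.ImageStack(np.full((30, 32, 32), 7.0), frame_rate_hz=1.0)
        assert np.all(sf.activity_map(stack, _protocol()) == 0.0)

    def test_single_punctum_peak_equals_brightness_times_kinetic(self):
        truth = simkit.GroundTruth("syphy", [(16.0, 16.0)], [400.0],
                                   background_level=5.0, bleach_tau=None)
        cfg = simkit.SimConfig(shape=(64, 64), n_puncta=(1, 1), poisson=False,
                               read_noise_sigma=0.0, bleach_tau_frames=None)
        k = 0.37
        kin = np.concatenate([np.zeros(9), np.full(21, k)])
        stack = simkit.render_stack(truth, kin, cfg)
        amap = sf.activity_map(stack, _protocol())
        assert amap.max() == pytest.approx(400.0 * k, rel=1e-6)

    def test_short_response_window_uses_remaining_frames(self, caplog):
        stack = sf.ImageStack(np.ones((20, 16, 16)), frame_rate_hz=1.0)
        prot = StimulusProtocol(frame_rate_hz=1.0, n_frames=20,
                                baseline_frames=(1, 5),
                                activity_baseline=(1, 5),
                                activity_response=(10, 20))
        prot.n_frames = 15          # pretend the stack was truncated
        stack = sf.ImageStack(np.ones((15, 16, 16)), frame_rate_hz=1.0)
        with caplog.at_level("WARNING"):
            amap = sf.activity_map(stack, prot)
        assert amap.shape == (16, 16)


class TestDetection:
    def test_recall_and_precision_on_snr10_field(self):
        rng = np.random.default_rng(5)
        centers = _grid_centers()[:150]
        amap = _stamp_field(centers, amplitude=10.0, rng=rng, noise_sd=1.0)
        pset = sf.detect_puncta(amap)
        recall, precision = match_rate(pset.centers, np.array(centers))
        assert recall >= 0.9
        assert precision >= 0.9

    def test_all_zero_map_is_no_puncta_error(self):
        with pytest.raises(NoPunctaError, match="no responding puncta"):
            sf.detect_puncta(np.zeros((64, 64)))

    def test_detection_invariant_to_scaling_and_offset(self):
        rng = np.random.default_rng(6)
        amap = _stamp_field(_grid_centers()[:40], 10.0, rng=rng, noise_sd=1.0)
        ref = sf.detect_puncta(amap).centers
        for transformed in (amap * 17.3, amap + 5.0, amap * 0.02 + 1.0):
            got = sf.detect_puncta(transformed).centers
            np.testing.assert_array_equal(got, ref)

    def test_f1_non_decreasing_in_snr(self):
        centers = _grid_centers()[:100]
        f1s = []
        for snr in (5.0, 10.0, 20.0):
            rng = np.random.default_rng(99)
            amap = _stamp_field(centers, amplitude=snr, rng=rng, noise_sd=1.0)
            try:
                r, p = match_rate(sf.detect_puncta(amap).centers,
                                  np.array(centers))
                f1s.append(2 * r * p / (r + p))
            except NoPunctaError:
                f1s.append(0.0)
        assert f1s[0] <= f1s[1] <= f1s[2]

    def test_activity_map_maxima_colocalize_with_truth(self, ctrl):
        """On a default simulated field, detections land within 2 px of
        >= 90% generator centers they claim to match."""
        cfg = sf.default_config("syphy", shape=(128, 128), n_puncta=(40, 50))
        stack, truth, prot = simkit.simulate_recording("syphy", ctrl, cfg=cfg,
                                                       seed=2)
        pset = sf.detect_puncta(sf.activity_map(stack, prot))
        recall, precision = match_rate(pset.centers, truth.centers)
        assert precision >= 0.9


class TestTraces:
    def test_uniform_image_gives_constant_traces(self):
        stack = sf.ImageStack(np.full((6, 32, 32), 3.5), frame_rate_hz=1.0)
        pset = sf.extract_traces(stack, [(10, 10), (20, 20)], radius=3.0)
        assert np.all(pset.traces == 3.5)

    def test_trace_is_affine_in_kinetic_with_perfect_correlation(self):
        s = np.concatenate([np.zeros(5), np.linspace(0, 1, 10), np.ones(5)])
        truth = simkit.GroundTruth("x", [(20.0, 20.0)], [300.0],
                                   background_level=12.0, bleach_tau=None)
        cfg = simkit.SimConfig(shape=(64, 64), n_puncta=(1, 1), poisson=False,
                               read_noise_sigma=0.0, bleach_tau_frames=None)
        stack = simkit.render_stack(truth, 1.0 + s, cfg)
        pset = sf.extract_traces(stack, truth.centers, radius=3.0)
        trace = pset.traces[0]
        r = np.corrcoef(trace, s)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        slope = np.polyfit(s, trace, 1)[0]
        assert slope > 0

    def test_radius_zero_samples_single_pixel(self):
        data = np.arange(4 * 16 * 16, dtype=float).reshape(4, 16, 16)
        stack = sf.ImageStack(data, frame_rate_hz=1.0)
        pset = sf.extract_traces(stack, [(5, 7)], radius=0.0)
        np.testing.assert_array_equal(pset.traces[0], data[:, 5, 7])

    def test_edge_clipped_roi_is_dropped(self):
        stack = sf.ImageStack(np.ones((3, 32, 32)), frame_rate_hz=1.0)
        pset = sf.extract_traces(stack, [(1, 1), (16, 16)], radius=3.0)
        assert pset.n_puncta == 1

    def test_mean_trace_arithmetic_and_permutation(self):
        pset = sf.PunctaSet(centers=[(1, 1), (2, 2)],
                            traces=np.array([[1., 2., 3.], [3., 2., 1.]]))
        np.testing.assert_array_equal(sf.mean_trace(pset), [2., 2., 2.])
        perm = sf.PunctaSet(centers=[(2, 2), (1, 1)],
                            traces=pset.traces[::-1])
        np.testing.assert_array_equal(sf.mean_trace(perm), sf.mean_trace(pset))

    def test_single_punctum_mean_is_identity(self):
        pset = sf.PunctaSet(centers=[(1, 1)], traces=np.array([[4., 5.]]))
        np.testing.assert_array_equal(sf.mean_trace(pset), [4., 5.])


class TestBackground:
    def _field(self, bg=50.0, amp=400.0):
        centers = [(20, 20), (40, 40), (20, 44)]
        img = _stamp_field(centers, amp, shape=(64, 64)) + bg
        stack = sf.ImageStack(np.repeat(img[None], 3, axis=0), frame_rate_hz=1.0)
        return stack, sf.PunctaSet(centers=np.array(centers, dtype=float),
                                   radius=3.0)

    def test_recovers_constant_background(self):
        stack, pset = self._field(bg=50.0)
        assert sf.estimate_background(stack, pset) == pytest.approx(50.0,
                                                                    rel=0.01)

    def test_zero_background_render(self):
        stack, pset = self._field(bg=0.0)
        assert sf.estimate_background(stack, pset) < 1.0

    def test_independent_of_foreground_scaling(self):
        s1, pset = self._field(amp=400.0)
        s2, _ = self._field(amp=4000.0)
        b1 = sf.estimate_background(s1, pset)
        b2 = sf.estimate_background(s2, pset)
        assert abs(b2 - b1) / b1 < 0.01

    def test_saturated_foreground_is_an_error(self):
        stack = sf.ImageStack(np.ones((3, 16, 16)), frame_rate_hz=1.0)
        centers = np.array(_grid_centers((16, 16), spacing=4, margin=4),
                           dtype=float)
        pset = sf.PunctaSet(centers=centers, radius=5.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            sf.estimate_background(stack, pset, dilation_px=4)
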