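"""Paired-pulse rule, transient amplitudes, percent-change arithmetic."""

import numpy as np
import pytest

import synflux as sf
from synflux.imagio import StimulusEvent, StimulusProtocol
from synflux.simkit import ppr_at_calcium
from synflux.transients import (
    epoch_baseline,
    glutamate_change,
    paired_pulse_metrics,
    transient_amplitudes,
)


def pp_protocol(f1=101, gap=6, n_frames=200, fps=60.0):
    return StimulusProtocol(
        frame_rate_hz=fps, n_frames=n_frames, baseline_frames=(1, f1 - 1),
        stimuli=[StimulusEvent(f1, 1, 10.0), StimulusEvent(f1 + gap, 1, 10.0)],
        stimulus_kinds=["pair1", "pair2"],
        pp_interval_ms=gap / fps * 1000.0,
        peak_search_ms=80.0,
    )


class TestEpochBaseline:
    def test_constant_baseline(self):
        trace = np.full(100, 100.0)
        assert epoch_baseline(trace, 60) == 100.0

    def test_linear_ramp_mean(self):
        trace = np.concatenate([np.arange(1.0, 51.0), np.zeros(10)])
        assert epoch_baseline(trace, 51) == pytest.approx(25.5)

    def test_stimulus_at_first_frame_is_error(self):
        with pytest.raises(ValueError, match="baseline"):
            epoch_baseline(np.ones(10), 1)

    def test_short_baseline_uses_available_frames(self):
        trace = np.concatenate([np.full(20, 7.0), np.zeros(10)])
        assert epoch_baseline(trace, 21) == 7.0


class TestPairedPulse:
    def test_printed_accumulation_rule_arithmetic(self):
        """P1 raw 0.40 over baseline, trough 0.10, raw P2 0.55:
        corrected P2 = 0.45 and PPR = 1.125 exactly (F0 = 1)."""
        prot = pp_protocol()
        trace = np.ones(200)
        f1, f2 = 100, 106
        trace[f1 + 1] = 1.40
        trace[f1 + 2:f2] = 1.10           # inter-peak trough
        trace[f2 + 1] = 1.55
        m = paired_pulse_metrics(trace, prot)
        assert m.p1_amp == pytest.approx(0.40)
        assert m.p2_amp == pytest.approx(0.45)
        assert m.ppr == pytest.approx(1.125)

    def test_identical_full_decay_peaks_give_unity_ppr(self):
        prot = pp_protocol()
        trace = np.ones(200)
        for f in (100, 106):              # symmetric triangular peaks
            trace[f + 1] = 2.0
            trace[f + 2] = 1.5
        m = paired_pulse_metrics(trace, prot)
        assert m.ppr == pytest.approx(1.0)

    def test_full_decay_equals_naive_baseline_subtraction(self):
        """When the trace returns to baseline between pulses, the
        trough-corrected P2 equals the baseline-subtracted P2."""
        prot = pp_protocol()
        trace = np.ones(200)
        trace[101] = 1.8
        trace[107] = 2.1
        m = paired_pulse_metrics(trace, prot)
        assert m.p2_amp == pytest.approx(2.1 - 1.0)

    def test_ppr_invariant_to_scale_and_offset(self):
        prot = pp_protocol()
        rng = np.random.default_rng(3)
        trace = np.ones(200) + 0.01 * rng.standard_normal(200)
        trace[101], trace[107] = 1.9, 1.7
        ref = paired_pulse_metrics(trace, prot).ppr
        got = paired_pulse_metrics(trace * 12.0 + 30.0, prot).ppr
        assert got == pytest.approx(ref, rel=1e-12)

    def test_weak_epochs_are_discarded_and_all_weak_is_error(self):
        prot = pp_protocol()
        rng = np.random.default_rng(1)
        trace = np.ones(200) + 0.05 * rng.standard_normal(200)
        with pytest.raises(ValueError, match="discarded"):
            paired_pulse_metrics(trace, prot)

    def test_epoch_averaging_over_three_epochs(self, ctrl):
        prot = sf.iglusnfr_protocol()
        trace = np.ones(prot.n_frames)
        pairs = [(s.frame - 1, prot.stimuli[i + 1].frame - 1)
                 for i, s in enumerate(prot.stimuli)
                 if prot.stimulus_kinds[i] == "pair1"]
        for (f1, f2) in pairs:
            trace[f1 + 1] = 2.0
            trace[f2 + 1] = 1.8
        m = paired_pulse_metrics(trace, prot)
        assert len(m.epoch_ppr) == 3


class TestTransientAmplitudes:
    def _single_prot(self):
        return StimulusProtocol(
            frame_rate_hz=15.0, n_frames=400, baseline_frames=(1, 225),
            stimuli=[StimulusEvent(226, 1, 0.1), StimulusEvent(376, 1, 0.1)],
            stimulus_kinds=["single", "single"],
            peak_search_ms=300.0,
        )

    def test_flat_trace_gives_zero_amplitudes(self):
        a = transient_amplitudes(np.full(400, 5.0), self._single_prot())
        assert a.single_amp == 0.0

    def test_peak_df_over_f0(self):
        prot = self._single_prot()
        trace = np.full(400, 2.0)
        trace[226] = 3.0                 # dF/F0 = 0.5
        trace[376] = 4.0                 # dF/F0 = 1.0
        a = transient_amplitudes(trace, prot)
        assert a.single_amp == pytest.approx(0.75)

    def test_overlapping_windows_rejected(self):
        prot = StimulusProtocol(
            frame_rate_hz=15.0, n_frames=300, baseline_frames=(1, 100),
            stimuli=[StimulusEvent(110, 1, 0.1), StimulusEvent(112, 1, 0.1)],
            stimulus_kinds=["single", "single"],
            peak_search_ms=300.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            transient_amplitudes(np.full(300, 1.0), prot)


class TestGlutamateChange:
    def test_printed_percent_change(self):
        assert glutamate_change([1.0], [1.7]) == pytest.approx(70.0)

    def test_identical_samples_give_zero(self):
        assert glutamate_change([0.5, 1.5], [1.0, 1.0]) == pytest.approx(0.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            glutamate_change([0.0], [1.0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            glutamate_change([], [1.0])


def test_low_calcium_raises_ppr_for_every_preset():
    """The depletion/facilitation rule makes the paired-pulse ratio rise
    when external calcium (release probability) drops."""
    for name in sf.registered_conditions():
        mu = sf.make_preset(name).ppr_mu
        assert ppr_at_calcium(mu, 0.55) > mu
        assert ppr_at_calcium(mu, 1.0) == pytest.approx(mu)
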