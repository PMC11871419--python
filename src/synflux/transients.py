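"""Paired-pulse glutamate metrics and evoked calcium amplitudes.

Works on the background-subtracted mean punctum trace of a recording.
For paired pulses (two field stimuli 100 ms apart): the first-peak
amplitude P1 is the post-pulse maximum minus the epoch baseline (mean of
the 50 frames preceding the first pulse); because the indicator has not
fully decayed when the second pulse arrives, the trough between the two
peaks is subtracted from the raw second peak to obtain the
accumulation-corrected P2; the paired-pulse ratio is P2/P1.  Amplitudes
are expressed as dF/F0 with F0 the epoch baseline.  Per-recording values
are means over the recording's epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imagio import StimulusProtocol

__all__ = [
    "PairedPulseMetrics",
    "TransientAmplitudes",
    "epoch_baseline",
    "paired_pulse_metrics",
    "transient_amplitudes",
    "quantify_iglusnfr",
    "quantify_gcamp",
    "glutamate_change",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedPulseMetrics:
    """Per-recording paired-pulse readout (dF/F0 units)."""

    recording_id: str
    condition: str
    p1_amp: float
    p2_amp: float
    ppr: float
    epoch_p1: list[float] = field(default_factory=list)
    epoch_p2: list[float] = field(default_factory=list)
    epoch_ppr: list[float] = field(default_factory=list)


@dataclass
class TransientAmplitudes:
    """Mean peak dF/F0 per stimulation type for one recording."""

    recording_id: str
    condition: str
    single_amp: float = float("nan")
    pair_amp: float = float("nan")
    burst_amp: float = float("nan")


def epoch_baseline(trace: np.ndarray, stim_frame: int,
                   n_frames: int = 50) -> float:
    """Mean of the ``n_frames`` frames immediately preceding a 1-based
    stimulus frame (all available frames if fewer, with a log note)."""
    trace = np.asarray(trace, dtype=float)
    if stim_frame <= 1:
        raise ValueError(f"stimulus frame {stim_frame} leaves no baseline")
    start = stim_frame - 1 - n_frames
    if start < 0:
        logger.info("only %d baseline frames precede stimulus at frame %d "
                    "(wanted %d)", stim_frame - 1, stim_frame, n_frames)
        start = 0
    return float(trace[start:stim_frame - 1].mean())


def _search_frames(protocol: StimulusProtocol) -> int:
    return max(1, round(protocol.peak_search_ms * protocol.frame_rate_hz / 1000.0))


def _pairs(protocol: StimulusProtocol) -> list[tuple[int, int]]:
    """0-based (pulse1, pulse2) frame indices of each paired-pulse epoch."""
    kinds = protocol.stimulus_kinds
    pairs = []
    if kinds:
        for i, k in enumerate(kinds):
            if k == "pair1":
                pairs.append((protocol.stimuli[i].frame - 1,
                              protocol.stimuli[i + 1].frame - 1))
    elif protocol.pp_interval_ms is not None:
        # untagged protocols: consecutive single-AP stimuli one PP interval apart
        gap = round(protocol.pp_interval_ms * protocol.frame_rate_hz / 1000.0)
        ev = [s.frame - 1 for s in protocol.stimuli]
        i = 0
        while i + 1 < len(ev):
            if ev[i + 1] - ev[i] == gap:
                pairs.append((ev[i], ev[i + 1]))
                i += 2
            else:
                i += 1
    if not pairs:
        raise ValueError("protocol contains no paired-pulse epochs")
    return pairs


def paired_pulse_metrics(
    trace: np.ndarray,
    protocol: StimulusProtocol,
    noise_floor_sd: float = 3.0,
    discard_weak_epochs: bool = True,
    recording_id: str = "",
    condition: str = "",
) -> PairedPulseMetrics:
    """Paired-pulse amplitudes and ratio from a background-subtracted
    mean trace.

    Per epoch: P1 = max in the post-pulse-1 search window minus the epoch
    baseline; the trough between the P1 peak and the pulse-2 frame is
    subtracted from the raw second-peak maximum to give P2; PPR = P2/P1.
    Amplitudes are reported as dF/F0 with F0 = epoch baseline.  Epochs
    whose P1 is below ``noise_floor_sd`` baseline SDs are discarded with
    a log entry (disable with ``discard_weak_epochs=False``); if every
    epoch fails, an error is raised.
    """
    trace = np.asarray(trace, dtype=float)
    w = _search_frames(protocol)
    p1s, p2s, pprs = [], [], []
    for (f1, f2) in _pairs(protocol):
        base_frames = trace[max(0, f1 - protocol.n_baseline_frames_epoch):f1]
        f0 = float(base_frames.mean())
        base_sd = float(base_frames.std(ddof=0))
        if f0 <= 0:
            raise ValueError(
                f"epoch baseline F0 = {f0:.3g} is not positive; was the "
                "background subtracted?"
            )
        w1 = trace[f1:f1 + w + 1]
        p1_peak_idx = f1 + int(np.argmax(w1))
        p1_raw = float(w1.max())
        p1 = p1_raw - f0
        if discard_weak_epochs and p1 < noise_floor_sd * base_sd:
            logger.info("epoch at frame %d discarded: P1 = %.3g below %.1f "
                        "baseline SD", f1 + 1, p1, noise_floor_sd)
            continue
        trough = float(trace[p1_peak_idx:f2].min()) if f2 > p1_peak_idx \
            else float(trace[p1_peak_idx])
        p2_raw = float(trace[f2:f2 + w + 1].max())
        p2 = p2_raw - trough
        p1s.append(p1 / f0)
        p2s.append(p2 / f0)
        pprs.append(p2 / p1)
    if not p1s:
        raise ValueError("all paired-pulse epochs were discarded (P1 below "
                         "noise floor)")
    return PairedPulseMetrics(
        recording_id=recording_id, condition=condition,
        p1_amp=float(np.mean(p1s)), p2_amp=float(np.mean(p2s)),
        ppr=float(np.mean(pprs)),
        epoch_p1=p1s, epoch_p2=p2s, epoch_ppr=pprs,
    )


def transient_amplitudes(
    trace: np.ndarray,
    protocol: StimulusProtocol,
    recording_id: str = "",
    condition: str = "",
) -> TransientAmplitudes:
    """Peak dF/F0 per stimulus, averaged per stimulation type.

    Single stimuli: peak in the post-stimulus search window relative to
    the pre-stimulus baseline.  Bursts: peak between burst onset and
    burst end + search window.  Paired stimuli: raw accumulated peak of
    the paired response above the epoch baseline.  Search windows of
    successive stimuli must not overlap.
    """
    trace = np.asarray(trace, dtype=float)
    fps = protocol.frame_rate_hz
    w = _search_frames(protocol)
    kinds = protocol.stimulus_kinds or ["single"] * len(protocol.stimuli)
    if len(kinds) != len(protocol.stimuli):
        raise ValueError("stimulus_kinds length must match stimuli")

    windows: list[tuple[str, int, int]] = []   # (type, start0, stop0_excl)
    i = 0
    while i < len(protocol.stimuli):
        s = protocol.stimuli[i]
        f = s.frame - 1
        kind = kinds[i]
        if kind == "single":
            windows.append(("single", f, f + w + 1))
            i += 1
        elif kind == "burst":
            dur = max(1, round(s.n_ap / s.freq_hz * fps))
            windows.append(("burst", f, f + dur + w + 1))
            i += 1
        elif kind == "pair1":
            f2 = protocol.stimuli[i + 1].frame - 1
            windows.append(("pair", f, f2 + w + 1))
            i += 2
        else:
            raise ValueError(f"unknown stimulus kind {kind!r}")
    for (_, a1, b1), (_, a2, _) in zip(windows, windows[1:]):
        if a2 < b1:
            raise ValueError("overlapping peak-search windows between "
                             "successive stimuli")

    amps: dict[str, list[float]] = {"single": [], "pair": [], "burst": []}
    for kind, a, b in windows:
        f0 = epoch_baseline(trace, a + 1, protocol.n_baseline_frames_epoch)
        if f0 <= 0:
            raise ValueError(f"epoch baseline F0 = {f0:.3g} is not positive")
        peak = float(trace[a:min(b, len(trace))].max())
        amps[kind].append((peak - f0) / f0)

    def _mean(xs):
        return float(np.mean(xs)) if xs else float("nan")

    return TransientAmplitudes(
        recording_id=recording_id, condition=condition,
        single_amp=_mean(amps["single"]),
        pair_amp=_mean(amps["pair"]),
        burst_amp=_mean(amps["burst"]),
    )


def quantify_iglusnfr(
    stack,
    protocol: StimulusProtocol,
    detection=None,
    roi_radius: float = 3.0,
    recording_id: str = "",
    condition: str = "",
) -> PairedPulseMetrics:
    """Full paired-pulse pipeline for one glutamate recording: detect
    release sites on the first-epoch activity map, extract and average
    ROI traces, subtract background, and compute paired-pulse metrics."""
    from .puncta import (activity_map, detect_puncta, estimate_background,
                         extract_traces, mean_trace)

    amap = activity_map(stack, protocol)
    pset = detect_puncta(amap, detection)
    pset = extract_traces(stack, pset.centers, roi_radius)
    trace = mean_trace(pset) - estimate_background(stack, pset)
    return paired_pulse_metrics(trace, protocol, recording_id=recording_id,
                                condition=condition)


def quantify_gcamp(
    stack,
    protocol: StimulusProtocol,
    detection=None,
    roi_radius: float = 3.0,
    recording_id: str = "",
    condition: str = "",
) -> TransientAmplitudes:
    """Full evoked-calcium pipeline for one recording: detect puncta on
    the first-to-last-stimulus activity map, average ROI traces, subtract
    background, and measure per-stimulus-type peak dF/F0."""
    from .puncta import (activity_map, detect_puncta, estimate_background,
                         extract_traces, mean_trace)

    amap = activity_map(stack, protocol)
    pset = detect_puncta(amap, detection)
    pset = extract_traces(stack, pset.centers, roi_radius)
    trace = mean_trace(pset) - estimate_background(stack, pset)
    return transient_amplitudes(trace, protocol, recording_id=recording_id,
                                condition=condition)


def glutamate_change(ctrl_p1s, drug_p1s) -> float:
    """Percent change of the mean first-peak amplitude, drug vs control:
    ``100 * (mean(drug) / mean(ctrl) - 1)``."""
    ctrl = np.asarray(ctrl_p1s, dtype=float)
    drug = np.asarray(drug_p1s, dtype=float)
    if ctrl.size == 0 or drug.size == 0:
        raise ValueError("both samples must be non-empty")
    mc = ctrl.mean()
    if mc <= 0:
        raise ValueError(f"control mean P1 = {mc:.3g} is not positive")
    return float(100.0 * (drug.mean() / mc - 1.0))
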