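"""Vesicle-pool quantification from sypHy recordings.

A recording's mean punctum trace is background-subtracted, corrected for
photobleaching against a paired no-stimulation recording, normalized
between the baseline level (F_min) and the NH4Cl plateau (F_max) with
(F - F_min) / (F_max - F_min), and the readily releasable and total
recycling pool fractions are read off as window means of the normalized
trace.  In bafilomycin the trace is cumulative, so the windows sit on
plateaus: the RRP window follows the 40 AP train and the TRP window the
900 AP train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .imagio import ImageStack, StimulusProtocol
from .puncta import (
    DetectionParams,
    activity_map,
    detect_puncta,
    estimate_background,
    extract_traces,
    mean_trace,
)

__all__ = [
    "NormalizedTrace",
    "PoolFractions",
    "bleach_correct",
    "fit_bleach_tau",
    "normalize",
    "pool_fractions",
    "quantify_syphy",
]

logger = logging.getLogger(__name__)

# a fitted bleaching time constant longer than this many recording lengths
# is treated as "no measurable bleaching" (identity correction)
_TAU_IDENTITY_FACTOR = 50.0


@dataclass
class NormalizedTrace:
    """Fluorescence normalized to the 0 (baseline) .. 1 (NH4Cl) range."""

    values: np.ndarray
    f_min: float
    f_max: float
    fmin_window: tuple[int, int]
    fmax_window: tuple[int, int]


@dataclass
class PoolFractions:
    """Pool sizes as fractions of the total sensor-expressing pool."""

    recording_id: str
    condition: str
    rrp: float
    trp: float


def fit_bleach_tau(nostim_trace: np.ndarray) -> float:
    """Fit a single exponential ``a * exp(-t/tau)`` to a no-stimulation
    mean trace (background already subtracted) and return tau in frames.

    Raises on non-finite input, non-positive fitted tau, or divergence.
    Returns ``inf`` for traces with no measurable decay.
    """
    y = np.asarray(nostim_trace, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("no-stimulation trace contains non-finite values")
    if np.any(y <= 0):
        raise ValueError("no-stimulation trace must be strictly positive after "
                         "background subtraction")
    T = len(y)
    t = np.arange(T, dtype=float)
    # log-linear initial guess
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0 or -1.0 / slope > _TAU_IDENTITY_FACTOR * T:
        return float("inf")
    p0 = (float(np.exp(intercept)), float(-1.0 / slope))
    try:
        (a, tau), _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau), t, y, p0=p0, maxfev=10000
        )
    except RuntimeError as e:
        raise RuntimeError(f"bleaching fit did not converge: {e}") from e
    if tau <= 0:
        raise RuntimeError(
            f"bleaching fit returned non-positive tau = {tau:.3g} "
            f"(amplitude a = {a:.3g})"
        )
    if tau > _TAU_IDENTITY_FACTOR * T:
        return float("inf")
    return float(tau)


def bleach_correct(trace: np.ndarray, nostim_trace: np.ndarray) -> np.ndarray:
    """Divide a trace by the bleaching factor fitted to a no-stimulation
    reference.

    The factor is ``b(t) = exp(-t/tau)`` normalized to 1 at the first
    frame; a reference with no measurable decay yields the identity.
    """
    trace = np.asarray(trace, dtype=float)
    nostim_trace = np.asarray(nostim_trace, dtype=float)
    if trace.shape != nostim_trace.shape:
        raise ValueError("trace and no-stimulation trace must have equal length")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    tau = fit_bleach_tau(nostim_trace)
    if np.isinf(tau):
        return trace.copy()
    t = np.arange(len(trace), dtype=float)
    return trace / np.exp(-t / tau)


def normalize(trace: np.ndarray, protocol: StimulusProtocol,
              floor_sd_factor: float = 3.0) -> NormalizedTrace:
    """Normalize a (background-subtracted, bleach-corrected) trace to
    (F - F_min) / (F_max - F_min).

    F_min is the mean over the protocol's F_min window (early baseline
    frames) and F_max the mean over the NH4Cl window.  If the dynamic
    range F_max - F_min does not exceed ``floor_sd_factor`` baseline
    standard deviations there was no NH4Cl response and normalization is
    refused.
    """
    trace = np.asarray(trace, dtype=float)
    fmin_win = protocol.fmin_window or protocol.baseline_frames
    if protocol.nh4cl_frames is None:
        raise ValueError("protocol has no NH4Cl window; F_max undefined")
    base = trace[protocol.sl(fmin_win)]
    f_min = float(base.mean())
    f_max = float(trace[protocol.sl(protocol.nh4cl_frames)].mean())
    floor = floor_sd_factor * float(base.std(ddof=0))
    if f_max - f_min <= floor:
        raise ValueError(
            f"no NH4Cl response: F_max - F_min = {f_max - f_min:.3g} is not "
            f"above {floor_sd_factor} baseline SD ({floor:.3g})"
        )
    values = (trace - f_min) / (f_max - f_min)
    return NormalizedTrace(values=values, f_min=f_min, f_max=f_max,
                           fmin_window=tuple(fmin_win),
                           fmax_window=tuple(protocol.nh4cl_frames))


def pool_fractions(norm: NormalizedTrace | np.ndarray,
                   protocol: StimulusProtocol,
                   recording_id: str = "", condition: str = "") -> PoolFractions:
    """Window means of the normalized trace: RRP and TRP fractions."""
    values = norm.values if isinstance(norm, NormalizedTrace) else np.asarray(norm)
    if protocol.rrp_window is None or protocol.trp_window is None:
        raise ValueError("protocol does not define RRP/TRP windows")
    T = len(values)
    for name, win in (("rrp_window", protocol.rrp_window),
                      ("trp_window", protocol.trp_window)):
        if win[1] > T:
            raise ValueError(f"{name}=[{win[0]}, {win[1]}] outside trace of "
                             f"{T} frames")
    rrp = float(values[protocol.sl(protocol.rrp_window)].mean())
    trp = float(values[protocol.sl(protocol.trp_window)].mean())
    return PoolFractions(recording_id=recording_id, condition=condition,
                         rrp=rrp, trp=trp)


def quantify_syphy(
    stack: ImageStack,
    nostim_stack: ImageStack,
    protocol: StimulusProtocol,
    detection: DetectionParams | None = None,
    roi_radius: float = 3.0,
    recording_id: str = "",
    condition: str = "",
) -> PoolFractions:
    """Full vesicle-pool pipeline for one recording.

    detect (activity map + blob detector) -> extract ROI traces ->
    average -> subtract background -> bleach-correct against the paired
    no-stimulation stack (same ROIs) -> normalize to baseline/NH4Cl ->
    RRP/TRP window means.  Errors from any stage are re-raised with the
    stage name attached.
    """
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise type(e)(f"[{name}] {e}") from e

    amap = _stage("activity_map", activity_map, stack, protocol)
    pset = _stage("detect_puncta", detect_puncta, amap, detection)
    pset = _stage("extract_traces", extract_traces, stack, pset.centers, roi_radius)
    trace = mean_trace(pset)
    bg = _stage("estimate_background", estimate_background, stack, pset)
    trace = trace - bg

    nset = _stage("extract_traces", extract_traces, nostim_stack, pset.centers,
                  roi_radius)
    nbg = _stage("estimate_background", estimate_background, nostim_stack, nset)
    nostim = mean_trace(nset) - nbg

    corrected = _stage("bleach_correct", bleach_correct, trace, nostim)
    norm = _stage("normalize", normalize, corrected, protocol)
    return pool_fractions(norm, protocol, recording_id=recording_id,
                          condition=condition)
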