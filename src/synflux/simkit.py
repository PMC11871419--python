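"""Synthetic fluorescence-movie generator with known ground truth.

Renders time-lapse movies of cultured-neuron fields expressing one of
three presynaptic sensors, plus immunocytochemistry (ICC) still images,
under the acquisition regimes of the quantification pipeline:

* ``syphy`` — vesicle-pool measurement at 1 frame/s: 15 s baseline,
  40 AP @ 20 Hz (readily releasable pool), 900 AP @ 20 Hz (total
  recycling pool, in bafilomycin so the signal is cumulative), terminal
  NH4Cl pulse unquenching the whole pool.
* ``syphy_nostim`` — the same field with no stimulation (photobleaching
  reference).
* ``iglusnfr`` — glutamate transients at 60 frames/s: 6 s baseline, then
  three paired-pulse epochs (pulses 100 ms apart, 10 s recovery).
* ``gcamp_single`` / ``gcamp_pp`` / ``gcamp_burst`` — presynaptic
  calcium transients: 5 single stimuli at 0.1 Hz (15 fps), paired
  stimuli 100 ms apart at 0.1 Hz (83 fps), or one 30 AP @ 40 Hz burst
  (15 fps), each after a 15 s baseline.

Each punctum is an isotropic Gaussian spot whose amplitude follows a
per-punctum kinetic series; frames are background + signal, multiplied
by exponential photobleaching, with Poisson shot noise and Gaussian read
noise.  Per-recording parameters are drawn around the condition preset's
means with the preset's between-recording CV, so cohorts of simulated
recordings scatter like published ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imagio import ImageStack, StimulusEvent, StimulusProtocol
from .presets import ConditionPreset

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_config",
    "syphy_protocol",
    "iglusnfr_protocol",
    "gcamp_protocol",
    "syphy_punctum_trace",
    "render_stack",
    "simulate_recording",
    "simulate_icc_image",
    "MODALITIES",
]

MODALITIES = (
    "syphy", "syphy_nostim", "iglusnfr", "gcamp_single", "gcamp_pp", "gcamp_burst",
)

# first-order release time constants (seconds); release occurs during the
# stimulus train and the rise is normalized to saturate exactly at train end,
# so the downstream analysis windows sit on plateaus
TAU_RRP_S = 1.0
TAU_TRP_S = 15.0
# sensor decay time constants (seconds)
TAU_GLU_S = 0.08
TAU_CA_S = 0.5
# resting (quenched) sypHy fluorescence as a fraction of the unquenched level
QUENCHED_FRACTION = 0.15
# baseline release probability entering the two-pulse depletion/facilitation
# rule used by the external-calcium hook (PPR = phi * (1 - p))
P_RELEASE_BASE = 0.35


@dataclass
class SimConfig:
    """Rendering configuration for one synthetic field."""

    shape: tuple[int, int] = (256, 256)
    psf_sigma: float = 1.5
    n_puncta: tuple[int, int] = (100, 200)
    min_separation: float = 6.0
    edge_margin: int = 8
    punctum_peak: float = 600.0          # mean peak counts at full signal
    punctum_peak_cv: float = 0.3
    background: float = 100.0            # non-bleaching offset (counts)
    bleach_tau_frames: float | None = 300.0
    poisson: bool = True
    read_noise_sigma: float = 2.0
    bit_depth: int = 16
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.shape) < 64:
            raise ValueError("field must be at least 64 x 64 pixels")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.n_puncta[0] < 1 or self.n_puncta[1] < self.n_puncta[0]:
            raise ValueError("n_puncta must be a range with lower bound >= 1")

    @property
    def noise_free(self) -> bool:
        return not self.poisson and self.read_noise_sigma == 0


def default_config(modality: str, **overrides) -> SimConfig:
    """Per-modality default configuration.

    Field sizes and punctum counts follow the acquisition regime each
    sensor is imaged under: ~100-200 sypHy puncta on a 256 px field,
    30-80 glutamate release sites on a 96 px crop, 150-250 calcium
    puncta on a 128 px crop.
    """
    # photobleaching has a fixed time constant in illumination time
    # (~300 s), so its value in frames scales with the acquisition rate
    if modality in ("syphy", "syphy_nostim"):
        kw = dict(shape=(256, 256), n_puncta=(100, 200), punctum_peak=600.0,
                  background=100.0, min_separation=6.0,
                  bleach_tau_frames=300.0)
    elif modality == "iglusnfr":
        kw = dict(shape=(128, 128), n_puncta=(30, 80), punctum_peak=300.0,
                  background=80.0, min_separation=6.0,
                  bleach_tau_frames=300.0 * 60.0)
    elif modality == "gcamp_pp":
        kw = dict(shape=(256, 256), n_puncta=(150, 250), punctum_peak=300.0,
                  background=80.0, min_separation=6.0,
                  bleach_tau_frames=300.0 * 83.0)
    elif modality.startswith("gcamp"):
        kw = dict(shape=(256, 256), n_puncta=(150, 250), punctum_peak=300.0,
                  background=80.0, min_separation=6.0,
                  bleach_tau_frames=300.0 * 15.0)
    else:
        raise ValueError(f"unknown modality {modality!r}; known: {MODALITIES}")
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass
class GroundTruth:
    """What the generator actually put into a rendered field."""

    modality: str
    centers: np.ndarray                      # (P, 2) row, col
    brightness: np.ndarray                   # (P,) peak counts at full signal
    background_level: float
    bleach_tau: float | None
    params: dict = field(default_factory=dict)        # recording-level truths
    per_punctum: dict = field(default_factory=dict)   # per-punctum arrays
    noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.brightness = np.atleast_1d(np.asarray(self.brightness, dtype=float))
        if self.bleach_tau is not None and self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0")

    @property
    def n_puncta(self) -> int:
        return len(self.centers)

    def to_json(self, path: str | Path) -> Path:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x
        d = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        path = Path(path)
        path.write_text(json.dumps(d, indent=1))
        return path


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def syphy_protocol() -> StimulusProtocol:
    """Standard vesicle-pool protocol at 1 frame/s.

    15 s baseline; 40 AP @ 20 Hz at frame 16; 900 AP @ 20 Hz at frame 40
    (45 s train); RRP window frames 23-37; TRP window frames 130-159;
    NH4Cl during the last 15 frames (166-180).  F_min is taken from
    frames 3-13 and the activity map from the 70 frames following the
    900 AP train onset.
    """
    return StimulusProtocol(
        frame_rate_hz=1.0,
        n_frames=180,
        baseline_frames=(1, 15),
        stimuli=[StimulusEvent(16, 40, 20.0), StimulusEvent(40, 900, 20.0)],
        nh4cl_frames=(166, 180),
        rrp_window=(23, 37),
        trp_window=(130, 159),
        fmin_window=(3, 13),
        activity_baseline=(3, 13),
        activity_response=(41, 110),
    )


def iglusnfr_protocol(n_epochs: int = 3) -> StimulusProtocol:
    """Paired-pulse glutamate protocol at 60 frames/s.

    6 s baseline, then ``n_epochs`` paired pulses 100 ms (6 frames)
    apart with 10 s recovery between epochs.
    """
    fps = 60.0
    gap = 6               # 100 ms at 60 fps
    epoch_period = 612    # ~10.2 s
    first = 361
    stimuli, kinds = [], []
    for e in range(n_epochs):
        f1 = first + e * epoch_period
        stimuli += [StimulusEvent(f1, 1, 10.0), StimulusEvent(f1 + gap, 1, 10.0)]
        kinds += ["pair1", "pair2"]
    n_frames = stimuli[-1].frame + 60
    return StimulusProtocol(
        frame_rate_hz=fps,
        n_frames=n_frames,
        baseline_frames=(1, 360),
        stimuli=stimuli,
        stimulus_kinds=kinds,
        pp_interval_ms=100.0,
        peak_search_ms=80.0,
        activity_baseline=(250, 355),
        activity_response=(first, first + 36),
    )


def gcamp_protocol(kind: str, n_epochs: int = 5) -> StimulusProtocol:
    """Presynaptic-calcium protocols.

    ``single``: 15 s baseline + 5 single stimuli at 0.1 Hz, 15 fps.
    ``pp``: 15 s baseline + 5 paired stimuli (100 ms apart) at 0.1 Hz,
    83 fps.  ``burst``: 15 s baseline + 30 AP @ 40 Hz, 15 fps.
    """
    if kind == "single":
        fps, first, period = 15.0, 226, 150
        stimuli = [StimulusEvent(first + e * period, 1, 0.1) for e in range(n_epochs)]
        kinds = ["single"] * n_epochs
        n_frames = stimuli[-1].frame + 75
        search_ms = 300.0
    elif kind == "pp":
        fps, first, period, gap = 83.0, 1246, 830, 8
        stimuli, kinds = [], []
        for e in range(n_epochs):
            f1 = first + e * period
            stimuli += [StimulusEvent(f1, 1, 0.1), StimulusEvent(f1 + gap, 1, 0.1)]
            kinds += ["pair1", "pair2"]
        n_frames = stimuli[-1].frame + 100
        search_ms = 80.0
    elif kind == "burst":
        fps, first = 15.0, 226
        stimuli = [StimulusEvent(first, 30, 40.0)]
        kinds = ["burst"]
        n_frames = first + 90
        search_ms = 300.0
    else:
        raise ValueError(f"unknown gcamp protocol kind {kind!r}")
    baseline_end = stimuli[0].frame - 1
    last = stimuli[-1].frame
    return StimulusProtocol(
        frame_rate_hz=fps,
        n_frames=n_frames,
        baseline_frames=(1, baseline_end),
        stimuli=stimuli,
        stimulus_kinds=kinds,
        pp_interval_ms=100.0 if kind == "pp" else None,
        peak_search_ms=search_ms,
        activity_baseline=(baseline_end - 100, baseline_end - 5),
        activity_response=(stimuli[0].frame, min(last + 30, n_frames)),
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _saturating_rise(n_frames: int, onset_idx: int, dur_frames: int,
                     tau_frames: float) -> np.ndarray:
    """0 -> 1 first-order rise during a stimulus train, saturating exactly
    at train end (release only happens while stimuli are delivered)."""
    t = np.arange(n_frames, dtype=float)
    x = np.clip(t - onset_idx, 0.0, float(dur_frames))
    return (1.0 - np.exp(-x / tau_frames)) / (1.0 - np.exp(-dur_frames / tau_frames))


def syphy_unquenched_fraction(f_rrp: float, f_trp: float,
                              protocol: StimulusProtocol) -> np.ndarray:
    """Noise-free unquenched-fraction series u(t) for one sypHy recording.

    Monotone non-decreasing (bafilomycin blocks re-acidification): 0 in
    baseline, rising to ``f_rrp`` during the 40 AP train, to ``f_trp``
    during the 900 AP train, and exactly 1 inside the NH4Cl window.
    """
    if protocol.nh4cl_frames is None:
        raise ValueError("protocol has no NH4Cl window; normalization to the "
                         "total pool would be impossible")
    if len(protocol.stimuli) < 2:
        raise ValueError("sypHy protocol needs the RRP and TRP stimulus trains")
    if not 0.0 <= f_rrp <= f_trp <= 1.0:
        raise ValueError("need 0 <= f_rrp <= f_trp <= 1")
    fps = protocol.frame_rate_hz
    T = protocol.n_frames
    s1, s2 = protocol.stimuli[0], protocol.stimuli[1]
    u = np.zeros(T)
    d1 = max(1, round(s1.n_ap / s1.freq_hz * fps))
    d2 = max(1, round(s2.n_ap / s2.freq_hz * fps))
    u += f_rrp * _saturating_rise(T, s1.frame - 1, d1, TAU_RRP_S * fps)
    u += (f_trp - f_rrp) * _saturating_rise(T, s2.frame - 1, d2, TAU_TRP_S * fps)
    u[protocol.sl(protocol.nh4cl_frames)] = 1.0
    return u


def syphy_punctum_trace(
    preset: ConditionPreset,
    protocol: StimulusProtocol | None = None,
    noise_free: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-frame unquenched fraction for one punctum of a given condition.

    With ``noise_free=True`` the preset means are used directly; otherwise
    recording-level pool fractions are drawn with the preset's
    between-recording CV (requires ``rng``).
    """
    if protocol is None:
        protocol = syphy_protocol()
    if noise_free:
        f_rrp, f_trp = preset.f_rrp, preset.f_trp
    else:
        if rng is None:
            raise ValueError("rng is required when noise_free=False")
        f_rrp, f_trp = _draw_pool_fractions(preset, rng)
    return syphy_unquenched_fraction(f_rrp, f_trp, protocol)


def _draw_pool_fractions(preset: ConditionPreset, rng: np.random.Generator
                         ) -> tuple[float, float]:
    f_rrp = rng.normal(preset.f_rrp, preset.cv("f_rrp") * preset.f_rrp)
    f_trp = rng.normal(preset.f_trp, preset.cv("f_trp") * preset.f_trp)
    f_trp = float(np.clip(f_trp, 0.02, 0.98))
    f_rrp = float(np.clip(f_rrp, 0.005, f_trp))
    return f_rrp, f_trp


def _lognormal_mean(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draws with exact mean ``mean`` and coefficient of
    variation ``cv``."""
    if cv <= 0:
        return mean if size is None else np.full(size, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _psf_stamp(sigma: float) -> tuple[np.ndarray, int]:
    r = int(np.ceil(4.0 * sigma))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    return np.exp(-(x**2 + y**2) / (2.0 * sigma**2)), r


def place_centers(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Sequential random placement with a hard minimum pairwise distance."""
    H, W = cfg.shape
    m = cfg.edge_margin
    centers: list[np.ndarray] = []
    min_d2 = cfg.min_separation**2
    attempts = 0
    while len(centers) < n:
        c = np.array([rng.uniform(m, H - 1 - m), rng.uniform(m, W - 1 - m)])
        if centers:
            d2 = np.sum((np.asarray(centers) - c) ** 2, axis=1)
            if d2.min() < min_d2:
                attempts += 1
                if attempts > 200 * n:
                    raise RuntimeError(
                        f"could not place {n} puncta with min separation "
                        f"{cfg.min_separation} px on a {H}x{W} field"
                    )
                continue
        centers.append(np.round(c))
    return np.asarray(centers)


def render_stack(
    truth: GroundTruth,
    kinetics: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    frame_rate_hz: float = 1.0,
) -> ImageStack:
    """Render a movie: background + sum of PSF x brightness x kinetic x
    bleach, plus shot/read noise per the config.

    ``kinetics`` is (T,) shared by all puncta or (P, T) per punctum; it is
    the dimensionless brightness factor (e.g. the sypHy quenching state or
    1 + dF/F0).  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    kin = np.atleast_2d(np.asarray(kinetics, dtype=float))
    P = truth.n_puncta
    if kin.shape[0] == 1 and P > 1:
        kin = np.broadcast_to(kin, (P, kin.shape[1]))
    if kin.shape[0] != P:
        raise ValueError(f"kinetics rows ({kin.shape[0]}) != puncta ({P})")
    T = kin.shape[1]
    H, W = cfg.shape

    if truth.bleach_tau is None:
        bleach = np.ones(T)
    else:
        bleach = np.exp(-np.arange(T, dtype=float) / truth.bleach_tau)

    # saturation check against the output bit depth
    full_scale = 2**cfg.bit_depth - 1
    peak = truth.background_level + truth.brightness * kin.max(axis=1)
    bad = np.nonzero(peak > full_scale)[0]
    if bad.size:
        raise ValueError(
            f"punctum {bad[0]} would saturate {cfg.bit_depth}-bit output "
            f"(expected peak {peak[bad[0]]:.0f} > {full_scale})"
        )

    stamp, r = _psf_stamp(cfg.psf_sigma)
    expected = np.full((T, H, W), float(truth.background_level))
    for i in range(P):
        row, col = int(truth.centers[i, 0]), int(truth.centers[i, 1])
        r0, r1 = max(0, row - r), min(H, row + r + 1)
        c0, c1 = max(0, col - r), min(W, col + r + 1)
        sub = stamp[r0 - (row - r):r1 - (row - r), c0 - (col - r):c1 - (col - r)]
        amp = truth.brightness[i] * kin[i] * bleach            # (T,)
        expected[:, r0:r1, c0:c1] += amp[:, None, None] * sub

    if cfg.noise_free:
        data = expected
    else:
        data = np.empty((T, H, W), dtype=np.float32)
        chunk = max(1, int(2e7) // (H * W))   # bound the Poisson working set
        for a in range(0, T, chunk):
            b = min(T, a + chunk)
            block = expected[a:b]
            out = rng.poisson(block).astype(np.float32) if cfg.poisson \
                else block.astype(np.float32)
            if cfg.read_noise_sigma > 0:
                out += rng.normal(0.0, cfg.read_noise_sigma,
                                  size=block.shape).astype(np.float32)
            data[a:b] = np.maximum(out, 0.0)
    return ImageStack(data, frame_rate_hz=frame_rate_hz, modality=truth.modality)


# ---------------------------------------------------------------------------
# per-modality recording simulation
# ---------------------------------------------------------------------------

def _field_rng(seed: int) -> np.random.Generator:
    # field geometry shared between a stimulated recording and its
    # no-stimulation bleaching reference of the same seed
    return np.random.default_rng([int(seed) % (2**31), 101])


def _noise_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), 202, tag])


def _draw_field(rng: np.random.Generator, cfg: SimConfig, modality: str
                ) -> GroundTruth:
    n = int(rng.integers(cfg.n_puncta[0], cfg.n_puncta[1] + 1))
    centers = place_centers(rng, cfg, n)
    brightness = _lognormal_mean(rng, cfg.punctum_peak, cfg.punctum_peak_cv, n)
    return GroundTruth(
        modality=modality,
        centers=centers,
        brightness=brightness,
        background_level=cfg.background,
        bleach_tau=cfg.bleach_tau_frames,
        noise={"poisson": cfg.poisson, "read_noise_sigma": cfg.read_noise_sigma},
    )


def _decay_kernel(T: int, onset: int, peak: int, amp: float, tau_frames: float,
                  out: np.ndarray) -> None:
    """Add a transient: linear rise onset->peak, exponential decay after.
    The series value at ``peak`` is exactly ``amp``."""
    t = np.arange(T)
    if peak > onset:
        rise = (t - onset) / (peak - onset)
        m = (t >= onset) & (t < peak)
        out[m] += amp * rise[m]
    m = t >= peak
    out[m] += amp * np.exp(-(t[m] - peak) / tau_frames)


def _pp_epoch_kinetic(T: int, f1: int, f2: int, a1: float, ppr: float,
                      tau_frames: float, out: np.ndarray) -> None:
    """One paired-pulse epoch on a dF/F0 series (0-based pulse indices).

    The second-pulse increment is calibrated so that the standard
    accumulation-corrected measurement (trough between the peaks
    subtracted from the raw second peak) applied to the noise-free trace
    returns exactly ``ppr * a1``.
    """
    _decay_kernel(T, f1, f1, a1, tau_frames, out)
    trough = out[f1:f2].min()
    residual = out[f2]
    inc = ppr * a1 + trough - residual
    if inc < 0:
        inc = 0.0
    _decay_kernel(T, f2, f2, inc, tau_frames, out)


def ppr_at_calcium(ppr_2mm: float, calcium_scale: float) -> float:
    """Two-pulse depletion/facilitation rule for the external-calcium hook.

    Release probability scales with external calcium; with facilitation
    factor phi and baseline release probability p, PPR = phi * (1 - p).
    Calibrated so that calcium_scale = 1 returns the 2 mM value.
    """
    p = P_RELEASE_BASE * calcium_scale
    return ppr_2mm * (1.0 - p) / (1.0 - P_RELEASE_BASE)


def _pair_indices(protocol: StimulusProtocol) -> list[tuple[int, int]]:
    pairs = []
    kinds = protocol.stimulus_kinds
    for i, k in enumerate(kinds):
        if k == "pair1":
            if i + 1 >= len(kinds) or kinds[i + 1] != "pair2":
                raise ValueError("unpaired 'pair1' stimulus in protocol")
            pairs.append((protocol.stimuli[i].frame - 1,
                          protocol.stimuli[i + 1].frame - 1))
    return pairs


def simulate_recording(
    modality: str,
    preset: ConditionPreset,
    cfg: SimConfig | None = None,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
    calcium_scale: float = 1.0,
) -> tuple[ImageStack, GroundTruth, StimulusProtocol]:
    """Simulate one recording of the given modality and condition.

    Returns the rendered stack, the ground truth actually used, and the
    matching stimulation protocol.  ``syphy`` and ``syphy_nostim`` with
    the same seed share the same field (centers, brightness, bleach), so
    the no-stimulation movie is a true paired bleaching reference.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; known: {MODALITIES}")
    if cfg is None:
        cfg = default_config(modality)
    if protocol is None:
        protocol = _default_protocol(modality)
    _check_protocol_matches(modality, protocol)

    field_rng = _field_rng(seed)
    truth = _draw_field(field_rng, cfg, modality)
    noise_rng = _noise_rng(seed, MODALITIES.index(modality))
    T = protocol.n_frames
    P = truth.n_puncta

    if modality in ("syphy", "syphy_nostim"):
        f_rrp, f_trp = _draw_pool_fractions(preset, field_rng)
        q0 = QUENCHED_FRACTION
        if modality == "syphy_nostim":
            kin = np.full((P, T), q0)
            truth.params = {"condition": preset.name, "stimulated": False}
        else:
            jit_r = _lognormal_mean(noise_rng, 1.0, 0.10, P)
            jit_t = _lognormal_mean(noise_rng, 1.0, 0.10, P)
            kin = np.empty((P, T))
            for i in range(P):
                fr = float(np.clip(f_rrp * jit_r[i], 0.002, 0.98))
                ft = float(np.clip(f_trp * jit_t[i], fr, 0.99))
                u = syphy_unquenched_fraction(fr, ft, protocol)
                kin[i] = q0 + (1.0 - q0) * u
            truth.params = {"condition": preset.name, "f_rrp": f_rrp,
                            "f_trp": f_trp, "stimulated": True}

    elif modality == "iglusnfr":
        fps = protocol.frame_rate_hz
        tau = TAU_GLU_S * fps
        p1_rec = float(_lognormal_mean(field_rng, preset.glu_p1_scale,
                                       preset.cv("glu_p1"), None)) * calcium_scale
        ppr_rec = float(_lognormal_mean(field_rng, preset.ppr_mu,
                                        preset.cv("ppr"), None))
        ppr_eff = ppr_at_calcium(ppr_rec, calcium_scale)
        pairs = _pair_indices(protocol)
        site_amp = _lognormal_mean(noise_rng, p1_rec, 0.25, P)
        kin = np.zeros((P, T))
        for i in range(P):
            for (f1, f2) in pairs:
                _pp_epoch_kinetic(T, f1, f2, site_amp[i], ppr_eff, tau, kin[i])
        kin += 1.0                      # resting fluorescence F0
        truth.params = {"condition": preset.name, "p1": p1_rec,
                        "ppr": ppr_eff, "ppr_2mm": ppr_rec,
                        "calcium_scale": calcium_scale}

    elif modality in ("gcamp_single", "gcamp_pp", "gcamp_burst"):
        fps = protocol.frame_rate_hz
        tau = TAU_CA_S * fps
        kin = np.zeros((P, T))
        if modality == "gcamp_single":
            a_rec = float(_lognormal_mean(field_rng, preset.ca_single,
                                          preset.cv("ca_single"), None))
            site_amp = _lognormal_mean(noise_rng, a_rec, 0.25, P)
            for i in range(P):
                for s in protocol.stimuli:
                    _decay_kernel(T, s.frame - 1, s.frame - 1, site_amp[i], tau,
                                  kin[i])
            truth.params = {"condition": preset.name, "ca_single": a_rec}
        elif modality == "gcamp_burst":
            a_rec = float(_lognormal_mean(field_rng, preset.ca_burst,
                                          preset.cv("ca_burst"), None))
            site_amp = _lognormal_mean(noise_rng, a_rec, 0.25, P)
            s = protocol.stimuli[0]
            dur = max(1, round(s.n_ap / s.freq_hz * fps))
            for i in range(P):
                _decay_kernel(T, s.frame - 1, s.frame - 1 + dur, site_amp[i],
                              tau, kin[i])
            truth.params = {"condition": preset.name, "ca_burst": a_rec,
                            "burst_peak_frame": s.frame + dur}
        else:  # gcamp_pp
            a1_rec = float(_lognormal_mean(field_rng, preset.ca_single,
                                           preset.cv("ca_single"), None))
            ap_rec = float(_lognormal_mean(field_rng, preset.ca_pair,
                                           preset.cv("ca_pair"), None))
            site1 = _lognormal_mean(noise_rng, a1_rec, 0.25, P)
            scale = ap_rec / a1_rec
            for i in range(P):
                for (f1, f2) in _pair_indices(protocol):
                    _decay_kernel(T, f1, f1, site1[i], tau, kin[i])
                    # accumulated second peak reaches the drawn paired
                    # amplitude exactly (raw peak above epoch baseline)
                    inc = max(site1[i] * scale - kin[i][f2], 0.0)
                    _decay_kernel(T, f2, f2, inc, tau, kin[i])
            truth.params = {"condition": preset.name, "ca_single": a1_rec,
                            "ca_pair": ap_rec}
        kin += 1.0                      # resting fluorescence F0

    stack = render_stack(truth, kin, cfg, rng=noise_rng,
                         frame_rate_hz=protocol.frame_rate_hz)
    truth.per_punctum.setdefault("kinetics_shape", list(kin.shape))
    return stack, truth, protocol


def _default_protocol(modality: str) -> StimulusProtocol:
    if modality in ("syphy", "syphy_nostim"):
        return syphy_protocol()
    if modality == "iglusnfr":
        return iglusnfr_protocol()
    return gcamp_protocol(modality.split("_")[1])


def _check_protocol_matches(modality: str, protocol: StimulusProtocol) -> None:
    if modality in ("syphy", "syphy_nostim"):
        if protocol.nh4cl_frames is None or len(protocol.stimuli) < 2:
            raise ValueError(
                "sypHy modality needs a protocol with two stimulus trains "
                "and an NH4Cl window"
            )
    elif modality in ("iglusnfr", "gcamp_pp"):
        if "pair1" not in protocol.stimulus_kinds:
            raise ValueError(f"{modality} needs a paired-pulse protocol")
    elif modality == "gcamp_single":
        if "single" not in protocol.stimulus_kinds:
            raise ValueError("gcamp_single needs single-stimulus events")
    elif modality == "gcamp_burst":
        if "burst" not in protocol.stimulus_kinds:
            raise ValueError("gcamp_burst needs a burst stimulus")


# ---------------------------------------------------------------------------
# ICC still images (nuclear pCREB)
# ---------------------------------------------------------------------------

@dataclass
class IccConfig:
    """Configuration for simulated three-channel ICC fields."""

    shape: tuple[int, int] = (256, 256)
    n_nuclei: tuple[int, int] = (10, 15)
    nucleus_axes: tuple[float, float] = (6.5, 10.0)   # semi-axis range (px)
    min_separation: float = 28.0
    edge_margin: int = 16
    neuronal_fraction: float = 0.75
    pcreb_ctrl_level: float = 120.0     # counts above background for CTRL
    pcreb_background: float = 40.0
    nucleus_cv: float = 0.30            # per-nucleus lognormal variation
    dapi_level: float = 200.0
    map2_level: float = 150.0
    soma_radius: float = 16.0
    blur_sigma: float = 1.0
    poisson: bool = True
    read_noise_sigma: float = 2.0

    @property
    def noise_free(self) -> bool:
        return not self.poisson and self.read_noise_sigma == 0


def simulate_icc_image(
    preset: ConditionPreset,
    cfg: IccConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render one ICC field: (pCREB channel, nuclear-stain channel, MAP2
    channel, ground truth).

    10-15 elliptical nuclei are placed; a subset sits inside MAP2-positive
    somata (neuronal).  Neuronal nuclear pCREB means are drawn around the
    preset's level (percent of control) with between-field and per-nucleus
    lognormal variation; non-neuronal nuclei are dimmer.  In noise-free
    configurations all draws collapse to their means so the rendered field
    is an exact identity check of the generator.
    """
    from scipy.ndimage import gaussian_filter

    if cfg is None:
        cfg = IccConfig()
    rng = np.random.default_rng([int(seed) % (2**31), 303])
    H, W = cfg.shape
    deterministic = cfg.noise_free

    n = (cfg.n_nuclei[0] if deterministic
         else int(rng.integers(cfg.n_nuclei[0], cfg.n_nuclei[1] + 1)))
    # place nucleus centers
    centers = []
    attempts = 0
    m = cfg.edge_margin
    while len(centers) < n:
        c = np.array([rng.uniform(m, H - 1 - m), rng.uniform(m, W - 1 - m)])
        if centers and np.sqrt(((np.asarray(centers) - c) ** 2).sum(1)).min() \
                < cfg.min_separation:
            attempts += 1
            if attempts > 500 * n:
                raise RuntimeError(
                    f"could not place {n} nuclei of the configured size on a "
                    f"{H}x{W} field"
                )
            continue
        centers.append(c)
    centers = np.asarray(centers)
    if len(centers) < cfg.n_nuclei[0]:
        raise RuntimeError("fewer nuclei placed than the configured minimum")

    lo, hi = cfg.nucleus_axes
    if deterministic:
        ax_a = np.full(n, (lo + hi) / 2)
        ax_b = np.full(n, (lo + hi) / 2)
        angles = np.zeros(n)
        neuronal = np.ones(n, dtype=bool)
    else:
        ax_a = rng.uniform(lo, hi, n)
        ax_b = rng.uniform(lo, hi, n)
        angles = rng.uniform(0, np.pi, n)
        neuronal = rng.random(n) < cfg.neuronal_fraction
        if not neuronal.any():
            neuronal[0] = True

    # nuclear pCREB means: field level x per-nucleus lognormal
    field_scale = preset.pcreb_mean / 100.0
    if deterministic:
        field_level = cfg.pcreb_ctrl_level * field_scale
        true_means = np.full(n, field_level)
    else:
        field_level = float(_lognormal_mean(
            rng, cfg.pcreb_ctrl_level * field_scale, preset.cv("pcreb")))
        true_means = _lognormal_mean(rng, field_level, cfg.nucleus_cv, n)
        true_means = np.where(neuronal, true_means, true_means * 0.6)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    nuclei_mask = np.zeros((H, W), dtype=bool)
    pcreb = np.full((H, W), cfg.pcreb_background)
    dapi = np.full((H, W), 15.0)
    map2 = np.full((H, W), 20.0)
    for i in range(n):
        cy, cx = centers[i]
        ca, sa = np.cos(angles[i]), np.sin(angles[i])
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        ell = (u / ax_a[i]) ** 2 + (v / ax_b[i]) ** 2 <= 1.0
        nuclei_mask |= ell
        dapi[ell] += cfg.dapi_level
        pcreb[ell] += true_means[i]
        if neuronal[i]:
            soma = (xx - cx) ** 2 + (yy - cy) ** 2 <= cfg.soma_radius**2
            map2[soma] += cfg.map2_level

    if cfg.blur_sigma > 0:
        pcreb = gaussian_filter(pcreb, cfg.blur_sigma)
        dapi = gaussian_filter(dapi, cfg.blur_sigma)
        map2 = gaussian_filter(map2, cfg.blur_sigma)
    if not deterministic:
        def _noisy(img):
            out = rng.poisson(img).astype(float) if cfg.poisson else img.copy()
            if cfg.read_noise_sigma > 0:
                out += rng.normal(0, cfg.read_noise_sigma, img.shape)
            return np.maximum(out, 0.0)
        pcreb, dapi, map2 = _noisy(pcreb), _noisy(dapi), _noisy(map2)

    truth = GroundTruth(
        modality="icc",
        centers=centers,
        brightness=true_means,
        background_level=cfg.pcreb_background,
        bleach_tau=None,
        params={"condition": preset.name, "field_level": field_level,
                "n_nuclei": n},
        per_punctum={"true_mean": true_means, "neuronal": neuronal,
                     "axes_a": ax_a, "axes_b": ax_b},
    )
    return pcreb, dapi, map2, truth
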