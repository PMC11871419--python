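"""Image-stack and protocol I/O.

Movies are multi-frame grayscale TIFFs (8- or 16-bit on disk, floats in
memory); stimulation protocols are JSON sidecars.  All protocol windows are
**1-based inclusive** frame ranges, matching the slice convention of ImageJ
where such analyses are usually prototyped; the conversion to Python's
0-based half-open indexing happens exactly once, in
:meth:`StimulusProtocol.sl`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "StimulusEvent",
    "StimulusProtocol",
    "read_stack",
    "write_stack",
    "read_protocol",
    "write_protocol",
    "write_results",
    "read_results",
]


@dataclass
class ImageStack:
    """A T x H x W grayscale movie with acquisition metadata.

    Intensities are kept as floats (photon-count scale); files on disk are
    integer TIFFs.  ``pixel_size_um`` is carried as optional metadata and
    never used in any computation.
    """

    data: np.ndarray
    frame_rate_hz: float
    modality: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("stack must have at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        if self.data.min() < 0:
            raise ValueError("stack contains negative intensities")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class StimulusEvent:
    """One field-stimulation event: ``n_ap`` action potentials at
    ``freq_hz``, starting at 1-based ``frame``."""

    frame: int
    n_ap: int
    freq_hz: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StimulusProtocol:
    """Frame-indexed description of a stimulation/analysis protocol.

    All ``*_window``/``*_frames`` fields are ``[first, last]`` 1-based
    inclusive pairs.  sypHy protocols carry ``nh4cl_frames`` plus the
    RRP/TRP analysis windows; paired-pulse protocols carry
    ``pp_interval_ms``; transient protocols may carry per-stimulus search
    windows via ``peak_search_ms``.
    """

    frame_rate_hz: float
    n_frames: int
    baseline_frames: tuple[int, int]
    stimuli: list[StimulusEvent] = field(default_factory=list)
    # sypHy-specific
    nh4cl_frames: tuple[int, int] | None = None
    rrp_window: tuple[int, int] | None = None
    trp_window: tuple[int, int] | None = None
    fmin_window: tuple[int, int] | None = None
    # puncta-detection windows (activity map)
    activity_baseline: tuple[int, int] | None = None
    activity_response: tuple[int, int] | None = None
    # paired-pulse / transient protocols
    pp_interval_ms: float | None = None
    n_baseline_frames_epoch: int = 50
    peak_search_ms: float = 80.0
    stimulus_kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- indexing helpers ---------------------------------------------------
    @staticmethod
    def sl(window: Sequence[int]) -> slice:
        """1-based inclusive window -> 0-based half-open slice."""
        a, b = int(window[0]), int(window[1])
        return slice(a - 1, b)

    def frames_of(self, window: Sequence[int]) -> np.ndarray:
        s = self.sl(window)
        return np.arange(s.start, s.stop)

    # -- validation ---------------------------------------------------------
    def _check_window(self, name: str, window: Sequence[int] | None) -> None:
        if window is None:
            return
        a, b = window
        if not (1 <= a <= b <= self.n_frames):
            raise ValueError(
                f"window {name}=[{a}, {b}] outside stack of {self.n_frames} frames"
            )

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("protocol must span at least 2 frames")
        for name in (
            "baseline_frames",
            "nh4cl_frames",
            "rrp_window",
            "trp_window",
            "fmin_window",
            "activity_baseline",
            "activity_response",
        ):
            self._check_window(name, getattr(self, name))
        frames = [s.frame for s in self.stimuli]
        if any(f2 < f1 for f1, f2 in zip(frames, frames[1:])):
            raise ValueError(f"stimulus frames not monotone: {frames}")
        if frames and not (1 <= frames[0] and frames[-1] <= self.n_frames):
            raise ValueError("stimulus frames outside stack")
        if self.stimuli and self.baseline_frames[1] >= self.stimuli[0].frame:
            raise ValueError("baseline window must precede the first stimulus")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "frame_rate_hz": self.frame_rate_hz,
            "n_frames": self.n_frames,
            "baseline_frames": list(self.baseline_frames),
            "stimuli": [s.to_dict() for s in self.stimuli],
            "n_baseline_frames_epoch": self.n_baseline_frames_epoch,
            "peak_search_ms": self.peak_search_ms,
        }
        for name in (
            "nh4cl_frames",
            "rrp_window",
            "trp_window",
            "fmin_window",
            "activity_baseline",
            "activity_response",
        ):
            v = getattr(self, name)
            if v is not None:
                d[name] = list(v)
        if self.pp_interval_ms is not None:
            d["pp_interval_ms"] = self.pp_interval_ms
        if self.stimulus_kinds:
            d["stimulus_kinds"] = list(self.stimulus_kinds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        kw = dict(d)
        kw["stimuli"] = [StimulusEvent(**s) for s in d.get("stimuli", [])]
        for name in (
            "baseline_frames",
            "nh4cl_frames",
            "rrp_window",
            "trp_window",
            "fmin_window",
            "activity_baseline",
            "activity_response",
        ):
            if name in kw and kw[name] is not None:
                kw[name] = tuple(kw[name])
        return cls(**kw)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path, dtype=np.uint16) -> Path:
    """Write a stack as a multi-frame grayscale TIFF (values rounded)."""
    path = Path(path)
    info = np.iinfo(dtype)
    data = np.clip(np.rint(stack.data), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(protocol.to_dict(), indent=1))
    return path


def read_protocol(path: str | Path) -> StimulusProtocol:
    return StimulusProtocol.from_dict(json.loads(Path(path).read_text()))


def read_stack(
    path: str | Path,
    protocol_path: str | Path,
    modality: str = "",
) -> tuple[ImageStack, StimulusProtocol]:
    """Load a TIFF movie and its JSON protocol, cross-validated.

    8- and 16-bit TIFFs load to the same float values.  Every protocol
    window is checked against the actual frame count.
    """
    protocol = read_protocol(protocol_path)
    data = tifffile.imread(path).astype(np.float64)
    if data.ndim == 2:
        data = data[None]
    stack = ImageStack(data, frame_rate_hz=protocol.frame_rate_hz, modality=modality)
    protocol.n_frames = stack.n_frames
    protocol.validate()
    return stack, protocol


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results(
    records: Sequence, path: str | Path, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Write per-recording (or per-nucleus) result records to CSV.

    Records may be dataclasses or mappings; all must share one schema.
    Rows are sorted by ``recording_id`` (or the first column) so output
    ordering is bit-stable.
    """
    rows = []
    for r in records:
        rows.append(dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r))
    if rows:
        schema = set(rows[0])
        for r in rows[1:]:
            if set(r) != schema:
                raise ValueError(f"mixed record schemas: {sorted(schema)} vs {sorted(r)}")
        df = pd.DataFrame(rows)
        key = "recording_id" if "recording_id" in df.columns else df.columns[0]
        df = df.sort_values(key, kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, index=False)
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
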