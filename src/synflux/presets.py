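"""Treatment-condition presets for the synthetic-movie generator.

Each preset bundles the ground-truth group means for one treatment of
cultured cortical neurons: vesicle-pool fractions from sypHy (readily
releasable pool released by 40 AP @ 20 Hz, total recycling pool by
900 AP @ 20 Hz, both as fractions of the NH4Cl-unquenched total pool),
iGluSnFR paired-pulse parameters, synGCaMP6 evoked-calcium amplitudes
(peak dF/F0), and nuclear pCREB immunofluorescence relative to vehicle
controls after 24 h.  The numbers are the published group means for
30-min treatments (24 h for pCREB); ``between_recording_cv`` carries the
published across-recording dispersion (SD/mean) per metric so simulated
cohorts scatter like the real ones.

Conditions: CTRL (vehicle), LSD, DMT, PSI (psilocin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["ConditionPreset", "make_preset", "registered_conditions"]


@dataclass(frozen=True)
class ConditionPreset:
    """Ground-truth parameter bundle for one treatment condition.

    Amplitude-like fields are dimensionless dF/F0; ``pcreb_mean`` is a
    percentage of the same-experiment control mean; ``glu_p1_scale``
    scales the mean first-peak glutamate response relative to control
    (the underlying absolute amplitudes were not published, only the
    ratios).
    """

    name: str
    f_rrp: float
    f_trp: float
    glu_p1_scale: float
    ppr_mu: float
    ca_single: float
    ca_pair: float
    ca_burst: float
    pcreb_mean: float
    between_recording_cv: Mapping[str, float] = field(default_factory=dict)
    default_cv: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_rrp <= self.f_trp <= 1.0):
            raise ValueError(
                f"pool fractions must satisfy 0 <= f_rrp <= f_trp <= 1, "
                f"got f_rrp={self.f_rrp}, f_trp={self.f_trp}"
            )
        for fname in ("glu_p1_scale", "ppr_mu", "ca_single", "ca_pair", "ca_burst",
                      "pcreb_mean"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")

    def cv(self, metric: str) -> float:
        """Between-recording coefficient of variation for one metric."""
        return float(self.between_recording_cv.get(metric, self.default_cv))


def _cv(sd: float, mean: float) -> float:
    return sd / mean


# Published group means (mean +/- SD across recordings / visual fields).
# CVs are SD/mean from the same report; glutamate P1 dispersion was not
# published and defaults to 0.15 (each recording already averages 30-80
# release sites, so field-to-field scatter of the mean is modest).
_PRESETS: dict[str, ConditionPreset] = {}


def _register(preset: ConditionPreset) -> None:
    _PRESETS[preset.name] = preset


_register(ConditionPreset(
    name="CTRL",
    f_rrp=0.13, f_trp=0.61,
    glu_p1_scale=1.0, ppr_mu=1.13,
    ca_single=0.40, ca_pair=0.86, ca_burst=6.21,
    pcreb_mean=100.0,
    between_recording_cv={
        "f_rrp": _cv(0.02, 0.13), "f_trp": _cv(0.05, 0.61),
        "ppr": _cv(0.23, 1.13),
        "ca_single": _cv(0.09, 0.40), "ca_pair": _cv(0.31, 0.86),
        "ca_burst": _cv(1.71, 6.21), "pcreb": _cv(21.0, 100.0),
    },
))

_register(ConditionPreset(
    name="LSD",
    f_rrp=0.10, f_trp=0.53,
    glu_p1_scale=1.0, ppr_mu=1.11,
    ca_single=0.23, ca_pair=0.42, ca_burst=4.47,
    pcreb_mean=165.0,
    between_recording_cv={
        "f_rrp": _cv(0.02, 0.10), "f_trp": _cv(0.08, 0.53),
        "ppr": _cv(0.16, 1.11),
        "ca_single": _cv(0.07, 0.23), "ca_pair": _cv(0.15, 0.42),
        "ca_burst": _cv(1.19, 4.47), "pcreb": _cv(72.0, 165.0),
    },
))

_register(ConditionPreset(
    name="DMT",
    f_rrp=0.12, f_trp=0.56,
    glu_p1_scale=1.7,       # evoked glutamate release +70% vs control
    ppr_mu=1.04,
    ca_single=0.36, ca_pair=0.82, ca_burst=5.65,
    pcreb_mean=213.0,
    between_recording_cv={
        "f_rrp": _cv(0.02, 0.12), "f_trp": _cv(0.04, 0.56),
        "ppr": _cv(0.19, 1.04),
        "ca_single": _cv(0.13, 0.36), "ca_pair": _cv(0.30, 0.82),
        "ca_burst": _cv(1.41, 5.65), "pcreb": _cv(109.0, 213.0),
    },
))

_register(ConditionPreset(
    name="PSI",
    f_rrp=0.10, f_trp=0.54,
    glu_p1_scale=1.5,       # evoked glutamate release +50% vs control
    ppr_mu=0.90,
    ca_single=0.33, ca_pair=0.80, ca_burst=4.58,
    pcreb_mean=160.0,
    between_recording_cv={
        "f_rrp": _cv(0.01, 0.10), "f_trp": _cv(0.05, 0.54),
        "ppr": _cv(0.23, 0.90),
        "ca_single": _cv(0.09, 0.33), "ca_pair": _cv(0.12, 0.80),
        "ca_burst": _cv(1.27, 4.58), "pcreb": _cv(80.0, 160.0),
    },
))


def registered_conditions() -> list[str]:
    return sorted(_PRESETS)


def make_preset(name: str) -> ConditionPreset:
    """Return the ground-truth preset for a registered condition.

    Raises ``KeyError`` listing the registered names for unknown labels.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; registered conditions: "
            f"{registered_conditions()}"
        ) from None
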