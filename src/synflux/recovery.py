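"""Cohort-level parameter-recovery experiments.

Each function simulates a cohort of recordings for one condition, runs
the full quantification pipeline on every recording, and returns a
per-recording results table together with the generator's ground truth.
These are the validation experiments of the package: because the
generator's presets carry published group means, recovering those means
from rendered movies demonstrates every stage of the pipeline at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simkit
from .nucquant import normalize_to_ctrl, quantify_field
from .pools import quantify_syphy
from .presets import make_preset
from .transients import quantify_gcamp, quantify_iglusnfr

__all__ = [
    "recording_seed",
    "syphy_pool_recovery",
    "ppr_recovery",
    "gcamp_recovery",
    "pcreb_recovery",
]


def recording_seed(base_seed: int, index: int) -> int:
    """Per-recording seed derived from a cohort base seed."""
    return int((base_seed * 1_000_003 + index) % (2**31))


def syphy_pool_recovery(
    condition: str,
    n_recordings: int = 8,
    base_seed: int = 1,
    cfg: simkit.SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate sypHy recordings (each with its paired no-stimulation
    reference of the same field) and recover RRP/TRP fractions."""
    preset = make_preset(condition)
    rows = []
    for i in range(n_recordings):
        seed = recording_seed(base_seed, i)
        stack, truth, protocol = simkit.simulate_recording(
            "syphy", preset, cfg=cfg, seed=seed)
        nostim, _, _ = simkit.simulate_recording(
            "syphy_nostim", preset, cfg=cfg, seed=seed)
        pf = quantify_syphy(stack, nostim, protocol,
                            recording_id=f"{condition}_{i:03d}",
                            condition=condition)
        rows.append({
            "recording_id": pf.recording_id, "condition": condition,
            "rrp": pf.rrp, "trp": pf.trp,
            "true_rrp": truth.params["f_rrp"], "true_trp": truth.params["f_trp"],
        })
    return pd.DataFrame(rows)


def ppr_recovery(
    condition: str,
    n_recordings: int = 30,
    base_seed: int = 1,
    calcium_scale: float = 1.0,
    cfg: simkit.SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate iGluSnFR paired-pulse recordings and recover P1 and PPR."""
    preset = make_preset(condition)
    rows = []
    for i in range(n_recordings):
        seed = recording_seed(base_seed, i)
        stack, truth, protocol = simkit.simulate_recording(
            "iglusnfr", preset, cfg=cfg, seed=seed,
            calcium_scale=calcium_scale)
        m = quantify_iglusnfr(stack, protocol,
                              recording_id=f"{condition}_{i:03d}",
                              condition=condition)
        rows.append({
            "recording_id": m.recording_id, "condition": condition,
            "p1_amp": m.p1_amp, "p2_amp": m.p2_amp, "ppr": m.ppr,
            "true_p1": truth.params["p1"], "true_ppr": truth.params["ppr"],
            "calcium_scale": calcium_scale,
        })
    return pd.DataFrame(rows)


def gcamp_recovery(
    kind: str,
    condition: str,
    n_recordings: int = 20,
    base_seed: int = 1,
    cfg: simkit.SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate synGCaMP6 recordings (``single``, ``pp`` or ``burst``)
    and recover evoked-amplitude means."""
    preset = make_preset(condition)
    modality = f"gcamp_{kind}"
    rows = []
    for i in range(n_recordings):
        seed = recording_seed(base_seed, i)
        stack, truth, protocol = simkit.simulate_recording(
            modality, preset, cfg=cfg, seed=seed)
        a = quantify_gcamp(stack, protocol,
                           recording_id=f"{condition}_{i:03d}",
                           condition=condition)
        rows.append({
            "recording_id": a.recording_id, "condition": condition,
            "single_amp": a.single_amp, "pair_amp": a.pair_amp,
            "burst_amp": a.burst_amp, "truth": truth.params,
        })
    return pd.DataFrame(rows)


def pcreb_recovery(
    drug: str = "DMT",
    control: str = "CTRL",
    n_experiments: int = 3,
    n_fields: int = 10,
    base_seed: int = 1,
    cfg: simkit.IccConfig | None = None,
) -> pd.DataFrame:
    """Simulate ICC experiments (each with control and drug fields),
    quantify nuclear pCREB per field, and normalize to the same-experiment
    control mean.  Returns the long-format normalized table."""
    rows = []
    for e in range(n_experiments):
        for cond in (control, drug):
            preset = make_preset(cond)
            for f in range(n_fields):
                seed = recording_seed(base_seed, e * 10_000 + f
                                      + (50_000 if cond == drug else 0))
                pcreb, dapi, map2, _ = simkit.simulate_icc_image(
                    preset, cfg=cfg, seed=seed)
                field_mean, _ = quantify_field(pcreb, dapi, map2)
                rows.append({"experiment": f"exp{e}", "condition": cond,
                             "field_id": f"exp{e}_{cond}_{f:02d}",
                             "mean_if": field_mean})
    table = pd.DataFrame(rows)
    return normalize_to_ctrl(table, control=control)
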