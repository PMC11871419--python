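"""Nuclear pCREB immunofluorescence, normalized to control.

Simulates one small ICC experiment (control and DMT visual fields),
segments DAPI nuclei, keeps MAP2-positive (neuronal) ones, measures
background-subtracted nuclear pCREB, and expresses field means as
percent of the experiment's control mean.
"""

import pandas as pd

import synflux as sf
from synflux.nucquant import normalize_to_ctrl, quantify_field

rows = []
for condition in ("CTRL", "DMT"):
    preset = sf.make_preset(condition)
    for f in range(6):
        pcreb, dapi, map2, truth = sf.simulate_icc_image(
            preset, seed=1000 * (condition == "DMT") + f)
        mean_if, per_nucleus = quantify_field(pcreb, dapi, map2)
        rows.append({"experiment": "exp1", "condition": condition,
                     "field_id": f"{condition}_{f}", "mean_if": mean_if,
                     "n_nuclei": len(per_nucleus)})

table = normalize_to_ctrl(pd.DataFrame(rows))
summary = table.groupby("condition")["normalized_pct"].agg(["mean", "std"])
print(table[["condition", "field_id", "mean_if", "normalized_pct"]]
      .to_string(index=False))
print("\nper-condition normalized means (% of CTRL):")
print(summary.round(1).to_string())
print("\nThe 24 h DMT preset roughly doubles nuclear pCREB "
      "(published mean 213% of control).")
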