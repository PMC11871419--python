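"""Paired-pulse glutamate metrics from a simulated iGluSnFR movie.

Two field stimuli 100 ms apart probe short-term plasticity: the ratio of
the second to the first glutamate transient (PPR) reads out release
probability (PPR < 1 depression, > 1 facilitation).  The second peak is
corrected for indicator accumulation by subtracting the trough between
the peaks.
"""

import synflux as sf

for condition in ("CTRL", "PSI"):
    preset = sf.make_preset(condition)
    stack, truth, protocol = sf.simulate_recording("iglusnfr", preset, seed=12)
    m = sf.quantify_iglusnfr(stack, protocol, condition=condition)
    print(f"{condition}: P1={m.p1_amp:.2f} dF/F0, P2={m.p2_amp:.2f}, "
          f"PPR={m.ppr:.3f} (ground truth {truth.params['ppr']:.3f}) over "
          f"{len(m.epoch_ppr)} epochs")

print("\nPSI lowers the PPR versus CTRL (higher release probability); "
      "published means are 1.13 (CTRL) and 0.90 (PSI).")
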