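"""Individual-based simulation of spider perch height.

Runs 100 replicates of a 50-hour perch-movement simulation for a
sit-and-wait spider (hourly move probability 0.1, step |N(10.5, 14.5)| cm,
canopy clamped to [0, 100] cm).  Woodlice forage at dawn/dusk near the
ground; an encounter forces the spider to an upward escape move.  The paired
with/without-woodlice contrast shares all random draws, so the difference
isolates the encounter effect.  An active hunter (move probability 0.8) is
simulated for comparison.
"""

import numpy as np

from canopydomain import IBMConfig, run_simulation, summarize, \
    woodlouse_height_contrast

cfg = IBMConfig(seed=2025)
summary = summarize(run_simulation(cfg), cfg)
print("sit-and-wait spider, woodlice present (100 x 50 h):")
print(f"  realized movement probability per hour: "
      f"{summary.realized_move_probability:.3f}")
print(f"  mean hourly displacement (all steps):   {summary.mean_step:.2f} cm "
      f"(sd {summary.step_sd:.2f})")
print(f"  moves exceeding the 0.5 cm detection threshold: "
      f"{summary.n_effective_steps}")

sit = woodlouse_height_contrast(cfg)
print("\npaired with/without-woodlice contrast (final 10 hours):")
print(f"  mean height with woodlice    {sit['mean_with']:.1f} cm")
print(f"  mean height without woodlice {sit['mean_without']:.1f} cm")
print(f"  {sit['n_diverged']} of 100 replicate pairs diverged; "
      f"Wilcoxon signed-rank p = {sit['pvalue']:.2g}")

act = woodlouse_height_contrast(IBMConfig(seed=2025, p_move_base=0.8))
print(f"\nactive hunter (move probability 0.8): paired difference "
      f"{act['mean_difference']:+.2f} cm — the woodlouse effect washes out "
      f"when baseline movement is high.")
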