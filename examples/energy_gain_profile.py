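"""Daily net energy gain of a spider as a function of perch height.

Computes the expected net energy a sit-and-wait spider gains per day at each
canopy height, balancing grasshopper encounters (which peak where the
grasshopper domain overlaps the spider's hunting range) against
temperature-dependent respiration (which grows with height because the
canopy warms by 0.1 degC per cm).  Woodlouse encounters near the ground add
a tiny attack cost (~4.3 mJ each), so the curve barely changes when woodlice
are present — unless that cost is inflated a thousandfold.
"""

import numpy as np

from canopydomain import (
    DEFAULT_GRASSHOPPER_DOMAIN,
    DEFAULT_SPIDER_DOMAIN,
    DEFAULT_WOODLOUSE_DOMAIN,
    CanopyThermalProfile,
    EnergeticsParams,
    MetabolicModel,
    daily_net_gain_profile,
    expected_grasshopper_payoff,
    net_attack_outcomes,
)

domains = {
    "PIMI": DEFAULT_SPIDER_DOMAIN,
    "MEFE": DEFAULT_GRASSHOPPER_DOMAIN,
    "ONAS": DEFAULT_WOODLOUSE_DOMAIN,
}
params = EnergeticsParams()
met = MetabolicModel()
profile = CanopyThermalProfile()
grid = np.arange(0.0, 121.0, 1.0)

print(f"expected payoff per grasshopper encounter: "
      f"{expected_grasshopper_payoff(params):.3f} J")
g_net, w_net = net_attack_outcomes(params, met, 25.0)
print(f"net outcome of one attack at 25 degC: grasshopper {g_net:+.3f} J, "
      f"woodlouse {w_net * 1e3:+.2f} mJ\n")

for label, p, woodlice in [
    ("no woodlice", params, False),
    ("woodlice, unit attack cost", params, True),
    ("woodlice, 1000x attack cost",
     EnergeticsParams(woodlouse_cost_multiplier=1000.0), True),
]:
    tab = daily_net_gain_profile(domains, p, met, profile, grid, woodlice)
    best = tab.loc[tab.gain_J_per_day.idxmax()]
    print(f"{label:30s} best perch {best.z_cm:5.1f} cm, "
          f"gain {best.gain_J_per_day:+.3f} J/day")

print("\nthe optimum sits near the observed spider height (~60 cm); cheap "
      "woodlouse attacks leave it unchanged, and only a three-orders-of-"
      "magnitude cost pushes the spider higher.")
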