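# canopydomain

Models of how a sit-and-wait predator uses vertical space when a useless
distractor species shares its habitat — and what that does to its prey.

In New England old fields, the nursery web spider *Pisaurina mira* (code
`PIMI`) hunts the red-legged grasshopper *Melanoplus femurrubrum* (`MEFE`)
in the plant canopy, while the detritivorous woodlouse *Oniscus asellus*
(`ONAS`) forages in the litter below. Woodlice are not spider prey, yet
their presence shifts the spider's perch upward. This package implements
the computational chain used to dissect that interaction:

1. **Habitat domains** (`canopydomain.domains`) — each species' use of the
   canopy as a vertical density: normal for spider and grasshopper, gamma
   for the ground-skewed woodlice, fitted by sample moments. The overlap
   integral of two domains, `A = ∫ f_pred(z) f_prey(z) dz` (per cm), is the
   predicted attack-rate kernel.
2. **Foraging energetics** (`canopydomain.energetics`) — expected daily net
   energy gain at each perch height z: grasshopper encounters pay
   `s·ε·E_g = 0.25 × 0.8 × 33.81 J ≈ 6.76 J` each; attacks and handling
   cost active metabolism (8.6 mJ/min at 25 °C, Q10 = 2, canopy warming
   0.1 °C/cm); woodlouse attacks are pure cost (≈ 4.3 mJ).
3. **Signal detection theory** (`canopydomain.signal_detection`) — should
   the spider attack every encountered item, or pay assessment looks
   (discriminability d′ = 2.5 per look, 25 % risk of losing the opportunity
   per look) to filter out woodlice? Jointly optimizes criterion, number of
   looks, and perch height.
4. **Individual-based model** (`canopydomain.ibm`) — hourly perch movement
   with empirically calibrated rates (move probability 0.1 sit-and-wait /
   0.8 active, step |N(10.5, 14.5)| cm, canopy clamped to [0, 100] cm) plus
   woodlouse-encounter-triggered escape moves at dawn/dusk.
5. **Bayesian inference** (`canopydomain.inference`) — a multivariate
   normal mixed model of per-cage spider/grasshopper heights (woodlouse,
   warming, and interaction effects; year and block-in-year random
   intercepts; LKJ-uniform residual correlation) and a binomial
   logit model of grasshopper survival against attack rate, sampled with
   an affine-invariant ensemble sampler on hand-derived log-posteriors
   (random intercepts marginalized analytically in the Gaussian model).
6. **Synthetic data** (`canopydomain.synthgen`) — a generator emulating the
   three-year randomized-block cage experiments (half-hourly positions
   07:00–19:00, 2–3 grasshoppers stocked per cage, sparse woodlouse
   detections), so the whole chain is testable without field data.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/energy_gain_profile.py` prints:

```
expected payoff per grasshopper encounter: 6.762 J
net outcome of one attack at 25 degC: grasshopper +6.715 J, woodlouse -4.30 mJ

no woodlice                    best perch  61.0 cm, gain -1.487 J/day
woodlice, unit attack cost     best perch  61.0 cm, gain -1.487 J/day
woodlice, 1000x attack cost    best perch  66.0 cm, gain -1.964 J/day
```

Reading: a grasshopper encounter is worth ~6.8 J after discounting attack
success and assimilation; a wasted strike at a woodlouse costs ~4.3 mJ —
three orders of magnitude less. The best perch (61 cm, near the observed
spider height of ~60 cm) is therefore unchanged by woodlice unless their
attack cost is inflated ×1000, when the optimum shifts upward. The
strategy optimizer (`examples/attack_strategy_optimizer.py`) reaches the
same verdict from the decision side: the optimal policy is *always attack*
for any realistic prey composition, and the joint perch/strategy optimum
first changes at a ×1000 cost multiplier.

`python examples/perch_movement_simulation.py` runs the movement model:

```
sit-and-wait spider, woodlice present (100 x 50 h):
  realized movement probability per hour: 0.101
  mean hourly displacement (all steps):   1.38 cm (sd 5.19)

paired with/without-woodlice contrast (final 10 hours):
  mean height with woodlice    49.6 cm
  mean height without woodlice 48.5 cm
  9 of 100 replicate pairs diverged; Wilcoxon signed-rank p = 0.002
```

Sit-and-wait spiders end significantly higher when woodlice are present —
ground-level encounters force upward escape moves — while the same
contrast for an active hunter (move probability 0.8) washes out. So the
upward shift observed in cages is consistent with spiders simply moving
away from unprofitable woodlouse encounters, not with energy maximization.

`examples/treatment_effect_inference.py` closes the loop: it simulates a
full cage study with a +16.5 cm woodlouse effect and −19.3 cm
warming × woodlouse interaction on spider height, and the hierarchical
model recovers both within its 95 % credible intervals.

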