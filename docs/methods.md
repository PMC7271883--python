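# Methods

This note documents the models, the parameter choices that matter, the
numerical decisions, and what the synthetic-data tests do and do not show.
Heights are in cm above ground, energies in J, times in minutes unless
stated.

## Habitat domains and attack rates

A habitat domain is the distribution of an animal's height in the canopy.
Spider and grasshopper domains are normal, summarized by the sample mean
and sample standard deviation (n−1 denominator) of all height records;
woodlouse heights are strongly ground-skewed and use a gamma domain fitted
by method of moments (`shape = (mean/sd)²`, `rate = mean/sd²`). Normal
densities are evaluated *untruncated*: the fitted curve is a summary of
where the animal sits, and for the species involved less than ~2 % of mass
falls below ground. Quadrature integrals run over z ∈ [0, 120] cm (100 cm
cage fencing plus headroom).

The predicted attack rate of predator on prey is the overlap integral
`A = ∫ f_pred f_prey dz` (units cm⁻¹). For two normals this has the closed
form `N(μ₁−μ₂; 0, σ₁²+σ₂²)` evaluated at zero, which is what the per-cage
analysis uses; quadrature on [0, 120] is always computed alongside and the
two agree to 1e-6 whenever below-ground mass is negligible (a tested
oracle). Mixed normal–gamma pairs use quadrature only.

Pooled default domains for the model simulations: spider N(60, 28²),
grasshopper N(69, 10²), woodlouse gamma(shape 1, rate 0.2 cm⁻¹) — mean
woodlouse height 5 cm, consistent with litter-dwelling natural history.
These equal the centres of the height-model priors, standing in for the
multi-year pooled field observations.

## Encounter rates at a perch

The foraging models need the rate at which a spider perched at height z
encounters each species. A perched spider does not sample space as a point:
its hunting range is modelled as its own domain spread recentred at the
perch, so the encounter weight for prey i is the overlap

&nbsp;&nbsp;`o_i(z) = ∫ N(u; z, σ_S²) f_i(u) du`, σ_S = 28 cm,

normalized so the peak grasshopper rate equals the calibrated 0.8
encounters/day; woodlice share the same normalization (equal densities of
potential interactors). This choice matters: with *point* (local-density)
sampling the woodlouse tail is already ~e⁻¹² of its peak at the energetic
optimum and no finite attack cost could move the spider, which contradicts
the observed behavior of the full system; with overlap smoothing the
optimum sits at 61 cm — essentially the observed spider height — and
responds to extreme costs exactly as expected. The point-sampling
composition `π_G(z) = f_G/(f_G+f_W)` is still exposed as
`encounter_composition` for analyses that want it.

## Energetics

Temperature rises linearly with height, `T(z) = T0 + 0.1·z` °C (default
ground temperature 20 °C, a typical summer observation day). Metabolism is
a Q10 law (Q10 = 2) anchored at the active rate of 8.6 mJ/min at 25 °C —
equivalently 25.70 µl O₂/h through the oxycalorific equivalent of
0.0200832 J/µl — chosen so that one 0.5-min attack burst costs ~4.3 mJ;
resting is half of active at every temperature. The respiration quotient
(0.7) is carried for converting user-supplied CO₂ respirometry but is not
used in the default O₂-anchored chain.

Per-encounter outcomes at temperature T, with success s = 0.25,
assimilation ε = 0.8, prey energy E_g = 33.81 J, attack time 0.5 min,
handling 20 min, active rate a(T):

- grasshopper: `s·(ε·E_g − a(T)·20.5) − (1−s)·a(T)·0.5` (≈ +6.71 J at 25 °C)
- woodlouse: `−m·a(T)·0.5` (≈ −4.3 mJ at multiplier m = 1)

Daily gain at z is encounter-rate-weighted outcomes minus resting
metabolism over the remainder of the 24 h (the spider is assumed to stay at
its perch overnight; the paper-level conclusions depend only on the shape
of the profile, not its absolute level, since the non-hunting budget is a
z-dependent constant offset). The three reported components (payoff,
attack cost, resting) sum to the total exactly, which is a tested
invariant.

## Signal detection

An encountered item is a grasshopper with probability π_G. A single
assessment look draws a unit-variance normal cue with mean 0 (woodlouse) or
d′ = 2.5 (grasshopper); n looks average cues, giving separation d′√n, so
`hit = Φ(√n(d′−c))`, `false alarm = Φ(−√n·c)` for criterion c.

The value model treats immediate attack (and never-attack) as *zero-look*
policies: the spider strikes on detection and risks nothing. A selective
policy must hold and assess, and every look carries the 25 % probability of
losing the opportunity plus one attack-burst of respiration:

&nbsp;&nbsp;`V = (1−p_loss)ⁿ · [π_G·hit·payoff − (1−π_G)·fa·m·cost] − n·look_cost`.

Charging the loss risk per assessment look (rather than per look beyond the
first) is the modelling decision that makes assessment a genuine trade-off;
with a free first look a selective criterion would dominate always-attack
by construction for any Gaussian cue, which is inconsistent with the
cheap-distractor regime this system sits in. Under the defaults the
optimum is *always attack* for every π_G in (0, 1), and the joint
perch/strategy optimum first changes at a woodlouse-cost multiplier of
1000 — the attack cost must approach the grasshopper payoff
(6.76 J / 4.3 mJ ≈ 1.6 × 10³) before discrimination or perch shifts pay.

The optimizer grid-searches c ∈ [−4, d′+4] (step 0.05) × n ∈ [1, 5], then
polishes the criterion continuously around each look-count's grid optimum,
so its value is never below any finer enumeration (tested against a 10×
finer brute force). Ties break toward fewer looks, then smaller |c|.

## Individual-based model

State is perch height; time steps are hourly over 50 h, 100 replicates,
initial heights uniform on [0, 100] cm. Per hour, in order of precedence:

1. *Woodlouse encounter* (dawn/dusk hours {5, 6, 7, 18, 19, 20} only, when
   woodlice forage above ground): probability
   `0.8 × f_W(z)/f_W(mode) / 6` per active hour — the daily encounter
   budget at full overlap spread over the active window. An encounter
   forces an *upward* escape move: the stimulus is in the litter below the
   spider, and near the ground up is the only productive direction.
2. *Baseline move* with probability 0.1 (sit-and-wait) or 0.8 (active
   hunter), direction random.
3. Optionally (`respond_to_failed_attacks`), a failed grasshopper strike
   (encounter weighted by the grasshopper domain during the 8 midday
   hunting hours, failing with probability 0.75) also forces a move,
   direction random — a grasshopper's position relative to the perch is
   not systematically below it.

Moves draw magnitude |N(10.5, 14.5)| cm and are clamped to [0, 100] cm
(clamp, not reflect); a realized displacement ≤ 0.5 cm counts as a
non-movement, which is how the realized movement probability (~0.092) falls
below the nominal 0.1 — spiders pinned at a boundary draw moves they cannot
realize. Movement statistics are computed over all steps, with the
daytime-window (07–19 h) versions also reported.

Each step consumes a fixed number of random draws, so two runs differing
only in `woodlice_present` share every draw (common random numbers). The
with/without contrast is therefore paired: replicates never touched by an
encounter are identical in both arms and drop out of a Wilcoxon signed-rank
test, which isolates the encounter effect with far less noise than an
independent-ensembles comparison — essential here because the effect
(~1–2 cm on the ensemble mean) is small against the ~28 cm between-replicate
spread of a 50-h clamped random walk. Under the same design the active
hunter's contrast collapses to near zero: encounters mostly coincide with
moves the spider would have made anyway.

## Hierarchical models

**Heights.** Per-cage mean heights (L_MEFE, L_PIMI) are bivariate normal
with linear predictor `α_i + α_i,year + α_i,block|year + β_i,T·T + β_i,W·W
+ β_i,TW·T·W` per species i. Priors: intercepts t₃(69, 10) (grasshopper)
and t₃(60, 28) (spider); warming effects informed by earlier published
work, N(−0.13, 16.1) and N(−12.7, 9.4); woodlouse and interaction effects
N(0, 100); residual scales half-t₃(0, 10)/(0, 28); random-intercept scales
likewise; residual correlation uniform on (−1, 1) (LKJ with η = 1).
Because the likelihood is Gaussian, the year and block random intercepts
are marginalized analytically — the sampler walks only the 8 fixed effects
and 7 variance/correlation parameters, with scales on the log scale and
the correlation as atanh(ρ) (Jacobians included).

**Survival.** Survivors of the n_k grasshoppers stocked per cage (2 in the
first two study years, 3 in the warmed-design year) are
`Binomial(n_k, logit⁻¹(α + α_year + α_block|year + β_A·A))`. The display
form of the model writes p as the bare linear predictor; the logit link is
the standard binomial convention and keeps p bounded. Priors: β_A ~
N(0, 10), α and scales t₃(0, 10); random effects are sampled non-centred.

Sampling uses the emcee ensemble sampler with differential-evolution moves
and vectorized posteriors (40 walkers × 4000 steps height, 64 × 1500
survival, half discarded as warmup; seeds fixed). Summaries report
posterior means, sds, [2.5 %, 97.5 %] intervals, split-chain R-hat and bulk
ESS via arviz; a fit is flagged non-converged unless R-hat < 1.01 and
ESS > 400 everywhere. Ensemble chains decorrelate slowly on this posterior,
so default budgets typically flag; the credible intervals are nevertheless
stable well before the R-hat gate is met (coverage tests below), and users
wanting clean diagnostics should raise `n_steps` several-fold.

## Synthetic data

The generator reproduces the experimental design: years {2015, 2017, 2018}
× 4 blocks × 5 cages, woodlouse treatment alternating within block, warming
only in the last year (second half of each block), 25 half-hourly checks
per animal 07:00–19:00, heights recorded at 0.5 cm resolution, 1 spider and
2–3 grasshoppers per cage, 6 woodlice detected with probability 0.02 per
check (matching how rarely woodlice surface by day). Cage-level means
follow the height model's own linear predictor — default truths
β_PIMI,W = +16.5 cm, β_PIMI,TW = −19.3 cm, all grasshopper effects 0 —
with year/block deviation sds of 3/6 cm and correlated cage residuals
(5/12 cm, ρ = 0.2); within-cage observations are truncated-normal
(redrawn at ground). Survival is binomial with logit slope −10 per cm⁻¹ of
attack rate. Everything is bit-reproducible from (seed, config).

What the round-trip tests show: the full pipeline — generate, summarize,
fit — recovers the generating treatment effects with ~nominal 95 % CI
coverage at the study's design size, and the survival model's interval
covers its slope (the attack rates vary so little between cages that the
posterior stays near its prior; the real study was similarly weakly
informative, reporting β_A ≈ −0.5 [−17, 16]). What they do not show:
robustness to features of real data the generator omits — within-day
autocorrelation of positions (the cage-mean analysis is insensitive by
construction), observer error beyond block effects, non-gamma woodlouse
height shapes, or model misspecification generally. One known wrinkle is
intentional realism: ground truncation of within-cage spider heights
(sd 28 cm) inflates control-cage means slightly more than woodlouse-cage
means, attenuating the realized woodlouse effect by ~0.8 cm relative to
the configured value, which keeps measured coverage at (rather than above)
the 17/20 acceptance line.

## Numerical and degenerate-input conventions

Domain fits require ≥ 2 observations and positive variance (errors
otherwise); negative heights are rejected everywhere. The height grid is
[0, 120] cm at 1 cm; perch ties break toward the lower height. Gamma
hunting-range overlaps use a 1201-point trapezoid rule on [0, 120]
(relative error < 1e-6 against adaptive quadrature for the default
domains). Cages missing either focal species are excluded from summaries
with a logged warning. Boundary survival data (all cages at full survival)
fit without special handling — the priors regularize the intercept.

## Limitations

The energetics' absolute daily gain depends on the assumed non-hunting
budget and is reported for profile comparison, not as a growth prediction.
The SDT look-cost accounting is one defensible convention among several;
its qualitative conclusions (always-attack; ~10³ cost threshold) are robust
to the look-cost magnitude but not to making the first look free. The IBM
has no explicit woodlouse agents, prey depletion, or 2-D structure, and its
escape-direction rule encodes the ground-stimulus geometry rather than
deriving it. The inference module targets this design's scale; very large
designs would warrant a gradient-based sampler.
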