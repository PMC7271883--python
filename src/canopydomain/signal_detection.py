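"""Signal detection theory combined with habitat-domain encounter rates.

An encountered item is a grasshopper (true prey, payoff) or a woodlouse
(false target, pure cost).  The spider may attack immediately, never attack,
or assess the item: each assessment look draws a unit-variance normal cue
with mean 0 for a woodlouse and mean d' for a grasshopper; n looks average
their cues, giving effective separation d' * sqrt(n).  Assessment is not
free — every look risks losing the current attack opportunity (probability
``p_loss``) and costs one attack-burst of active respiration.  The
immediate-attack and never-attack policies take zero looks and carry no
loss risk.

Given the composition of encountered items pi_G (the probability the item is
a grasshopper), the optimizer grid-searches the criterion and the number of
looks; combined with the energetics module it also optimizes the perch
height itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .domains import HabitatDomain
from .energetics import (
    CanopyThermalProfile,
    EnergeticsParams,
    MetabolicModel,
    encounter_rates,
    net_attack_outcomes,
    respiration_rate,
    temperature_at_height,
)

__all__ = [
    "SDTParams",
    "Strategy",
    "detection_probs",
    "strategy_value",
    "optimize_strategy",
    "optimize_perch",
    "cost_multiplier_threshold",
]


@dataclass(frozen=True)
class SDTParams:
    """Parameters of the attack-decision problem.

    ``payoff_G`` is the net energy of attacking a grasshopper (J) and
    ``cost_W`` the magnitude of the cost of attacking a woodlouse (J, >= 0),
    both typically supplied by the energetics module.  ``look_cost`` is the
    respiration cost of one assessment look (J); by default one attack-burst
    of active metabolism at 25 degC.
    """

    d_prime: float = 2.5
    p_loss: float = 0.25
    max_looks: int = 5
    payoff_G: float = 6.762
    cost_W: float = 0.0043
    cost_multiplier: float = 1.0
    look_cost: float = 0.0043

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ValueError("d_prime must be non-negative")
        if not (0 <= self.p_loss < 1):
            raise ValueError("p_loss must be in [0, 1)")
        if self.max_looks < 1:
            raise ValueError("max_looks must be >= 1")
        if self.cost_W < 0:
            raise ValueError("cost_W is a magnitude and must be >= 0")


@dataclass(frozen=True)
class Strategy:
    """An attack policy: criterion ``c`` and number of assessment looks.

    ``looks = 0`` with ``c = -inf`` is the immediate always-attack policy and
    with ``c = +inf`` the never-attack policy; selective policies take
    ``looks >= 1`` cue samples and attack when the pooled cue exceeds ``c``.
    """

    criterion: float
    looks: int
    expected_value: float = float("nan")
    label: str = "selective"


def detection_probs(d_prime: float, c: float, n: int = 1) -> tuple[float, float]:
    """Hit and false-alarm probabilities after ``n`` pooled looks.

    hit = Phi(sqrt(n) * (d' - c)), false_alarm = Phi(-sqrt(n) * c).
    ``c = -inf`` gives (1, 1) (attack everything); ``c = +inf`` gives (0, 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if math.isinf(c):
        return (1.0, 1.0) if c < 0 else (0.0, 0.0)
    rt = math.sqrt(n)
    hit = float(stats.norm.cdf(rt * (d_prime - c)))
    fa = float(stats.norm.cdf(-rt * c))
    return hit, fa


def strategy_value(strategy: Strategy, pi_G: float, params: SDTParams) -> float:
    """Expected net energy (J) per encountered item under ``strategy``.

    Zero-look policies attack everything (or nothing) immediately.  A
    selective policy with n looks retains the opportunity with probability
    (1 - p_loss)^n, then attacks when the pooled cue exceeds the criterion;
    each look also costs ``look_cost`` of active respiration.
    """
    if not (0.0 <= pi_G <= 1.0):
        raise ValueError("pi_G must be in [0, 1]")
    n = strategy.looks
    c = strategy.criterion
    m = params.cost_multiplier
    if n == 0:
        hit, fa = (1.0, 1.0) if c < 0 else (0.0, 0.0)
        retention = 1.0
    else:
        hit, fa = detection_probs(params.d_prime, c, n)
        retention = (1.0 - params.p_loss) ** n
    attack_term = (pi_G * hit * params.payoff_G
                   - (1.0 - pi_G) * fa * m * params.cost_W)
    return retention * attack_term - n * params.look_cost


def _candidate_policies(params: SDTParams, step: float):
    """Candidate (criterion, looks) arrays: zero-look policies + the c/n grid."""
    cs = np.arange(-4.0, params.d_prime + 4.0 + 1e-9, step)
    n_grid = np.arange(1, params.max_looks + 1)
    C = np.concatenate([[-np.inf, np.inf], np.tile(cs, n_grid.size)])
    N = np.concatenate([[0, 0], np.repeat(n_grid, cs.size)])
    return C, N


def _policy_values(pi_G: float, params: SDTParams, C: np.ndarray,
                   N: np.ndarray) -> np.ndarray:
    """Vectorized ``strategy_value`` over candidate policy arrays."""
    from scipy.special import ndtr

    rt = np.sqrt(np.maximum(N, 1))
    with np.errstate(invalid="ignore"):
        hit = ndtr(rt * (params.d_prime - C))
        fa = ndtr(-rt * C)
    zero = N == 0
    hit[zero] = np.where(C[zero] < 0, 1.0, 0.0)
    fa[zero] = hit[zero]
    retention = (1.0 - params.p_loss) ** N
    attack_term = (pi_G * hit * params.payoff_G
                   - (1.0 - pi_G) * fa * params.cost_multiplier * params.cost_W)
    return retention * attack_term - N * params.look_cost


def optimize_strategy(pi_G: float, params: SDTParams,
                      step: float = 0.05) -> Strategy:
    """Grid-search the best attack policy for prey composition ``pi_G``.

    Candidates: immediate attack (c = -inf), never attack (c = +inf), and
    selective policies with c in [-4, d'+4] (step 0.05) and 1..max_looks
    looks.  Ties break toward fewer looks, then smaller |c|.  The label is
    ``always_attack``/``never_attack`` when the corresponding zero-look
    policy is within 1e-12 J of the optimum.
    """
    if not (0.0 <= pi_G <= 1.0):
        raise ValueError("pi_G must be in [0, 1]")
    from scipy.optimize import minimize_scalar

    C, N = _candidate_policies(params, step)
    vals = _policy_values(pi_G, params, C, N)
    # polish the criterion continuously around each look-count's grid optimum,
    # so the result is at least as good as any finer grid
    cand_c = [C[0], C[1]]
    cand_n = [0, 0]
    cand_v = [float(vals[0]), float(vals[1])]
    for n in range(1, params.max_looks + 1):
        sel = N == n
        j = int(np.argmax(np.where(sel, vals, -np.inf)))
        c0 = float(C[j])
        res = minimize_scalar(
            lambda c: -strategy_value(Strategy(float(c), n), pi_G, params),
            bounds=(c0 - step, c0 + step), method="bounded",
            options={"xatol": 1e-10})
        if -res.fun > vals[j]:
            cand_c.append(float(res.x))
            cand_v.append(float(-res.fun))
        else:
            cand_c.append(c0)
            cand_v.append(float(vals[j]))
        cand_n.append(n)
    cand_c = np.array(cand_c)
    cand_n = np.array(cand_n)
    cand_v = np.array(cand_v)
    best_val = float(cand_v.max())
    near = np.flatnonzero(cand_v >= best_val - 1e-12)
    # ties: fewer looks, then smaller |criterion| (infinities sort last)
    i = int(near[np.lexsort((np.abs(cand_c[near]), cand_n[near]))][0])
    always_val = cand_v[0]
    never_val = cand_v[1]
    if always_val >= best_val - 1e-12:
        return Strategy(-math.inf, 0, float(always_val), "always_attack")
    if never_val >= best_val - 1e-12:
        return Strategy(math.inf, 0, float(never_val), "never_attack")
    return Strategy(float(cand_c[i]), int(cand_n[i]), float(cand_v[i]),
                    "selective")


def _sdt_params_at(params: SDTParams, p: EnergeticsParams, met: MetabolicModel,
                   temp: float) -> SDTParams:
    """Recompute temperature-dependent payoffs for the decision problem."""
    g_net, _ = net_attack_outcomes(replace(p, woodlouse_cost_multiplier=1.0), met, temp)
    burst = respiration_rate(met, temp, "active") * p.attack_time
    return replace(params, payoff_G=g_net, cost_W=burst, look_cost=burst,
                   cost_multiplier=params.cost_multiplier)


def optimize_perch(domains: dict[str, HabitatDomain],
                   sdt_params: SDTParams,
                   p: EnergeticsParams,
                   met: MetabolicModel,
                   profile: CanopyThermalProfile,
                   heights=None,
                   woodlice_present: bool = True,
                   step: float = 0.05):
    """Jointly optimize perch height and attack policy.

    For each height: the encounter composition follows the overlap of the
    hunting spider's domain (recentred at the perch) with each prey domain;
    the per-encounter payoffs are evaluated at the local temperature; the
    daily value is total encounters x per-encounter strategy value minus
    resting metabolism outside the expected attack/handling time.  Returns
    ``(z_star, strategy_at_z_star, table)`` with ties broken toward lower z.
    """
    if heights is None:
        heights = np.arange(0.0, 120.0 + 1e-9, 1.0)
    z = np.asarray(heights, dtype=float)
    if z.size == 0:
        raise ValueError("empty height grid")
    lam_g, lam_w = encounter_rates(domains, p, z, woodlice_present)
    temp = np.asarray(temperature_at_height(profile, z))
    r = np.asarray(respiration_rate(met, temp, "resting"))

    rows = []
    best_idx, best_gain = 0, -math.inf
    strategies: list[Strategy] = []
    for i in range(z.size):
        total = lam_g[i] + lam_w[i]
        pi = 1.0 if total == 0 else float(lam_g[i] / total)
        local = _sdt_params_at(sdt_params, p, met, float(temp[i]))
        strat = optimize_strategy(pi, local, step=step)
        attack_minutes = (lam_g[i] * (p.attack_time + p.attack_success * p.handling_time)
                          + lam_w[i] * p.attack_time)
        gain = total * strat.expected_value - r[i] * (1440.0 - attack_minutes)
        strategies.append(strat)
        rows.append({"z_cm": z[i], "pi_G": pi, "criterion": strat.criterion,
                     "looks": strat.looks, "label": strat.label,
                     "value_J": strat.expected_value, "gain_J_per_day": gain})
        if gain > best_gain + 1e-12:
            best_idx, best_gain = i, gain
    table = pd.DataFrame(rows)
    return float(z[best_idx]), strategies[best_idx], table


def cost_multiplier_threshold(domains: dict[str, HabitatDomain],
                              sdt_params: SDTParams,
                              p: EnergeticsParams,
                              met: MetabolicModel,
                              profile: CanopyThermalProfile,
                              decades=(1, 10, 100, 1000),
                              heights=None) -> float | None:
    """Smallest woodlouse-attack-cost multiplier that alters the optimum.

    Scans the given multipliers (ascending) against the baseline optimum at
    multiplier 1; returns the first at which the optimal perch shifts by
    more than one grid step or the strategy at the optimal perch leaves
    always-attack.  Returns None when no scanned multiplier alters it.
    """
    decades = list(decades)
    if not decades:
        raise ValueError("empty decade list")
    if sorted(decades) != decades:
        raise ValueError("decades must be sorted ascending")
    if heights is None:
        heights = np.arange(0.0, 120.0 + 1e-9, 1.0)
    grid_step = float(np.diff(np.asarray(heights, dtype=float)).max()) if len(heights) > 1 else 1.0

    base_sdt = replace(sdt_params, cost_multiplier=1.0)
    base_p = replace(p, woodlouse_cost_multiplier=1.0)
    z0, strat0, _ = optimize_perch(domains, base_sdt, base_p, met, profile,
                                   heights=heights, woodlice_present=True)
    for mult in decades:
        sdt_m = replace(sdt_params, cost_multiplier=float(mult))
        p_m = replace(p, woodlouse_cost_multiplier=float(mult))
        z_m, strat_m, _ = optimize_perch(domains, sdt_m, p_m, met, profile,
                                         heights=heights, woodlice_present=True)
        shifted = abs(z_m - z0) > grid_step + 1e-9
        left_always = (strat0.label == "always_attack"
                       and strat_m.label != "always_attack")
        if shifted or left_always:
            return float(mult)
    return None
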