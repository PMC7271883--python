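"""Signal-detection attack strategies and the perch/strategy optimizer."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from canopydomain.energetics import (
    DEFAULT_GRASSHOPPER_DOMAIN,
    DEFAULT_SPIDER_DOMAIN,
    DEFAULT_WOODLOUSE_DOMAIN,
    CanopyThermalProfile,
    EnergeticsParams,
    MetabolicModel,
)
from canopydomain.signal_detection import (
    SDTParams,
    Strategy,
    cost_multiplier_threshold,
    detection_probs,
    optimize_perch,
    optimize_strategy,
    strategy_value,
)

DOMAINS = {
    "PIMI": DEFAULT_SPIDER_DOMAIN,
    "MEFE": DEFAULT_GRASSHOPPER_DOMAIN,
    "ONAS": DEFAULT_WOODLOUSE_DOMAIN,
}


class TestDetectionProbs:
    def test_single_look_at_midpoint_criterion(self):
        hit, fa = detection_probs(2.5, 1.25, 1)
        assert hit == pytest.approx(stats.norm.cdf(1.25))
        assert fa == pytest.approx(stats.norm.cdf(-1.25))

    def test_always_attack_limit(self):
        assert detection_probs(2.5, -math.inf, 1) == (1.0, 1.0)

    def test_pooling_four_looks_doubles_separation(self):
        hit1, fa1 = detection_probs(2.5, 1.25, 1)
        hit4, fa4 = detection_probs(2.5, 1.25, 4)
        assert hit4 == pytest.approx(stats.norm.cdf(2.0 * (2.5 - 1.25)))
        assert fa4 == pytest.approx(stats.norm.cdf(-2.0 * 1.25))


class TestStrategyValue:
    params = SDTParams(payoff_G=6.762, cost_W=4.3e-3, look_cost=4.3e-3)

    def test_immediate_attack_value(self):
        v = strategy_value(Strategy(-math.inf, 0), 0.5, self.params)
        assert v == pytest.approx(0.5 * 6.762 - 0.5 * 4.3e-3)  # 3.3789

    def test_each_look_costs_one_retention_factor(self):
        base = replace(self.params, look_cost=0.0, d_prime=0.0)
        v1 = strategy_value(Strategy(-10.0, 1), 0.5, base)
        v2 = strategy_value(Strategy(-10.0, 2), 0.5, base)
        # criterion far below both cue means: attack everything after looking
        assert v2 / v1 == pytest.approx(0.75, rel=1e-6)

    def test_pure_cost_when_no_prey(self):
        v = strategy_value(Strategy(-math.inf, 0), 0.0, self.params)
        assert v < 0.0


class TestOptimizeStrategy:
    def test_always_attack_across_prey_compositions(self):
        """Woodlouse attacks are so cheap that assessment never pays."""
        params = SDTParams()
        for pi in (0.01, 0.05, 0.25, 0.5, 0.75, 0.99):
            s = optimize_strategy(pi, params)
            assert s.label == "always_attack"
            assert s.looks == 0

    def test_high_cost_regime_turns_selective(self):
        s = optimize_strategy(0.1, SDTParams(cost_multiplier=1000.0))
        assert s.label == "selective"
        assert s.looks >= 1

    def test_worthless_prey_never_attacked(self):
        s = optimize_strategy(0.5, SDTParams(payoff_G=0.0))
        assert s.label == "never_attack"
        assert s.expected_value == 0.0

    def test_optimizer_beats_degenerate_policies(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            params = SDTParams(
                d_prime=rng.uniform(0.0, 4.0),
                p_loss=rng.uniform(0.0, 0.6),
                payoff_G=rng.uniform(0.1, 10.0),
                cost_W=rng.uniform(1e-3, 1.0),
                cost_multiplier=10.0 ** rng.integers(0, 4),
            )
            pi = rng.uniform(0.0, 1.0)
            best = optimize_strategy(pi, params)
            always = strategy_value(Strategy(-math.inf, 0), pi, params)
            never = strategy_value(Strategy(math.inf, 0), pi, params)
            assert best.expected_value >= always - 1e-12
            assert best.expected_value >= never - 1e-12

    def test_matches_brute_force_on_finer_grid(self):
        """Optimum value agrees with an exhaustive 10x finer enumeration."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            params = SDTParams(
                d_prime=rng.uniform(0.5, 4.0),
                p_loss=rng.uniform(0.0, 0.5),
                payoff_G=rng.uniform(0.5, 10.0),
                cost_W=rng.uniform(1e-3, 0.5),
                cost_multiplier=float(10.0 ** rng.integers(0, 4)),
                max_looks=3,
            )
            pi = float(rng.uniform(0.0, 1.0))
            got = optimize_strategy(pi, params).expected_value
            # independent brute force at 10x resolution
            best = max(
                strategy_value(Strategy(-math.inf, 0), pi, params),
                strategy_value(Strategy(math.inf, 0), pi, params),
            )
            for n in range(1, params.max_looks + 1):
                for c in np.arange(-4.0, params.d_prime + 4.0 + 1e-9, 0.005):
                    best = max(best, strategy_value(Strategy(float(c), n), pi,
                                                    params))
            # never worse than the enumeration; better only within the fine
            # grid's own discretization error
            assert got >= best - 1e-6
            assert got - best < 1e-4

    def test_value_monotone_in_cost_multiplier_and_dprime(self):
        pi = 0.3
        vals = [optimize_strategy(pi, SDTParams(cost_multiplier=m)).expected_value
                for m in (1.0, 10.0, 100.0, 1000.0, 10000.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        vals_d = [optimize_strategy(pi, SDTParams(cost_multiplier=1000.0,
                                                  d_prime=d)).expected_value
                  for d in (0.0, 1.0, 2.5, 4.0)]
        assert all(b >= a - 1e-12 for a, b in zip(vals_d, vals_d[1:]))

    def test_free_looks_never_hurt(self):
        """With no loss risk and free looks, more information cannot lower
        the best achievable value."""
        params = SDTParams(p_loss=0.0, look_cost=0.0, cost_multiplier=1000.0,
                           max_looks=5)
        pi = 0.2

        def best_at(n):
            vals = [strategy_value(Strategy(float(c), n), pi, params)
                    for c in np.arange(-4.0, 6.5, 0.05)]
            return max(vals)

        bests = [best_at(n) for n in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(bests, bests[1:]))


class TestOptimizePerch:
    p = EnergeticsParams()
    met = MetabolicModel()
    prof = CanopyThermalProfile()

    def test_unit_cost_perch_unchanged_by_woodlice(self):
        sdt = SDTParams()
        z_on, s_on, _ = optimize_perch(DOMAINS, sdt, self.p, self.met, self.prof,
                                       woodlice_present=True)
        z_off, s_off, _ = optimize_perch(DOMAINS, sdt, self.p, self.met, self.prof,
                                         woodlice_present=False)
        assert z_on == z_off
        assert s_on.label == "always_attack"

    def test_absent_woodlice_always_attack_everywhere(self):
        _, _, tab = optimize_perch(DOMAINS, SDTParams(), self.p, self.met,
                                   self.prof, woodlice_present=False)
        assert (tab.label == "always_attack").all()
        assert (tab.pi_G == 1.0).all()

    def test_extreme_cost_moves_perch_upward(self):
        sdt1000 = SDTParams(cost_multiplier=1000.0)
        p1000 = replace(self.p, woodlouse_cost_multiplier=1000.0)
        z_hi, _, _ = optimize_perch(DOMAINS, sdt1000, p1000, self.met, self.prof)
        z_base, _, _ = optimize_perch(DOMAINS, SDTParams(), self.p, self.met,
                                      self.prof)
        assert z_hi > z_base

    def test_cost_multiplier_threshold_is_three_orders(self):
        th = cost_multiplier_threshold(DOMAINS, SDTParams(), self.p, self.met,
                                       self.prof, decades=(1, 10, 100, 1000))
        assert th == 1000

    def test_unbeatable_payoff_gives_no_threshold(self):
        sdt = SDTParams(payoff_G=1e9)
        p = EnergeticsParams(grasshopper_energy=1e9 / 0.2)
        th = cost_multiplier_threshold(DOMAINS, sdt, p, self.met, self.prof,
                                       decades=(1, 10, 100))
        assert th is None

    def test_empty_decades_rejected(self):
        with pytest.raises(ValueError):
            cost_multiplier_threshold(DOMAINS, SDTParams(), self.p, self.met,
                                      self.prof, decades=())
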