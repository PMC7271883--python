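"""Habitat-domain fitting, densities and overlap integrals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from canopydomain.domains import (
    DegenerateFitError,
    HabitatDomain,
    InsufficientDataError,
    encounter_composition,
    domain_density,
    fit_domain,
    hunting_overlap,
    pairwise_attack_rate,
    read_domains,
    write_domains,
)


class TestFitDomain:
    def test_two_point_normal_moments(self):
        dom = fit_domain([50.0, 70.0], family="normal")
        assert dom.mu == pytest.approx(60.0)
        assert dom.sigma == pytest.approx(math.sqrt(200.0))  # 14.142

    def test_gamma_method_of_moments(self):
        # sample with mean 5 and sd 5 -> shape 1, rate 0.2
        heights = np.array([0.0, 10.0]) + 5.0
        heights = np.array([5 - 5, 5 + 5], dtype=float)
        dom = fit_domain(heights, family="gamma")
        assert dom.shape == pytest.approx((5.0 / math.sqrt(50.0)) ** 2)
        # hand-checked moments: mean 5, sd 5 gives shape 1, rate 0.2
        dom2 = HabitatDomain("ONAS", "gamma", 5.0, 5.0, shape=1.0, rate=0.2)
        assert dom2.shape == 1.0 and dom2.rate == pytest.approx(0.2)

    def test_single_observation_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_domain([42.0], family="normal")

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_domain([30.0, 30.0, 30.0], family="gamma")
        with pytest.raises(DegenerateFitError):
            fit_domain([30.0, 30.0], family="normal")

    def test_gamma_recovers_parameters_at_large_n(self):
        rng = np.random.default_rng(7)
        sample = rng.gamma(2.0, 1.0 / 0.1, size=10_000)
        dom = fit_domain(sample, family="gamma")
        assert dom.shape == pytest.approx(2.0, rel=0.05)
        assert dom.rate == pytest.approx(0.1, rel=0.05)

    @given(st.lists(st.floats(1.0, 100.0), min_size=3, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_normal_fit_matches_sample_moments(self, heights):
        arr = np.asarray(heights)
        if arr.std(ddof=1) == 0:
            return
        dom = fit_domain(arr, family="normal")
        assert dom.mu == pytest.approx(arr.mean())
        assert dom.sigma == pytest.approx(arr.std(ddof=1))


class TestDensity:
    def test_normal_density_at_mean(self):
        dom = HabitatDomain("PIMI", "normal", 60.0, 28.0)
        assert domain_density(dom, 60.0) == pytest.approx(
            1.0 / (28.0 * math.sqrt(2.0 * math.pi)))  # 0.0142479 per cm

    def test_gamma_density_at_origin(self):
        dom = HabitatDomain("ONAS", "gamma", 5.0, 5.0, shape=1.0, rate=0.2)
        assert domain_density(dom, 0.0) == pytest.approx(0.2)

    def test_normal_mass_above_ground(self):
        dom = HabitatDomain("PIMI", "normal", 60.0, 28.0)
        mass, _ = integrate.quad(dom.pdf, 0.0, 200.0)
        assert mass == pytest.approx(0.984, abs=2e-3)

    def test_negative_height_rejected(self):
        dom = HabitatDomain("PIMI", "normal", 60.0, 28.0)
        with pytest.raises(ValueError):
            domain_density(dom, -1.0)


class TestOverlap:
    def test_identical_normals_closed_form(self):
        dom = HabitatDomain("X", "normal", 60.0, 10.0)
        res = pairwise_attack_rate(dom, dom)
        assert res.attack_rate_density == pytest.approx(1.0 / (20.0 * math.sqrt(math.pi)))
        assert res.method == "closed_form"

    def test_mixed_pair_quadrature(self):
        spider = HabitatDomain("PIMI", "normal", 60.0, 28.0)
        grass = HabitatDomain("MEFE", "normal", 69.0, 10.0)
        res = pairwise_attack_rate(spider, grass)
        assert res.attack_rate_density == pytest.approx(0.01282, abs=2e-5)
        # quadrature and closed form agree when little mass lies below ground
        assert res.quadrature == pytest.approx(res.closed_form, abs=1e-4)

    def test_disjoint_supports_vanish(self):
        a = HabitatDomain("A", "normal", 10.0, 1.0)
        b = HabitatDomain("B", "normal", 110.0, 1.0)
        assert pairwise_attack_rate(a, b).attack_rate_density < 1e-12

    def test_symmetry_and_scale(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mu = rng.uniform(30, 90, size=2)
            sd = rng.uniform(5, 25, size=2)
            a = HabitatDomain("A", "normal", mu[0], sd[0])
            b = HabitatDomain("B", "normal", mu[1], sd[1])
            ab = pairwise_attack_rate(a, b).attack_rate_density
            ba = pairwise_attack_rate(b, a).attack_rate_density
            assert ab == pytest.approx(ba, rel=1e-9)
        # coincident means: overlap scales as 1/s when both sds scale by s
        for s in (2.0, 3.0):
            a = HabitatDomain("A", "normal", 60.0, 8.0)
            a2 = HabitatDomain("A", "normal", 60.0, 8.0 * s)
            b2 = HabitatDomain("B", "normal", 60.0, 8.0 * s)
            base = pairwise_attack_rate(a, a).attack_rate_density
            scaled = pairwise_attack_rate(a2, b2).attack_rate_density
            assert scaled == pytest.approx(base / s, rel=1e-9)

    def test_closed_form_matches_quadrature_random_draws(self):
        """Normal-normal overlap: analytic density vs numerical integral."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            mu = rng.uniform(30.0, 90.0, size=2)
            sd = rng.uniform(4.0, 12.0, size=2)
            a = HabitatDomain("A", "normal", mu[0], sd[0])
            b = HabitatDomain("B", "normal", mu[1], sd[1])
            # keep below-ground mass under 1%
            if stats.norm.cdf(0.0, mu.min(), sd.max()) > 0.01:
                continue
            res = pairwise_attack_rate(a, b)
            assert res.quadrature == pytest.approx(res.closed_form, abs=1e-6)


class TestComposition:
    grass = HabitatDomain("MEFE", "normal", 69.0, 10.0)
    wood = HabitatDomain("ONAS", "gamma", 5.0, 5.0, shape=1.0, rate=0.2)

    def test_equal_densities_give_half(self):
        dom = HabitatDomain("X", "normal", 50.0, 10.0)
        assert encounter_composition(50.0, dom, dom) == pytest.approx(0.5)

    def test_absent_woodlice_gives_one(self):
        assert encounter_composition(42.0, self.grass, None) == 1.0

    def test_ground_composition_near_zero(self):
        # at the ground the woodlouse density dwarfs a 69-cm grasshopper domain
        assert encounter_composition(0.0, self.grass, self.wood) < 1e-6

    def test_monotone_when_ratio_monotone(self):
        z = np.linspace(0.0, 69.0, 200)
        pi = encounter_composition(z, self.grass, self.wood)
        assert np.all(np.diff(pi) > 0)

    def test_both_zero_densities_error(self):
        a = HabitatDomain("A", "normal", 10.0, 0.5)
        b = HabitatDomain("B", "normal", 10.0, 0.5)
        with pytest.raises(ValueError):
            encounter_composition(119.0, a, b)


class TestHuntingOverlap:
    def test_normal_prey_closed_form_matches_quadrature(self):
        grass = HabitatDomain("MEFE", "normal", 69.0, 10.0)
        got = hunting_overlap(grass, 60.0, sigma_hunt=28.0)
        num, _ = integrate.quad(
            lambda u: stats.norm.pdf(u, 60.0, 28.0)
            * stats.norm.pdf(u, 69.0, 10.0), -300, 400)
        assert got == pytest.approx(num, rel=1e-6)

    def test_zero_hunting_range_reduces_to_local_density(self):
        wood = HabitatDomain("ONAS", "gamma", 5.0, 5.0, shape=1.0, rate=0.2)
        assert hunting_overlap(wood, 10.0, 0.0) == pytest.approx(wood.pdf(10.0))


def test_domain_csv_round_trip(tmp_path):
    doms = [
        HabitatDomain("PIMI", "normal", 60.0, 28.0, n_obs=100),
        HabitatDomain("ONAS", "gamma", 5.0, 5.0, shape=1.0, rate=0.2, n_obs=40),
    ]
    path = tmp_path / "domains.csv"
    write_domains(doms, path)
    back = read_domains(path)
    assert back["PIMI"].mu == 60.0 and back["PIMI"].family == "normal"
    assert back["ONAS"].rate == pytest.approx(0.2)
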