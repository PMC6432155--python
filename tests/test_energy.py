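"""Torus and bundle free-energy functionals and their constrained optima."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from polycollapse.energy import (
    ChainSpec,
    bundle_free_energy,
    bundle_optimal_geometry,
    torus_free_energy,
    torus_optimal_geometry,
)


def brute_force_torus(chain, kb, r_lo=1e-3, r_hi=50.0):
    """Independent 1-D minimizer of the torus free energy (bounded Brent)."""
    res = minimize_scalar(
        lambda r: torus_free_energy(r, chain, kb),
        bounds=(r_lo, r_hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return res.x, res.fun


def brute_force_bundle(chain, k1, r_lo=1e-3, r_hi=50.0):
    res = minimize_scalar(
        lambda r: bundle_free_energy(r, chain, k1),
        bounds=(r_lo, r_hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return res.x, res.fun


class TestTorusFreeEnergy:
    def test_surface_plus_bending_decomposition(self, chain600):
        # independent route: G = 4 pi^2 R r (surface) + kb L/R^2 (bending)
        # with R fixed by volume conservation R = L/(8 pi r^2)
        r, kb = 1.0, 1.0
        R = 600.0 / (8.0 * math.pi * r**2)
        expected = 4.0 * math.pi**2 * R * r + kb * 600.0 / R**2
        assert torus_free_energy(r, chain600, kb) == pytest.approx(expected, rel=1e-12)
        assert torus_free_energy(r, chain600, kb) == pytest.approx(943.53055, rel=1e-6)

    def test_pure_surface_term_when_bending_free(self, chain600):
        for r in (0.5, 1.7, 9.0):
            assert torus_free_energy(r, chain600, 0.0) == pytest.approx(
                0.5 * math.pi * 600.0 / r, rel=1e-14
            )

    def test_bending_term_is_quarter_of_surface_at_optimum(self, chain600):
        kb = 3.7
        g = torus_optimal_geometry(chain600, kb)
        surface = 0.5 * math.pi * 600.0 / g.r_t
        bending = g.G - surface
        assert bending == pytest.approx(surface / 4.0, rel=1e-10)
        assert g.G == pytest.approx(5.0 * math.pi / 8.0 * 600.0 / g.r_t, rel=1e-12)

    def test_domain_errors(self, chain600):
        with pytest.raises(ValueError):
            torus_free_energy(0.0, chain600, 1.0)
        with pytest.raises(ValueError):
            torus_free_energy(-1.0, chain600, 1.0)
        with pytest.raises(ValueError):
            ChainSpec(-5.0)


class TestTorusOptimalGeometry:
    def test_unconstrained_example(self, chain600):
        g = torus_optimal_geometry(chain600, 4.0)
        # frozen from the bounded-Brent oracle
        r_oracle, G_oracle = brute_force_torus(chain600, 4.0)
        assert g.r_t == pytest.approx(r_oracle, rel=1e-8)
        assert g.G == pytest.approx(G_oracle, rel=1e-10)
        assert g.r_t == pytest.approx(2.2365, rel=1e-4)
        assert g.R == pytest.approx(4.773, rel=1e-3)
        assert g.R / g.r_t == pytest.approx(2.134, rel=1e-3)
        assert g.G == pytest.approx(526.76, rel=1e-4)
        assert not g.constrained

    def test_constrained_projection(self, chain600):
        # kb = 2 puts the unconstrained optimum inside the self-intersecting
        # region (R/r < 2); the optimum is projected to R = 2 r_t
        g = torus_optimal_geometry(chain600, 2.0)
        assert g.constrained
        assert g.r_t == pytest.approx((600.0 / (16.0 * math.pi)) ** (1 / 3), rel=1e-12)
        assert g.R == pytest.approx(2.0 * g.r_t, rel=1e-12)
        # oracle restricted to the feasible region agrees
        res = minimize_scalar(
            lambda r: torus_free_energy(r, chain600, 2.0),
            bounds=(1e-3, (600.0 / (16.0 * math.pi)) ** (1 / 3)),
            method="bounded", options={"xatol": 1e-12},
        )
        # the bounded minimizer stops just inside the boundary, so it can
        # only overestimate the edge minimum slightly
        assert g.G <= res.fun + 1e-9 * abs(res.fun)
        assert g.G == pytest.approx(res.fun, rel=1e-6)

    def test_volume_conservation(self, chain600):
        for kb in (0.5, 2.0, 40.0):
            g = torus_optimal_geometry(chain600, kb)
            vol = 2.0 * math.pi**2 * g.R * g.r_t**2
            assert vol == pytest.approx(chain600.volume, rel=1e-10)

    def test_radius_decreases_with_stiffness(self, chain600):
        kbs = np.logspace(0.7, 2, 12)  # all unconstrained at L*=600
        radii = [torus_optimal_geometry(chain600, kb).r_t for kb in kbs]
        assert all(a > b for a, b in zip(radii, radii[1:]))
        # exponent -1/5 exactly
        slope = np.polyfit(np.log(kbs), np.log(radii), 1)[0]
        assert slope == pytest.approx(-0.2, abs=1e-10)

    def test_degenerate_bending_free_chain(self, chain600):
        g = torus_optimal_geometry(chain600, 0.0)
        assert g.degenerate and g.constrained
        assert g.R == pytest.approx(2.0 * g.r_t, rel=1e-12)

    def test_thin_tube_flagged_not_projected(self):
        # very short chain: boundary torus is thinner than half a bead
        g = torus_optimal_geometry(ChainSpec(4.0), 100.0)
        assert g.r_t < 0.5 and g.thin


class TestBundle:
    def test_free_energy_example(self, chain600):
        # side + bare caps + fold penalty at the k1 = 3.23 optimum radius
        val = bundle_free_energy(2.6075, chain600, 3.23)
        side = 0.5 * math.pi * 600.0 / 2.6075
        caps = 2.0 * math.pi * 2.6075**2
        assert val == pytest.approx(side + caps + 3.23 * caps, rel=1e-12)
        assert val == pytest.approx(542.2, abs=0.1)

    def test_no_fold_penalty_at_k1_zero(self, chain600):
        r = 1.9
        assert bundle_free_energy(r, chain600, 0.0) == pytest.approx(
            0.5 * math.pi * 600.0 / r + 2.0 * math.pi * r**2, rel=1e-14
        )

    def test_caps_are_half_of_side_at_optimum(self, chain600):
        for k1 in (0.3, 1.0, 3.23, 40.0):
            g = bundle_optimal_geometry(chain600, k1)
            side = 0.5 * math.pi * 600.0 / g.r_b
            caps = g.G - side
            assert caps == pytest.approx(side / 2.0, rel=1e-10)
            assert g.G == pytest.approx(0.75 * math.pi * 600.0 / g.r_b, rel=1e-12)

    def test_optimal_geometry_example(self, chain600):
        g = bundle_optimal_geometry(chain600, 3.23)
        r_oracle, G_oracle = brute_force_bundle(chain600, 3.23)
        assert g.r_b == pytest.approx(r_oracle, rel=1e-8)
        assert g.G == pytest.approx(G_oracle, rel=1e-10)
        assert g.r_b == pytest.approx(2.6075, rel=1e-4)
        assert g.l == pytest.approx(22.06, rel=1e-3)
        assert g.diameter_ratio == pytest.approx(0.2364, rel=1e-3)

    def test_diameter_ratio_identity(self, chain600):
        for k1 in (0.0, 0.5, 1.0, 7.7, 120.0):
            g = bundle_optimal_geometry(chain600, k1)
            assert g.diameter_ratio == pytest.approx(1.0 / (1.0 + k1), rel=1e-12)
            vol = math.pi * g.r_b**2 * g.l
            assert vol == pytest.approx(chain600.volume, rel=1e-10)
        assert bundle_optimal_geometry(chain600, 1.0).diameter_ratio == pytest.approx(0.5)
        assert bundle_optimal_geometry(chain600, 0.0).diameter_ratio == pytest.approx(1.0)

    def test_globule_flag(self, chain600):
        assert bundle_optimal_geometry(chain600, 0.8).is_globule
        assert not bundle_optimal_geometry(chain600, 1.2).is_globule

    def test_domain_errors(self, chain600):
        with pytest.raises(ValueError):
            bundle_free_energy(0.0, chain600, 1.0)
        with pytest.raises(ValueError):
            bundle_optimal_geometry(chain600, -0.1)


class TestGeometryProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        L=st.floats(10.0, 5000.0, allow_nan=False),
        k1=st.floats(0.0, 500.0, allow_nan=False),
    )
    def test_bundle_identities_hold_everywhere(self, L, k1):
        g = bundle_optimal_geometry(ChainSpec(L), k1)
        assert g.diameter_ratio == pytest.approx(1.0 / (1.0 + k1), rel=1e-9)
        assert math.pi * g.r_b**2 * g.l == pytest.approx(math.pi * L / 4.0, rel=1e-10)
        assert g.G == pytest.approx(0.75 * math.pi * L / g.r_b, rel=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        L=st.floats(10.0, 5000.0, allow_nan=False),
        kb=st.floats(0.0, 500.0, allow_nan=False),
    )
    def test_torus_always_feasible_and_volume_conserving(self, L, kb):
        g = torus_optimal_geometry(ChainSpec(L), kb)
        assert g.R >= 2.0 * g.r_t - 1e-9 * g.r_t
        assert 2.0 * math.pi**2 * g.R * g.r_t**2 == pytest.approx(
            math.pi * L / 4.0, rel=1e-10
        )


class TestOracleEquivalence:
    """Closed-form optima vs independent bounded-Brent minimization."""

    def test_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = rng.uniform(50.0, 2000.0)
            k = 10.0 ** rng.uniform(-2.0, 2.0)
            chain = ChainSpec(L)
            tg = torus_optimal_geometry(chain, k)
            if not tg.constrained:
                r_o, G_o = brute_force_torus(chain, k)
                assert tg.r_t == pytest.approx(r_o, rel=1e-6)
                assert tg.G == pytest.approx(G_o, rel=1e-6)
            bg = bundle_optimal_geometry(chain, k)
            r_o, G_o = brute_force_bundle(chain, k)
            assert bg.r_b == pytest.approx(r_o, rel=1e-6)
            assert bg.G == pytest.approx(G_o, rel=1e-6)

    def test_convexity_at_optimum(self):
        rng = np.random.default_rng(11)
        h = 1e-5
        for _ in range(20):
            L = rng.uniform(50.0, 2000.0)
            k = 10.0 ** rng.uniform(-2.0, 2.0)
            chain = ChainSpec(L)
            tg = torus_optimal_geometry(chain, k)
            d2 = (
                torus_free_energy(tg.r_t + h, chain, k)
                - 2.0 * torus_free_energy(tg.r_t, chain, k)
                + torus_free_energy(tg.r_t - h, chain, k)
            )
            assert d2 > 0
            bg = bundle_optimal_geometry(chain, k)
            d2 = (
                bundle_free_energy(bg.r_b + h, chain, k)
                - 2.0 * bundle_free_energy(bg.r_b, chain, k)
                + bundle_free_energy(bg.r_b - h, chain, k)
            )
            assert d2 > 0
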