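"""Analytic diffusion solutions against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granudiff import pde_engine
from granudiff.forward_models import (
    center_step_response,
    crank_roots,
    finite_bath_bulk,
    flux_sensitivity_study,
    monod_flux_dimensionless,
    quasi_steady_bulk_decline,
    solve_monod_steady,
)
from granudiff.model_system import make_system

D_TRUE = 1.2e-9
R_G = 1.5e-3


class TestCrankRoots:
    def test_defining_residual_small_for_50_roots(self):
        q = crank_roots(4.0, 50).q
        resid = np.abs(np.tan(q) - 3.0 * q / (3.0 + 4.0 * q * q))
        assert resid.max() < 1e-10

    def test_roots_live_in_their_brackets(self):
        q = crank_roots(7.3, 20).q
        n = np.arange(1, 21)
        assert np.all(q > n * math.pi)
        assert np.all(q < n * math.pi + math.pi / 2)

    def test_infinite_bath_limit_approaches_n_pi(self):
        q = crank_roots(1e9, 5).q
        assert np.allclose(q, np.arange(1, 6) * math.pi, atol=1e-3)

    def test_first_root_matches_bisection_oracle(self):
        # plain bisection of tan q = 3q/(3 + alpha q^2) on (pi, 3pi/2)
        alpha = 4.0

        def f(q):
            return math.tan(q) - 3.0 * q / (3.0 + alpha * q * q)

        lo, hi = math.pi + 1e-9, 1.5 * math.pi - 1e-9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        oracle = 0.5 * (lo + hi)
        assert crank_roots(alpha, 1).q[0] == pytest.approx(oracle, abs=1e-10)


class TestFiniteBathBulk:
    def test_initial_and_equilibrium_concentrations(self):
        t = np.array([0.0, 1e8])
        up = finite_bath_bulk(t, D_TRUE, R_G, 4.0, "uptake", 10.0)
        assert up[0] == 10.0
        # mass balance: C_inf = C0 * alpha / (1 + alpha)
        assert up[1] == pytest.approx(8.0, rel=1e-9)
        rel = finite_bath_bulk(t, D_TRUE, R_G, 4.0, "release", 10.0)
        assert rel[0] == 0.0
        assert rel[1] == pytest.approx(2.0, rel=1e-9)

    def test_against_finite_volume_oracle(self, system, uptake_times):
        # independent numerical oracle: conservative finite-volume transient
        sol = pde_engine.solve_sphere_transient(
            system, 4.0, 10.0, 0.0, uptake_times, n_shells=400
        )
        ana = finite_bath_bulk(uptake_times, D_TRUE, R_G, 4.0, "uptake", 10.0)
        dev = np.abs(sol.bulk[1:] - ana[1:]) / ana[1:]
        assert dev.max() < 0.003

    def test_uptake_release_mass_complementarity(self):
        t = np.linspace(0.0, 5000.0, 40)
        up = finite_bath_bulk(t, D_TRUE, R_G, 4.0, "uptake", 10.0)
        rel = finite_bath_bulk(t, D_TRUE, R_G, 4.0, "release", 10.0)
        # release(t) mirrors the uptake deficit through the same F(t)
        assert np.allclose((10.0 - up) * 1.0, rel * 1.0, rtol=0, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        D=st.floats(1e-11, 1e-8),
        alpha=st.floats(0.5, 50.0),
    )
    def test_uptake_monotone_nonincreasing(self, D, alpha):
        t = np.linspace(0.0, 1e4, 60)
        c = finite_bath_bulk(t, D, R_G, alpha, "uptake", 10.0)
        assert np.all(np.diff(c) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            finite_bath_bulk(np.array([-1.0]), D_TRUE, R_G, 4.0)


class TestCenterStepResponse:
    def test_limits(self):
        assert center_step_response(0.0, D_TRUE, R_G) == 0.0
        assert center_step_response(1e9, D_TRUE, R_G) == pytest.approx(1.0, abs=1e-12)

    def test_fourier_number_one_fifth(self):
        # 50-term series evaluated directly as the oracle
        fo = 0.2
        n = np.arange(1, 51)
        oracle = 1.0 + 2.0 * np.sum((-1.0) ** n * np.exp(-(n**2) * math.pi**2 * fo))
        t = fo * R_G**2 / D_TRUE
        assert center_step_response(t, D_TRUE, R_G) == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.7229, abs=2e-4)

    def test_branch_continuity_at_crossover(self):
        # dual (small-Fo) and direct series must agree where they meet
        for fo in (0.2499, 0.2501):
            t = fo * R_G**2 / D_TRUE
            n = np.arange(1, 101)
            oracle = 1.0 + 2.0 * np.sum((-1.0) ** n * np.exp(-(n**2) * math.pi**2 * fo))
            assert center_step_response(t, D_TRUE, R_G) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_in_time(self):
        t = np.geomspace(1.0, 1e5, 200)
        c = center_step_response(t, D_TRUE, R_G)
        assert np.all(np.diff(c) >= -1e-12)


class TestMonodSteadyState:
    def test_zero_order_shallow_penetration_closed_form(self):
        # K -> 0 surrogate with high biomass: J = sqrt(2 D qmax CX Cs)
        s = make_system({"K": 1e-9, "C_X": 1e6})
        C_s = 8.0
        res = solve_monod_steady(s, C_s)
        closed = math.sqrt(2.0 * s.D_g * s.kinetics.volumetric_rate_max * C_s)
        assert res.flux == pytest.approx(closed, rel=0.02)

    def test_reaction_limited_closed_form(self):
        s = make_system({"q_max": 3.54e-6})
        C_s = 8.0
        res = solve_monod_steady(s, C_s)
        closed = s.kinetics.rate(C_s) * s.r_g / 3.0
        assert res.flux == pytest.approx(closed, rel=0.01)
        assert res.penetration_depth == pytest.approx(s.r_g)

    def test_first_order_closed_form(self, system):
        C_s = 1e-4 * system.kinetics.K
        kin = system.kinetics
        phi = system.r_g * math.sqrt(kin.volumetric_rate_max / (kin.K * system.D_g))
        closed = (system.D_g * C_s / system.r_g) * (phi / math.tanh(phi) - 1.0)
        res = solve_monod_steady(system, C_s)
        assert res.flux == pytest.approx(closed, rel=0.01)

    def test_profile_monotone_and_nonnegative(self, system):
        res = solve_monod_steady(system, 8.0)
        _, C = res.profile
        assert np.all(C >= 0)
        assert np.all(np.diff(C) >= -1e-12)

    def test_flux_monotone_in_surface_concentration_and_diffusivity(self, system):
        fluxes = [solve_monod_steady(system, c).flux for c in (0.5, 2.0, 8.0, 32.0)]
        assert np.all(np.diff(fluxes) > 0)
        s_hi = make_system({"D_g": 1.8e-9})
        assert solve_monod_steady(s_hi, 8.0).flux > solve_monod_steady(make_system(), 8.0).flux

    def test_zero_surface_concentration(self, system):
        res = solve_monod_steady(system, 0.0)
        assert res.flux == 0.0
        assert res.penetration_depth == 0.0


class TestMonodFluxTable:
    def test_table_matches_direct_solves(self, system):
        kin = system.kinetics
        for C_s in (0.05, 0.5, 5.0, 40.0):
            phi = system.r_g * math.sqrt(kin.volumetric_rate_max / (kin.K * system.D_g))
            g = monod_flux_dimensionless(phi, C_s / kin.K)
            direct = solve_monod_steady(system, C_s).flux
            tabled = system.D_g * kin.K * g / system.r_g
            assert tabled == pytest.approx(direct, rel=0.01)

    def test_decline_conserves_initial_condition(self, system):
        t = np.array([0.0, 30.0, 600.0])
        c = quasi_steady_bulk_decline(t, system.D_g, system.r_g, 200.0, 8.0,
                                      system.kinetics)
        assert c[0] == 8.0
        assert np.all(np.diff(c) < 0)


class TestFluxSensitivity:
    def test_zero_perturbation_changes_nothing(self, system):
        table = flux_sensitivity_study(system, 0.0, [0.5, 8.0])
        assert np.allclose(table["pct_change"], 0.0, atol=1e-9)

    def test_square_root_law_in_zero_order_shallow_regime(self):
        # near-zero-order kinetics, shallow penetration: J ~ sqrt(D)
        s = make_system({"K": 1e-3, "C_X": 1e6})
        table = flux_sensitivity_study(s, 0.21, [8.0])
        expected = 100.0 * (math.sqrt(1.21) - 1.0)
        assert table["pct_change"].iloc[0] == pytest.approx(expected, abs=0.5)
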