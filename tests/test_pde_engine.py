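"""Transient finite-volume solvers: conservation, convergence, geometry limits."""

import math

import numpy as np
import pytest

from granudiff import pde_engine as pe
from granudiff.forward_models import finite_bath_bulk
from granudiff.model_system import make_system

D_TRUE = 1.2e-9
R_G = 1.5e-3


def sphere_volume(r):
    return 4.0 / 3.0 * math.pi * r**3


class TestSphereTransient:
    def test_matches_series_solution(self, system, uptake_times):
        sol = pe.solve_sphere_transient(system, 4.0, 10.0, 0.0, uptake_times)
        ana = finite_bath_bulk(uptake_times, D_TRUE, R_G, 4.0, "uptake", 10.0)
        dev = np.abs(sol.bulk[1:] - ana[1:]) / ana[1:]
        assert dev.max() < 0.005
        assert sol.mass_residual < 1e-3

    def test_no_transport_keeps_bulk_constant(self, system, uptake_times):
        sol = pe.solve_sphere_transient(
            system, 4.0, 10.0, 0.0, uptake_times, D_granule=1e-20
        )
        assert np.allclose(sol.bulk, 10.0, rtol=1e-7)

    def test_spatial_convergence_second_order(self, system):
        times = np.arange(60.0, 3600.0 + 1e-9, 60.0)
        ana = finite_bath_bulk(times, D_TRUE, R_G, 4.0, "uptake", 10.0)
        errs = []
        for n in (20, 40, 80):
            sol = pe.solve_sphere_transient(
                system, 4.0, 10.0, 0.0, times, n_shells=n, time_refine=6
            )
            errs.append(np.max(np.abs(sol.bulk - ana) / ana))
        order1 = math.log(errs[0] / errs[1]) / math.log(2.0)
        order2 = math.log(errs[1] / errs[2]) / math.log(2.0)
        assert order1 > 1.8
        assert order2 > 1.8

    def test_mixed_bath_equivalent_to_high_diffusivity_continuum(self, system):
        # the well-mixed compartment replaces a continuum liquid of very high
        # diffusivity; put 99% of the liquid in a D=1e-5 m^2/s shell instead
        times = np.arange(60.0, 3600.0 + 1e-9, 120.0)
        from scipy.optimize import brentq

        v_g = sphere_volume(R_G)
        film = brentq(
            lambda L: sphere_volume(R_G + L) - v_g - 0.99 * 4.0 * v_g, 1e-6, 0.1
        )
        hi = pe.GranuleSystem(r_g=R_G, D_g=D_TRUE, D_aq=1e-5, kinetics=system.kinetics)
        sol_cont = pe.solve_sphere_transient(
            hi, 4.0, 10.0, 0.0, times, film_thickness=film, n_shells=200
        )
        sol_comp = pe.solve_sphere_transient(system, 4.0, 10.0, 0.0, times, n_shells=200)
        dev = np.abs(sol_cont.bulk - sol_comp.bulk) / sol_comp.bulk
        assert dev.max() < 1e-3

    def test_film_slows_uptake(self, system, uptake_times):
        free = pe.solve_sphere_transient(system, 4.0, 10.0, 0.0, uptake_times)
        filmed = pe.solve_sphere_transient(
            system, 4.0, 10.0, 0.0, uptake_times, film_thickness=100e-6
        )
        # external resistance keeps the bulk concentration higher at all times
        assert np.all(filmed.bulk[1:] >= free.bulk[1:])
        assert filmed.bulk[10] > free.bulk[10]

    def test_kinetics_sink_consumes_solute(self, system):
        times = np.arange(0.0, 600.0 + 1e-9, 60.0)
        inert = pe.solve_sphere_transient(system, 4.0, 8.0, 0.0, times, n_shells=80)
        reacting = pe.solve_sphere_transient(
            system, 4.0, 8.0, 0.0, times, n_shells=80, kinetics_on=True
        )
        assert reacting.bulk[-1] < inert.bulk[-1]


class TestCoupledGranules:
    def test_equal_radii_match_single_granule(self, system, uptake_times):
        single = pe.solve_sphere_transient(system, 4.0, 10.0, 0.0, uptake_times)
        four = pe.solve_coupled_granules([R_G] * 4, system, 4.0, 10.0, uptake_times)
        assert np.allclose(four.bulk, single.bulk, rtol=2e-4)

    def test_zero_spread_equals_base_case(self, system, uptake_times):
        base = pe.solve_coupled_granules([R_G] * 4, system, 4.0, 10.0, uptake_times)
        spread = pe.solve_coupled_granules(
            [R_G, R_G, R_G - 0.0, R_G + 0.0], system, 4.0, 10.0, uptake_times
        )
        assert np.allclose(base.bulk, spread.bulk, rtol=1e-12)

    def test_empty_radii_rejected(self, system, uptake_times):
        with pytest.raises(ValueError):
            pe.solve_coupled_granules([], system, 4.0, 10.0, uptake_times)


class TestAxisymmetric:
    def test_smooth_sphere_dispatch_matches_series(self, system, uptake_times):
        geom = pe.Geometry2D(
            "smooth_sphere", {"radius": R_G}, bath_volume=4.0 * sphere_volume(R_G)
        )
        sol = pe.solve_axisym_transient(geom, system, 10.0, uptake_times)
        ana = finite_bath_bulk(uptake_times, D_TRUE, R_G, 4.0, "uptake", 10.0)
        assert np.max(np.abs(sol.bulk[1:] - ana[1:]) / ana[1:]) < 0.005

    def test_vanishing_roughness_reduces_to_smooth_sphere(self, system, uptake_times):
        geom = pe.Geometry2D(
            "rough_sphere", {"radius": R_G, "amplitude": 1e-9, "waves": 10},
            bath_volume=4.0 * sphere_volume(R_G),
        )
        sol = pe.solve_axisym_transient(geom, system, 10.0, uptake_times,
                                        n_r=110, n_theta=128)
        ana = finite_bath_bulk(uptake_times, D_TRUE, R_G, 4.0, "uptake", 10.0)
        assert np.max(np.abs(sol.bulk[1:] - ana[1:]) / ana[1:]) < 0.005
        assert sol.mass_residual < 1e-3

    def test_near_spherical_oblate_matches_series(self, system, uptake_times):
        a, c = 1.5005e-3, 1.4995e-3
        geom = pe.Geometry2D(
            "oblate_spheroid", {"a": a, "c": c},
            bath_volume=4.0 * (4.0 / 3.0 * math.pi * a * a * c),
        )
        sol = pe.solve_axisym_transient(geom, system, 10.0, uptake_times,
                                        n_mu=100, n_nu=80)
        ana = finite_bath_bulk(uptake_times, D_TRUE, R_G, 4.0, "uptake", 10.0)
        assert np.max(np.abs(sol.bulk[1:] - ana[1:]) / ana[1:]) < 0.005

    def test_meshed_volumes_match_analytic(self, system, uptake_times):
        # rough sphere at the typical roughness parameters
        rough = pe.Geometry2D(
            "rough_sphere", {"radius": R_G, "amplitude": 50e-6, "waves": 10},
            bath_volume=4.0 * sphere_volume(R_G),
        )
        sol = pe.solve_axisym_transient(
            rough, system, 10.0, uptake_times[:2], n_r=220, n_theta=320
        )
        v_exact = pe.analytic_granule_volume(rough)
        assert sol.meshed_volume == pytest.approx(v_exact, rel=1e-3)
        oblate = pe.Geometry2D(
            "oblate_spheroid", {"a": 1.80e-3, "c": 1.04e-3},
            bath_volume=4.0 * (4.0 / 3.0 * math.pi * 1.80e-3**2 * 1.04e-3),
        )
        sol2 = pe.solve_axisym_transient(
            oblate, system, 10.0, uptake_times[:2], n_mu=120, n_nu=96
        )
        assert sol2.meshed_volume == pytest.approx(
            pe.analytic_granule_volume(oblate), rel=1e-3
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            pe.Geometry2D("cube", {}, bath_volume=1.0)
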