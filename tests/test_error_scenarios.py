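"""Systematic-error scenarios: closed forms, oracles, limits and signs."""

import numpy as np
import pytest

from granudiff.error_scenarios import (
    ErrorScenario,
    combined_ratio,
    deactivation_ratio,
    run_scenario,
    simulate_scenario_uptake,
    sorption_ratio,
)
from granudiff.forward_models import finite_bath_bulk
from granudiff.method_fitters import LOG10_D_BOUNDS
from granudiff.model_system import make_system

D_TRUE = 1.2e-9

COARSE = {"n_shells": 150, "n_r": 110, "n_theta": 160, "n_mu": 100, "n_nu": 80}


class TestSorption:
    @pytest.mark.parametrize("k,expected", [(0.0, 1.0), (1.0, 0.5), (0.25, 0.8)])
    def test_retardation_closed_form(self, k, expected):
        assert sorption_ratio(k).ratio == pytest.approx(expected, rel=1e-12)

    def test_retarded_transient_equals_rescaled_crank_solution(self, system, designs):
        """Instant linear sorption maps exactly onto the ideal finite-bath
        problem with D -> D/(1+k) and alpha -> alpha/(1+k); the transient
        solver must reproduce that equivalence."""
        k = 0.25
        d = designs[2]
        values = simulate_scenario_uptake(
            ErrorScenario("sorption", {"k": k}), system, d,
            resolution={"n_shells": 300},
        )
        R = 1.0 + k
        oracle = finite_bath_bulk(
            d.sample_times, D_TRUE / R, system.r_g, d.alpha / R, "uptake", 10.0
        )
        dev = np.abs(values[1:] - oracle[1:]) / oracle[1:]
        assert dev.max() < 0.003

    def test_equilibrium_matched_fit_recovers_retarded_diffusivity(
        self, system, designs
    ):
        """Fitting the fractional approach with the observed equilibrium (the
        standard practice for uptake fits) recovers D/(1+k)."""
        from scipy.optimize import minimize_scalar

        k = 0.25
        d = designs[2]
        values = simulate_scenario_uptake(
            ErrorScenario("sorption", {"k": k}), system, d,
            resolution={"n_shells": 300},
        )
        alpha_eff = values[-1] / (d.C0_bulk - values[-1])  # from observed plateau

        def obj(x):
            model = finite_bath_bulk(
                d.sample_times, 10.0**x, system.r_g, alpha_eff, "uptake", d.C0_bulk
            )
            return float(np.sum((model - values) ** 2))

        res = minimize_scalar(obj, bounds=LOG10_D_BOUNDS, method="bounded",
                              options={"xatol": 1e-4})
        assert 10.0**res.x / D_TRUE == pytest.approx(1.0 / (1.0 + k), rel=0.02)

    def test_negative_capacity_rejected(self):
        with pytest.raises(ValueError):
            sorption_ratio(-0.1)


class TestDeactivation:
    def test_no_cells_means_no_change(self):
        assert deactivation_ratio(0.0, 0.3).ratio == 1.0

    def test_equal_diffusivities_mean_no_change(self):
        assert deactivation_ratio(0.3, 0.7, 0.7).ratio == pytest.approx(1.0)

    def test_overestimation_bounded_by_water(self, system):
        # sweep feasible cell fractions with impermeable alive cells: the
        # permeabilised granule can at most reach the aqueous diffusivity,
        # capping the overestimation near D_aq/D_g
        best = 0.0
        for phi in np.linspace(0.0, 0.5, 26):
            try:
                r = deactivation_ratio(phi, 0.0, 1.0, system=system).ratio
            except ValueError:
                break  # implied matrix would out-diffuse water
            best = max(best, r)
        assert best <= system.D_aq / system.D_g + 1e-9
        assert best > 1.5

    def test_infeasible_matrix_rejected(self, system):
        with pytest.raises(ValueError, match="infeasible"):
            deactivation_ratio(0.5, 0.0, 1.0, system=system)

    def test_typical_case_modest_overestimation(self, system):
        r = deactivation_ratio(0.30, 0.5, 1.0, system=system).ratio
        assert 1.1 < r < 1.3


class TestCombination:
    def test_identity_and_arithmetic(self):
        assert combined_ratio([1.0, 1.0, 1.0]) == 1.0
        assert combined_ratio([0.9, 1.1]) == pytest.approx(0.99)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combined_ratio([])


class TestSimulatedScenarios:
    def test_degenerate_parameters_recover_truth(self, system, designs):
        d = designs[2]
        cases = [
            ErrorScenario("mtbl", {"film_thickness": 1e-9}),
            ErrorScenario("size_distribution", {"delta": 0.0}),
            ErrorScenario("roughness", {"amplitude": 1e-7, "waves": 10}),
            ErrorScenario("shape", {"a": 1.5e-3, "c": 1.4999e-3}),
        ]
        for sc in cases:
            ratio = run_scenario(sc, system, d, resolution=COARSE).ratio
            assert ratio == pytest.approx(1.0, abs=0.01), sc.kind

    def test_boundary_layer_ratio_decreases_with_thickness(self, system, designs):
        d = designs[2]
        ratios = [
            run_scenario(
                ErrorScenario("mtbl", {"film_thickness": L}), system, d,
                resolution=COARSE,
            ).ratio
            for L in (50e-6, 100e-6, 400e-6)
        ]
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[1] < 0.95  # clear underestimation at 100 um

    def test_size_spread_ratio_decreases_with_delta(self, system, designs):
        d = designs[2]
        ratios = [
            run_scenario(
                ErrorScenario("size_distribution", {"delta": dd}), system, d,
                resolution=COARSE,
            ).ratio
            for dd in (0.1e-3, 0.3e-3, 0.5e-3)
        ]
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] < 0.9

    def test_spheroid_overestimates(self, system, designs):
        r = run_scenario(
            ErrorScenario.typical("shape"), system, designs[2], resolution=COARSE
        ).ratio
        assert r > 1.05

    def test_sweep_table(self, system, designs):
        res = run_scenario(
            ErrorScenario("mtbl", {"film_thickness": 100e-6}), system, designs[2],
            sweep=[{"film_thickness": 0.0001e-6}, {"film_thickness": 200e-6}],
            resolution=COARSE,
        )
        assert res.sweep is not None
        assert len(res.sweep) == 2
        assert res.sweep["ratio"].iloc[0] > res.sweep["ratio"].iloc[1]

    def test_analytic_kinds_rejected_by_run_scenario(self, system, designs):
        with pytest.raises(ValueError):
            run_scenario(ErrorScenario("sorption", {"k": 0.1}), system, designs[2])
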