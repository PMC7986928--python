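"""Systematic-error studies: forward-simulate the corrupted uptake experiment.

Six sources of inaccuracy corrupt the transient-uptake experiment:

* sorption — instantaneous linear binding retards the apparent diffusion
  (closed form: D_apparent = D / (1 + k), ratio = 1/(1+k));
* deactivation — permeabilising the cells opens intracellular volume for
  diffusion; a Maxwell effective-medium model relates the granule
  diffusivity before and after permeabilisation;
* mass transfer boundary layer (MTBL) — a stagnant film adds external
  resistance;
* surface roughness — sinusoidal valleys filled with stagnant liquid
  lengthen the diffusion path;
* shape — an oblate spheroid has more surface per volume than the sphere
  assumed in fitting;
* size distribution — a mix of granule sizes is fitted as if monodisperse.

For the four geometry/transport errors the corrupted experiment is solved
with the transient finite-volume engines, then fitted naively with the
transient-uptake (Crank finite-bath) fitter assuming a single smooth sphere
of nominal radius; D_observed/D_true is the inaccuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from granudiff.method_fitters import AssumedParams, fit_diffusion
from granudiff.model_system import ExperimentDesign, GranuleSystem
from granudiff.pde_engine import (
    Geometry2D,
    analytic_granule_volume,
    solve_axisym_transient,
    solve_coupled_granules,
    solve_sphere_transient,
)

__all__ = [
    "ErrorScenario",
    "ScenarioResult",
    "simulate_scenario_uptake",
    "run_scenario",
    "sorption_ratio",
    "deactivation_ratio",
    "combined_ratio",
    "typical_scenarios",
    "TYPICAL_PARAMETERS",
]

_SIMULATED_KINDS = ("mtbl", "roughness", "shape", "size_distribution")
_ALL_KINDS = ("sorption", "deactivation") + _SIMULATED_KINDS

#: typical parameterisations of each systematic error
TYPICAL_PARAMETERS: dict[str, dict] = {
    "mtbl": {"film_thickness": 100e-6},
    "roughness": {"amplitude": 50e-6, "waves": 10},
    "shape": {"a": 1.80e-3, "c": 1.04e-3},
    "size_distribution": {"delta": 0.5e-3},
    "deactivation": {
        "cell_fraction": 0.30,
        "alive_relative_diffusivity": 0.5,
        "dead_relative_diffusivity": 1.0,
    },
}


@dataclass(frozen=True)
class ErrorScenario:
    """One systematic error with its parameterisation.

    ``parameters`` keys by kind: mtbl -> film_thickness [m]; roughness ->
    amplitude [m], waves; shape -> a, c [m]; size_distribution -> delta [m];
    sorption -> k (bound/free capacity ratio); deactivation ->
    cell_fraction, alive_relative_diffusivity, dead_relative_diffusivity.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _ALL_KINDS:
            raise ValueError(f"kind must be one of {_ALL_KINDS}, got {self.kind!r}")

    @classmethod
    def typical(cls, kind: str) -> "ErrorScenario":
        return cls(kind=kind, parameters=dict(TYPICAL_PARAMETERS[kind]))


@dataclass
class ScenarioResult:
    """D_observed/D_true for one systematic error."""

    kind: str
    parameters: dict
    ratio: float
    sweep: object | None = None  # optional pandas.DataFrame

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")


def simulate_scenario_uptake(
    scenario: ErrorScenario,
    system: GranuleSystem,
    design: ExperimentDesign,
    resolution: dict | None = None,
) -> np.ndarray:
    """Bulk series of the transient-uptake experiment under the scenario."""
    p = scenario.parameters
    times = design.sample_times
    res = resolution or {}
    if scenario.kind == "mtbl":
        sol = solve_sphere_transient(
            system, design.alpha, design.C0_bulk, 0.0, times,
            film_thickness=p["film_thickness"],
            n_shells=res.get("n_shells", 300),
        )
        return sol.bulk
    if scenario.kind == "sorption":
        sol = solve_sphere_transient(
            system, design.alpha, design.C0_bulk, 0.0, times,
            retardation=1.0 + p["k"], n_shells=res.get("n_shells", 300),
        )
        return sol.bulk
    if scenario.kind == "size_distribution":
        delta = p["delta"]
        radii = [system.r_g - delta, system.r_g, system.r_g, system.r_g + delta]
        sol = solve_coupled_granules(
            radii, system, design.alpha, design.C0_bulk, times,
            n_shells=res.get("n_shells", 200),
        )
        return sol.bulk
    if scenario.kind == "roughness":
        geom = Geometry2D(
            "rough_sphere",
            {"radius": system.r_g, "amplitude": p["amplitude"], "waves": p["waves"]},
            bath_volume=design.alpha * analytic_granule_volume(
                Geometry2D("rough_sphere",
                           {"radius": system.r_g, "amplitude": p["amplitude"],
                            "waves": p["waves"]}, bath_volume=1.0)
            ),
        )
        sol = solve_axisym_transient(
            geom, system, design.C0_bulk, times,
            n_r=res.get("n_r", 220), n_theta=res.get("n_theta", 320),
        )
        return sol.bulk
    if scenario.kind == "shape":
        a, c = p["a"], p["c"]
        v = 4.0 / 3.0 * math.pi * a * a * c
        geom = Geometry2D("oblate_spheroid", {"a": a, "c": c},
                          bath_volume=design.alpha * v)
        sol = solve_axisym_transient(
            geom, system, design.C0_bulk, times,
            n_mu=res.get("n_mu", 140), n_nu=res.get("n_nu", 112),
        )
        return sol.bulk
    raise ValueError(f"{scenario.kind} has no transient simulation")


def _naive_fit_ratio(
    values: np.ndarray, system: GranuleSystem, design: ExperimentDesign
) -> float:
    """Fit the corrupted series with the ideal smooth-sphere uptake model."""
    from granudiff.virtual_experiments import Dataset

    ds = Dataset(
        method_id=2, kind="time_series", abscissa=design.sample_times,
        values=np.maximum(values, 0.0), nominal_design=design,
    )
    assumed = AssumedParams.truth(system, design)
    fit = fit_diffusion(ds, assumed)
    return fit.D_hat / system.D_g


def run_scenario(
    scenario: ErrorScenario,
    system: GranuleSystem,
    design: ExperimentDesign,
    sweep: list[dict] | None = None,
    resolution: dict | None = None,
) -> ScenarioResult:
    """Simulate the corrupted uptake experiment and fit it naively.

    ``sweep`` optionally lists parameter dictionaries for a sensitivity
    sweep; the result's ``sweep`` table then holds one ratio per entry.
    """
    if scenario.kind not in _SIMULATED_KINDS:
        raise ValueError(
            f"run_scenario simulates {_SIMULATED_KINDS}; use sorption_ratio or "
            "deactivation_ratio for the analytic errors"
        )
    values = simulate_scenario_uptake(scenario, system, design, resolution)
    ratio = _naive_fit_ratio(values, system, design)
    table = None
    if sweep:
        import pandas as pd

        rows = []
        for params in sweep:
            sc = replace(scenario, parameters={**scenario.parameters, **params})
            v = simulate_scenario_uptake(sc, system, design, resolution)
            rows.append({**params, "ratio": _naive_fit_ratio(v, system, design)})
        table = pd.DataFrame(rows)
    return ScenarioResult(
        kind=scenario.kind, parameters=dict(scenario.parameters),
        ratio=ratio, sweep=table,
    )


def sorption_ratio(k: float) -> ScenarioResult:
    """Retardation by instantaneous linear sorption: ratio = 1/(1+k).

    ``k`` is the equilibrium bound/free capacity ratio; a transient fit that
    ignores sorption sees the retarded apparent diffusivity D/(1+k).
    """
    if k < 0:
        raise ValueError("sorption capacity ratio must be >= 0")
    return ScenarioResult(kind="sorption", parameters={"k": k}, ratio=1.0 / (1.0 + k))


def _maxwell(phi: float, d: float) -> float:
    """Maxwell effective-medium relative diffusivity of a cell suspension.

    ``phi`` is the cell volume fraction and ``d`` the cell diffusivity
    relative to the continuous matrix: D_eff/D_matrix =
    (2(1-phi) + d(1+2 phi)) / ((2+phi) + d(1-phi)).
    """
    return (2.0 * (1.0 - phi) + d * (1.0 + 2.0 * phi)) / (
        (2.0 + phi) + d * (1.0 - phi)
    )


def deactivation_ratio(
    cell_volume_fraction: float,
    relative_cell_diffusivity_alive: float,
    relative_cell_diffusivity_dead: float = 1.0,
    system: GranuleSystem | None = None,
) -> ScenarioResult:
    """Overestimation caused by permeabilising cells before the measurement.

    The granule is a matrix with embedded cells at volume fraction phi.
    Alive cells transmit the solute at a fraction ``d_alive`` of the matrix
    diffusivity; permeabilised (dead) cells at ``d_dead``.  The measured
    ratio is D_dead/D_alive from the Maxwell effective-medium relation.  If
    a ``system`` is given, the matrix diffusivity implied by anchoring the
    alive granule at D_g is checked against the aqueous diffusivity (a
    biofilm matrix cannot out-diffuse water), flagging infeasible
    configurations.
    """
    phi = cell_volume_fraction
    if not 0.0 <= phi < 1.0:
        raise ValueError("cell volume fraction must be in [0, 1)")
    for d in (relative_cell_diffusivity_alive, relative_cell_diffusivity_dead):
        if d < 0:
            raise ValueError("relative cell diffusivities must be >= 0")
    m_alive = _maxwell(phi, relative_cell_diffusivity_alive)
    m_dead = _maxwell(phi, relative_cell_diffusivity_dead)
    if system is not None:
        matrix_D = system.D_g / m_alive
        if matrix_D > system.D_aq * (1.0 + 1e-12):
            raise ValueError(
                f"infeasible: implied matrix diffusivity {matrix_D:.3g} exceeds "
                f"the aqueous value {system.D_aq:.3g}"
            )
    return ScenarioResult(
        kind="deactivation",
        parameters={
            "cell_fraction": phi,
            "alive_relative_diffusivity": relative_cell_diffusivity_alive,
            "dead_relative_diffusivity": relative_cell_diffusivity_dead,
        },
        ratio=m_dead / m_alive,
    )


def combined_ratio(ratios: list[float]) -> float:
    """Multiplicative combination of independent systematic errors."""
    if len(ratios) == 0:
        raise ValueError("need at least one ratio")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    return float(np.prod(ratios))


def typical_scenarios(
    system: GranuleSystem,
    design: ExperimentDesign,
    resolution: dict | None = None,
) -> dict[str, ScenarioResult]:
    """All typical-case scenario results plus their multiplicative combination.

    Sorption is excluded from the combination (no typical magnitude can be
    assigned to it for an oxygen-like solute); the combination covers the
    boundary layer, roughness, shape, size distribution and deactivation.
    """
    out: dict[str, ScenarioResult] = {}
    for kind in _SIMULATED_KINDS:
        out[kind] = run_scenario(
            ErrorScenario.typical(kind), system, design, resolution=resolution
        )
    p = TYPICAL_PARAMETERS["deactivation"]
    out["deactivation"] = deactivation_ratio(
        p["cell_fraction"], p["alive_relative_diffusivity"],
        p["dead_relative_diffusivity"], system=system,
    )
    out["combined"] = ScenarioResult(
        kind="combined", parameters={},
        ratio=combined_ratio([out[k].ratio for k in
                              ("mtbl", "roughness", "shape", "size_distribution",
                               "deactivation")]),
    )
    return out
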