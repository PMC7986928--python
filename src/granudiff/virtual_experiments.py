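"""Simulated experimental datasets for the six measurement methods.

Each method's virtual experiment produces the record an experimentalist
would take home:

1. steady-state reaction — bulk oxygen decline driven by the quasi-steady
   Monod flux into the granules;
2. transient uptake of a non-reactive solute — bulk concentration series of
   the finite-bath Crank solution;
3. transient release — the mirror image of 2;
4. steady-state microelectrode profile across the boundary layer and the
   granule surface region;
5. steady-state reaction with an internal profile — bulk decline plus a
   microelectrode profile just inside the surface;
6. transient penetration to the centre — centre concentration after a step
   change of the bath concentration.

Measurement noise is multiplicative Gaussian per concentration reading.
Electrode-position miscalibration is not baked into the stored data: in the
Monte Carlo analysis it enters through the analyst's assumed step size,
which is statistically equivalent and keeps the dataset nominal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from granudiff.forward_models import (
    center_step_response,
    finite_bath_bulk,
    monod_flux_dimensionless,
    quasi_steady_bulk_decline,
    solve_monod_steady,
)
from granudiff.model_system import ExperimentDesign, GranuleSystem, UncertaintySpec

__all__ = ["Dataset", "simulate_experiment", "steady_profile_with_film"]


@dataclass
class Dataset:
    """One simulated measurement record.

    ``abscissa`` is either sample times [s] (time series) or signed
    electrode depths [m] (spatial profile; negative = outside the granule).
    Method 5 carries both: the bulk time series in the primary arrays and
    the interior microelectrode profile in ``profile_positions`` /
    ``profile_values``.
    """

    method_id: int
    kind: str
    abscissa: np.ndarray
    values: np.ndarray
    nominal_design: ExperimentDesign
    seed: int | None = None
    profile_positions: np.ndarray = field(default_factory=lambda: np.array([]))
    profile_values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("time_series", "spatial_profile"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if self.abscissa.shape != self.values.shape:
            raise ValueError("abscissa and values must have matching shapes")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        """Write the data as CSV with a JSON sidecar of design metadata."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame({"abscissa": self.abscissa, "value": self.values}).to_csv(
            path, index=False
        )
        if self.profile_positions.size:
            pd.DataFrame(
                {"position": self.profile_positions, "value": self.profile_values}
            ).to_csv(path.with_suffix(".profile.csv"), index=False)
        design = self.nominal_design
        meta = {
            "method_id": self.method_id,
            "kind": self.kind,
            "seed": self.seed,
            "design": {
                "alpha": design.alpha,
                "C0_bulk": design.C0_bulk,
                "C0_granule": design.C0_granule,
                "V_T": design.V_T,
                "V_G": design.V_G,
                "electrode_step": design.electrode_step,
                "film_thickness": design.film_thickness,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def steady_profile_with_film(system: GranuleSystem, C_b: float, film: float):
    """Steady concentration field of a respiring granule behind a stagnant film.

    The surface concentration C_s solves the flux match between the internal
    Monod diffusion-reaction problem and conduction through the spherical
    stagnant shell, J_int(C_s) = k_ext (C_b - C_s) with
    k_ext = D_aq (r+L) / (r L).  Returns (C_s, J, profile function of signed
    depth z: negative z in the liquid, positive z inside the granule).
    """
    if film <= 0:
        raise ValueError("microelectrode experiments need a finite boundary layer")
    r, D_aq = system.r_g, system.D_aq
    k_ext = D_aq * (r + film) / (r * film)

    def balance(C_s: float) -> float:
        return solve_monod_steady(system, C_s).flux - k_ext * (C_b - C_s)

    C_s = brentq(balance, 0.0, C_b, rtol=1e-12)
    inner = solve_monod_steady(system, C_s)
    J = inner.flux
    radii, conc = inner.profile

    def profile(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        inside = z >= 0
        out[inside] = np.interp(r - z[inside], radii, conc)
        rpos = r - z[~inside]  # > r
        c_film = C_b - (J * r * r / D_aq) * (1.0 / rpos - 1.0 / (r + film))
        out[~inside] = np.where(rpos >= r + film, C_b, c_film)
        return out

    return C_s, J, profile


def _film_limited_decline(
    system: GranuleSystem, design: ExperimentDesign, times: np.ndarray
) -> np.ndarray:
    """Quasi-steady bulk decline when a stagnant film adds external resistance.

    Uses the cached dimensionless Monod flux for the interior and resolves
    the film/interior flux match per sub-step of a classical RK4 march.
    """
    kin = system.kinetics
    r, D_aq, D_g, K = system.r_g, system.D_aq, system.D_g, kin.K
    film = design.film_thickness
    k_ext = D_aq * (r + film) / (r * film)
    phi = r * np.sqrt(kin.volumetric_rate_max / (K * D_g))
    beta = (3.0 * design.V_G / r) / design.V_L  # granule area / liquid volume

    def J_tot(C_b: float) -> float:
        if C_b <= 0:
            return 0.0

        def bal(C_s: float) -> float:
            J_int = D_g * K * float(monod_flux_dimensionless(phi, C_s / K)) / r
            return J_int - k_ext * (C_b - C_s)

        C_s = brentq(bal, 0.0, C_b, rtol=1e-10)
        return k_ext * (C_b - C_s)

    out = np.empty_like(times)
    C = design.C0_bulk
    t_prev = 0.0
    for i, t in enumerate(times):
        span = t - t_prev
        if span > 0:
            n_sub = max(1, int(np.ceil(span / 5.0)))
            h = span / n_sub
            for _ in range(n_sub):
                k1 = -beta * J_tot(C)
                k2 = -beta * J_tot(C + 0.5 * h * k1)
                k3 = -beta * J_tot(C + 0.5 * h * k2)
                k4 = -beta * J_tot(C + h * k3)
                C = C + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = C
        t_prev = t
    return out


def simulate_experiment(
    method_id: int,
    system: GranuleSystem,
    design: ExperimentDesign,
    scenario=None,
    noise: UncertaintySpec | None = None,
    seed: int | None = None,
) -> Dataset:
    """Simulate the dataset an experimentalist would record with the method.

    With ``scenario`` (transient uptake only) the bulk series comes from the
    full numerical model of the corrupted experiment instead of the ideal
    closed form.  With ``noise`` every concentration reading receives an
    independent multiplicative Gaussian perturbation at the RSD of its
    channel (C_B for bulk samples, C_M for microelectrode readings).
    """
    if design.method_id != method_id:
        raise ValueError(
            f"design is for method {design.method_id}, asked for {method_id}"
        )
    times = design.sample_times
    rng = np.random.default_rng(seed)

    profile_positions = np.array([])
    profile_values = np.array([])

    if scenario is not None:
        if method_id != 2:
            raise ValueError(
                "systematic-error scenarios apply to the transient-uptake method"
            )
        from granudiff.error_scenarios import simulate_scenario_uptake

        values = simulate_scenario_uptake(scenario, system, design)
        kind, abscissa, noise_channel = "time_series", times, "C_B"
    elif method_id == 1:
        beta = (3.0 * design.V_G / system.r_g) / design.V_L
        values = quasi_steady_bulk_decline(
            times, system.D_g, system.r_g, beta, design.C0_bulk, system.kinetics
        )
        kind, abscissa, noise_channel = "time_series", times, "C_B"
    elif method_id in (2, 3):
        mode = "uptake" if method_id == 2 else "release"
        C_init = design.C0_bulk if method_id == 2 else design.C0_granule
        values = finite_bath_bulk(
            times, system.D_g, system.r_g, design.alpha, mode, C_init
        )
        kind, abscissa, noise_channel = "time_series", times, "C_B"
    elif method_id == 4:
        _, _, profile = steady_profile_with_film(
            system, design.C0_bulk, design.film_thickness
        )
        values = profile(design.electrode_positions)
        kind, abscissa, noise_channel = (
            "spatial_profile", design.electrode_positions, "C_M",
        )
    elif method_id == 5:
        values = _film_limited_decline(system, design, times)
        kind, abscissa, noise_channel = "time_series", times, "C_B"
        C_b_at_profile = float(np.interp(design.profile_time, times, values))
        _, _, profile = steady_profile_with_film(
            system, C_b_at_profile, design.film_thickness
        )
        profile_positions = design.electrode_positions
        profile_values = profile(profile_positions)
    elif method_id == 6:
        values = design.C0_bulk * center_step_response(times, system.D_g, system.r_g)
        kind, abscissa, noise_channel = "time_series", times, "C_M"
    else:
        raise ValueError(f"method_id must be 1..6, got {method_id}")

    if noise is not None:
        rsd = noise.rsd.get(noise_channel, 0.0)
        if rsd > 0:
            values = values * (1.0 + rsd * rng.standard_normal(values.shape))
        if profile_values.size:
            rsd_m = noise.rsd.get("C_M", 0.0)
            if rsd_m > 0:
                profile_values = profile_values * (
                    1.0 + rsd_m * rng.standard_normal(profile_values.shape)
                )
        values = np.maximum(values, 0.0)
        profile_values = np.maximum(profile_values, 0.0)

    return Dataset(
        method_id=method_id, kind=kind, abscissa=abscissa, values=values,
        nominal_design=design, seed=seed,
        profile_positions=profile_positions, profile_values=profile_values,
    )
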