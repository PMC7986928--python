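"""The six inverse procedures estimating D from a simulated dataset.

Every fitter receives the dataset together with the analyst's *assumed*
parameter values (granule radius, volumes, kinetics, electrode step, ...),
which in the Monte Carlo analysis are perturbed copies of the truth.  The
Fick's-2nd-law methods (1, 2, 3, 6) fit a transient model by bounded scalar
least squares over log10 D in [-11, -8]; the Fick's-1st-law methods (4, 5)
evaluate concentration gradients directly with small linear regressions.

The gradient windows of methods 4 and 5 are the four electrode positions
adjacent to the interface on each side.  Because the real steady profile is
curved on the scale of the penetration depth, these linear windows carry an
inherent positive bias — that bias is a property of the measurement
procedure itself, not of the fit, and it is what the Monte Carlo analysis
reports as the inherent inaccuracy of the microelectrode methods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from granudiff.forward_models import (
    center_step_response,
    finite_bath_bulk,
    quasi_steady_bulk_decline,
)
from granudiff.model_system import ExperimentDesign, GranuleSystem, MonodKinetics
from granudiff.virtual_experiments import Dataset

__all__ = ["AssumedParams", "FitResult", "fit_diffusion"]

LOG10_D_BOUNDS = (-11.0, -8.0)


@dataclass(frozen=True)
class AssumedParams:
    """The analyst's believed parameter values used in fitting.

    ``C_B_scale`` scales the assumed initial/step concentration relative to
    the design nominal (the analyst knows the prepared concentration only to
    the bulk-concentration uncertainty); ``dx`` is the believed electrode
    step size.  ``q_max`` is in per-second units, as stored in the kinetics.
    """

    V_G: float
    V_T: float
    r_g: float
    C_X: float
    K: float
    q_max: float
    dx: float
    C_B_scale: float = 1.0
    C_M_scale: float = 1.0
    D_aq: float = 2.0e-9

    @classmethod
    def truth(cls, system: GranuleSystem, design: ExperimentDesign) -> "AssumedParams":
        kin = system.kinetics
        return cls(
            V_G=design.V_G, V_T=design.V_T, r_g=system.r_g,
            C_X=kin.C_X, K=kin.K, q_max=kin.q_max,
            dx=design.electrode_step if design.electrode_step else 50e-6,
            D_aq=system.D_aq,
        )

    def perturb(self, factors: dict[str, float]) -> "AssumedParams":
        """Multiply selected fields by (1 + relative error) factors."""
        updates = {}
        for name, f in factors.items():
            if name == "C_B":
                updates["C_B_scale"] = self.C_B_scale * f
            elif name == "C_M":
                updates["C_M_scale"] = self.C_M_scale * f
            else:
                updates[name] = getattr(self, name) * f
        return replace(self, **updates)

    @property
    def V_L(self) -> float:
        return self.V_T - self.V_G

    @property
    def alpha(self) -> float:
        return (self.V_T - self.V_G) / self.V_G

    @property
    def kinetics(self) -> MonodKinetics:
        return MonodKinetics(C_X=self.C_X, q_max=self.q_max, K=self.K)


@dataclass
class FitResult:
    """Outcome of one scalar diffusion-coefficient fit."""

    D_hat: float
    objective: float
    converged: bool
    method_id: int


class DegenerateProfileError(RuntimeError):
    """A gradient window produced an unusable (non-negative) slope."""


def _scalar_fit(objective, method_id: int) -> FitResult:
    res = minimize_scalar(
        lambda x: objective(10.0**x),
        bounds=LOG10_D_BOUNDS, method="bounded",
        options={"xatol": 1e-4},
    )
    return FitResult(
        D_hat=float(10.0 ** res.x), objective=float(res.fun),
        converged=bool(res.success), method_id=method_id,
    )


def _slope(z: np.ndarray, c: np.ndarray) -> float:
    """Ordinary least-squares slope of c against z."""
    z = z - z.mean()
    return float(z @ (c - c.mean()) / (z @ z))


def fit_diffusion(
    dataset: Dataset, assumed: AssumedParams, window: int = 4
) -> FitResult:
    """Estimate the granule diffusion coefficient with the dataset's method.

    ``window`` is the number of electrode points per gradient segment for
    the microelectrode methods (4 and 5).
    """
    m = dataset.method_id
    design = dataset.nominal_design
    t = dataset.abscissa
    y = dataset.values

    if m == 1:
        C0 = design.C0_bulk * assumed.C_B_scale
        beta = (3.0 * assumed.V_G / assumed.r_g) / assumed.V_L
        kin = assumed.kinetics

        def objective(D: float) -> float:
            model = quasi_steady_bulk_decline(t, D, assumed.r_g, beta, C0, kin)
            return float(np.sum((model - y) ** 2))

        return _scalar_fit(objective, 1)

    if m in (2, 3):
        mode = "uptake" if m == 2 else "release"
        C_init = (design.C0_bulk if m == 2 else design.C0_granule) * assumed.C_B_scale
        alpha = assumed.alpha

        def objective(D: float) -> float:
            model = finite_bath_bulk(t, D, assumed.r_g, alpha, mode, C_init)
            return float(np.sum((model - y) ** 2))

        return _scalar_fit(objective, m)

    if m == 4:
        scale = assumed.dx / design.electrode_step
        z = t * scale  # believed positions
        outside = np.nonzero(z < 0)[0]
        inside = np.nonzero(z > 0)[0]
        if outside.size < window or inside.size < window:
            raise DegenerateProfileError("too few points on one side of the interface")
        sel_out = outside[-window:]
        sel_in = inside[:window]
        slope_out = _slope(z[sel_out], y[sel_out])
        slope_in = _slope(z[sel_in], y[sel_in])
        if slope_out >= 0 or slope_in >= 0:
            raise DegenerateProfileError(
                f"non-decreasing gradient window (outside {slope_out:.3g}, "
                f"inside {slope_in:.3g})"
            )
        D_hat = assumed.D_aq * slope_out / slope_in
        return FitResult(D_hat=float(D_hat), objective=0.0, converged=True, method_id=4)

    if m == 5:
        # flux from the early bulk decline
        drop = design.bulk_slope_fraction
        keep = y >= y[0] * (1.0 - drop)
        if keep.sum() < 3:
            keep = np.arange(len(y)) < 3
        slope_bulk = _slope(t[keep], y[keep])
        if slope_bulk >= 0:
            raise DegenerateProfileError("bulk series is not declining")
        area = 3.0 * assumed.V_G / assumed.r_g
        J = assumed.V_L / area * (-slope_bulk)
        scale = assumed.dx / design.electrode_step
        z = dataset.profile_positions * scale
        c = dataset.profile_values
        inside = np.nonzero(z > 0)[0]
        if inside.size < window:
            raise DegenerateProfileError("too few interior profile points")
        sel = inside[:window]
        slope_in = _slope(z[sel], c[sel])
        if slope_in >= 0:
            raise DegenerateProfileError("non-decreasing interior profile")
        D_hat = J / (-slope_in)
        return FitResult(D_hat=float(D_hat), objective=0.0, converged=True, method_id=5)

    if m == 6:
        C_step = design.C0_bulk * assumed.C_B_scale
        rel = y / C_step

        def objective(D: float) -> float:
            model = center_step_response(t, D, assumed.r_g)
            return float(np.sum((model - rel) ** 2))

        return _scalar_fit(objective, 6)

    raise ValueError(f"unknown method_id {m}")
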