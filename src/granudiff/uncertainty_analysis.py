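"""Latin-hypercube Monte Carlo propagation and SRC sensitivity analysis.

The precision of each measurement method is quantified by simulating ONE
noise-free nominal dataset, then refitting it 1000 times with perturbed
analyst assumptions and perturbed concentration readings:

* parameter channels (granule/total volume, radius, kinetics, electrode
  step, assumed initial concentration) perturb the ``AssumedParams`` fed to
  the fitter;
* concentration channels perturb the recorded data points themselves, with
  fresh independent per-point multiplicative noise on every Monte Carlo row.

All channels are sampled jointly with Latin Hypercube Sampling: each column
is a stratified normal sample (exactly one draw per equal-probability bin,
independently permuted), so even the per-point noise factors are stratified.

Sensitivity is analysed with standardized regression coefficients (SRC):
ordinary least squares of the fitted diffusion coefficient on all inputs,
slopes scaled by sigma_x/sigma_y.  beta_i^2 partitions the output variance
when the regression is sufficiently linear (R^2 >= 0.7); the per-point
concentration betas are summed into one aggregate share per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from scipy.stats import skew

from granudiff.method_fitters import AssumedParams, fit_diffusion
from granudiff.model_system import (
    ExperimentDesign,
    GranuleSystem,
    UncertaintySpec,
)
from granudiff.virtual_experiments import Dataset, simulate_experiment

__all__ = [
    "ParameterDraws",
    "MCResult",
    "SensitivityResult",
    "lhs_sample",
    "run_monte_carlo",
    "src_sensitivity",
]

#: methods whose bulk time series is the measured record (C_B per-point noise)
_BULK_SERIES_METHODS = (1, 2, 3, 5)
#: methods with a microelectrode record (C_M per-point noise)
_ELECTRODE_METHODS = (4, 5, 6)
#: methods whose fit uses an assumed initial/step concentration (C_B scale)
_CB_SCALE_METHODS = (1, 2, 3, 6)


@dataclass
class ParameterDraws:
    """LHS sample matrix with its column names and provenance."""

    matrix: np.ndarray
    names: list[str]
    seed: int | None
    spec: UncertaintySpec | None = None

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class MCResult:
    """Monte Carlo precision result for one method.

    ``rsd`` and ``inherent_inaccuracy`` are percentages;
    ``inherent_inaccuracy`` is 100 (mean(D_hat) - D_true)/D_true.
    """

    D_hat: np.ndarray
    rsd: float
    inherent_inaccuracy: float
    skewness: float
    n_failed: int
    method_id: int
    draws: ParameterDraws | None = None

    @property
    def skewed(self) -> bool:
        return abs(self.skewness) > 0.5


@dataclass
class SensitivityResult:
    """Standardized-regression sensitivity decomposition."""

    beta: dict[str, float]
    beta2_share: dict[str, float]  # percent of sum(beta^2), aggregated
    r_squared: float
    linear: bool
    significant: dict[str, bool] = field(default_factory=dict)


def _stratified_normal(n: int, rng: np.random.Generator) -> np.ndarray:
    """One standard-normal draw per equal-probability bin, in random order."""
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    return ndtri(u)


def _lhs_factors(
    rsds: np.ndarray, n: int, rng: np.random.Generator, max_redraw_frac: float = 0.10
) -> np.ndarray:
    """Matrix of multiplicative factors 1 + rsd*z with LHS stratification.

    Draws that would make a physical (positive) quantity non-positive are
    re-drawn inside their own probability bin; a column needing more than
    ``max_redraw_frac`` of its draws re-drawn raises, since that means the
    normal model is badly truncated at that RSD.
    """
    from scipy.special import ndtr

    out = np.empty((n, rsds.size))
    for j, rsd in enumerate(rsds):
        perm = rng.permutation(n)
        u = (perm + rng.uniform(size=n)) / n
        vals = 1.0 + rsd * ndtri(u)
        bad = vals <= 0
        if bad.sum() > max_redraw_frac * n:
            raise ValueError(
                f"RSD {rsd:.2f} truncates more than {max_redraw_frac:.0%} of a "
                "column at zero; review the distribution choice"
            )
        if np.any(bad):
            # redraw inside the positive part of each bin; bins that lie
            # entirely below zero use the nearest positive probability sliver
            thr = float(ndtr(-1.0 / rsd))  # P(factor <= 0)
            lo = perm[bad] / n
            hi = (perm[bad] + 1.0) / n
            lo_eff = np.maximum(lo, thr)
            hi_eff = np.maximum(hi, thr + (hi - lo))
            u_new = lo_eff + rng.uniform(size=lo.size) * (hi_eff - lo_eff)
            vals[bad] = 1.0 + rsd * ndtri(np.clip(u_new, thr + 1e-15, 1 - 1e-15))
        out[:, j] = np.maximum(vals, 1e-12)
    return out


def lhs_sample(
    spec: UncertaintySpec,
    nominal: dict[str, float],
    n: int,
    seed: int | None = None,
) -> ParameterDraws:
    """Latin-hypercube sample of parameter values around their nominals.

    Per parameter: stratify [0,1] into ``n`` bins, draw one uniform in each,
    map through the normal inverse CDF with mean = nominal and
    sd = RSD * nominal, and permute columns independently.
    """
    if n < 2:
        raise ValueError("need at least 2 samples for LHS")
    names = [k for k in spec.rsd]
    rng = np.random.default_rng(seed)
    factors = _lhs_factors(np.array([spec.rsd[k] for k in names]), n, rng)
    values = factors * np.array([nominal[k] for k in names])[None, :]
    return ParameterDraws(matrix=values, names=names, seed=seed, spec=spec)


def _channel_layout(method_id: int, spec: UncertaintySpec, dataset: Dataset):
    """Column names and RSDs for the method's full Monte Carlo sample."""
    rsd = spec.rsd
    param_names: list[str] = []
    for p in ("V_G", "V_T", "r_g", "C_X", "K", "q_max", "dx"):
        if p in rsd:
            param_names.append(p)
    if "C_B" in rsd and method_id in _CB_SCALE_METHODS:
        param_names.append("C_B")
    point_blocks: list[tuple[str, int]] = []
    if method_id in _BULK_SERIES_METHODS and "C_B" in rsd:
        point_blocks.append(("C_B_points", dataset.values.size))
    if method_id in _ELECTRODE_METHODS and "C_M" in rsd:
        n_pts = (
            dataset.profile_values.size if method_id == 5 else dataset.values.size
        )
        point_blocks.append(("C_M_points", n_pts))
    names = list(param_names)
    rsds = [rsd[p] for p in param_names]
    for block, count in point_blocks:
        channel = "C_B" if block.startswith("C_B") else "C_M"
        names += [f"{block}[{i}]" for i in range(count)]
        rsds += [rsd[channel]] * count
    return param_names, point_blocks, names, np.array(rsds)


def run_monte_carlo(
    method_id: int,
    system: GranuleSystem,
    design: ExperimentDesign,
    spec: UncertaintySpec,
    n: int = 1000,
    seed: int | None = 42,
) -> MCResult:
    """Propagate the parameter uncertainty budget through one method.

    One noise-free nominal dataset is simulated; every LHS row perturbs the
    analyst's assumed parameters and (freshly, per row) the concentration
    readings, and the method's fitter is re-run.  Failed fits (degenerate
    profiles, non-convergence) are counted, not fatal, as long as they stay
    below 1% of the rows.
    """
    spec_m = spec.for_method(method_id)
    dataset = simulate_experiment(method_id, system, design, seed=seed)
    truth = AssumedParams.truth(system, design)
    param_names, point_blocks, names, rsds = _channel_layout(
        method_id, spec_m, dataset
    )
    rng = np.random.default_rng(seed)
    factors = _lhs_factors(rsds, n, rng)
    draws = ParameterDraws(matrix=factors, names=names, seed=seed, spec=spec_m)

    n_params = len(param_names)
    D_true = system.D_g
    D_hat = np.full(n, np.nan)
    n_failed = 0
    for i in range(n):
        fac = {p: factors[i, j] for j, p in enumerate(param_names)}
        assumed = truth.perturb(fac)
        data = dataset
        col = n_params
        values = dataset.values
        profile_values = dataset.profile_values
        for block, count in point_blocks:
            f = factors[i, col: col + count]
            if block == "C_B_points":
                values = np.maximum(values * f, 0.0)
            else:
                if method_id == 5:
                    profile_values = np.maximum(profile_values * f, 0.0)
                else:
                    values = np.maximum(values * f, 0.0)
            col += count
        if values is not dataset.values or profile_values is not dataset.profile_values:
            data = Dataset(
                method_id=dataset.method_id, kind=dataset.kind,
                abscissa=dataset.abscissa, values=values,
                nominal_design=dataset.nominal_design, seed=dataset.seed,
                profile_positions=dataset.profile_positions,
                profile_values=profile_values,
            )
        try:
            fit = fit_diffusion(data, assumed)
            if not fit.converged:
                raise RuntimeError("fit did not converge")
            D_hat[i] = fit.D_hat
        except Exception:
            n_failed += 1
    ok = np.isfinite(D_hat)
    if n_failed > 0.01 * n:
        raise RuntimeError(
            f"method {method_id}: {n_failed}/{n} Monte Carlo fits failed"
        )
    D_ok = D_hat[ok]
    spread = float(D_ok.std(ddof=1))
    return MCResult(
        D_hat=D_ok,
        rsd=float(100.0 * spread / D_ok.mean()),
        inherent_inaccuracy=float(100.0 * (D_ok.mean() - D_true) / D_true),
        skewness=float(skew(D_ok)) if spread > 1e-12 * D_ok.mean() else 0.0,
        n_failed=n_failed,
        method_id=method_id,
        draws=draws,
    )


def src_sensitivity(
    draws: ParameterDraws,
    outputs: np.ndarray,
    per_point_inputs: bool = True,
) -> SensitivityResult:
    """Standardized regression coefficients of the output on the inputs.

    beta_i = b_i sigma_{x_i} / sigma_y from one multivariate OLS fit; the
    per-point concentration channels (columns named like ``C_B_points[k]``)
    are aggregated by summing their beta^2 into a single share.  With
    ``per_point_inputs=False`` the point columns are dropped from the
    regression (needed when there are more points than samples).
    """
    X = draws.matrix
    names = list(draws.names)
    if not per_point_inputs:
        keep = [i for i, nm in enumerate(names) if "[" not in nm]
        X = X[:, keep]
        names = [names[i] for i in keep]
    y = np.asarray(outputs, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(
            f"need more samples ({n}) than inputs ({p}) for the SRC regression"
        )
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    live = sx > 0
    Xc = (X[:, live] - X[:, live].mean(axis=0)) / sx[live]
    yc = (y - y.mean()) / sy
    A = np.column_stack([np.ones(n), Xc])
    coef, *_ = np.linalg.lstsq(A, yc, rcond=None)
    resid = yc - A @ coef
    r2 = 1.0 - float(resid @ resid) / float(yc @ yc)
    beta_all = np.zeros(p)
    beta_all[live] = coef[1:]

    beta: dict[str, float] = {}
    beta2: dict[str, float] = {}
    for j, nm in enumerate(names):
        group = nm.split("[")[0] if "[" in nm else nm
        beta2[group] = beta2.get(group, 0.0) + beta_all[j] ** 2
        if "[" not in nm:
            beta[nm] = float(beta_all[j])
    total = sum(beta2.values())
    share = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in beta2.items()}
    significant = {k: v > 0.01 for k, v in beta2.items()}
    return SensitivityResult(
        beta=beta, beta2_share=share, r_squared=float(r2),
        linear=bool(r2 >= 0.7), significant=significant,
    )
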