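"""Physical model system, experiment protocols and uncertainty specification.

All quantities are strict SI internally: metres, seconds, g/m^3 (mass
concentrations), gCOD/m^3 (biomass).  The maximum specific uptake rate is
conventionally reported per day and is converted to per-second exactly once,
at construction.

The default model system is an oxygen-like solute diffusing into aerobic
granular sludge: granule radius 1.5 mm, effective granule diffusivity
1.2e-9 m^2/s, aqueous diffusivity 2.0e-9 m^2/s, with Monod uptake kinetics
(q_max = 3.54 gO2/gCOD/d, K = 0.2 g/m^3, C_X = 10 kgCOD/m^3) taken from the
standard biofilm benchmark parameterisation.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SECONDS_PER_DAY",
    "MonodKinetics",
    "GranuleSystem",
    "ExperimentDesign",
    "UncertaintySpec",
    "TABLE2_RSD",
    "METHOD_PARAMETERS",
    "make_system",
    "default_design",
    "sphericity_oblate",
    "sem_from_rsd",
    "load_config",
]

SECONDS_PER_DAY = 86400.0

#: Default relative standard deviations (as fractions) of the experimental
#: parameters entering the Monte Carlo precision analysis.
TABLE2_RSD: dict[str, float] = {
    "V_G": 0.05,   # granule volume
    "V_T": 0.01,   # total (liquid + granule) volume
    "r_g": 0.10,   # granule radius
    "C_B": 0.01,   # bulk concentration
    "C_X": 0.25,   # biomass concentration
    "K": 0.50,     # half-saturation coefficient
    "q_max": 0.05, # maximum uptake rate
    "C_M": 0.01,   # microelectrode concentration reading
    "dx": 0.10,    # microelectrode step size
}

#: Which uncertain parameters are inputs to which measurement method.
METHOD_PARAMETERS: dict[int, tuple[str, ...]] = {
    1: ("V_G", "V_T", "r_g", "C_B", "C_X", "K", "q_max"),
    2: ("V_G", "V_T", "r_g", "C_B"),
    3: ("V_G", "V_T", "r_g", "C_B"),
    4: ("C_M", "dx"),
    5: ("V_G", "V_T", "r_g", "C_B", "C_M", "dx"),
    6: ("r_g", "C_B", "C_M"),
}


class ValidationError(ValueError):
    """A physical parameter failed validation."""


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class MonodKinetics:
    """Monod uptake kinetics of the rate-limiting solute.

    Attributes
    ----------
    C_X : biomass concentration [gCOD/m^3]
    q_max : maximum specific uptake rate [gO2/gCOD/s] (per-second, SI)
    K : half-saturation coefficient [g/m^3]
    """

    C_X: float
    q_max: float
    K: float

    def __post_init__(self) -> None:
        for name in ("C_X", "q_max", "K"):
            _require_positive(name, getattr(self, name))

    @classmethod
    def from_per_day(cls, C_X: float, q_max_per_day: float, K: float) -> "MonodKinetics":
        """Build kinetics from a per-day maximum uptake rate (reporting unit)."""
        return cls(C_X=C_X, q_max=q_max_per_day / SECONDS_PER_DAY, K=K)

    @property
    def q_max_per_day(self) -> float:
        return self.q_max * SECONDS_PER_DAY

    @property
    def volumetric_rate_max(self) -> float:
        """Maximum volumetric uptake rate q_max * C_X [g/m^3/s]."""
        return self.q_max * self.C_X

    def rate(self, C: np.ndarray | float) -> np.ndarray | float:
        """Volumetric uptake rate q_max * C_X * C / (K + C) [g/m^3/s]."""
        C = np.asarray(C, dtype=float)
        return self.volumetric_rate_max * C / (self.K + C)


@dataclass(frozen=True)
class GranuleSystem:
    """The fixed physical truth: a granule and a solute.

    Attributes
    ----------
    r_g : granule radius [m]
    D_g : effective diffusion coefficient in the granule [m^2/s]
    D_aq : diffusion coefficient in the bulk liquid [m^2/s]
    kinetics : Monod uptake kinetics
    """

    r_g: float
    D_g: float
    D_aq: float
    kinetics: MonodKinetics

    def __post_init__(self) -> None:
        for name in ("r_g", "D_g", "D_aq"):
            _require_positive(name, getattr(self, name))
        if self.D_g > self.D_aq:
            raise ValidationError(
                f"D_g ({self.D_g}) must not exceed D_aq ({self.D_aq}): a biofilm "
                "matrix hinders diffusion relative to water"
            )

    @property
    def granule_volume(self) -> float:
        """Volume of a single granule [m^3]."""
        return 4.0 / 3.0 * math.pi * self.r_g**3


#: Field-for-field defaults of the model system (reporting units for q_max).
_SYSTEM_DEFAULTS = {
    "r_g": 1.5e-3,
    "D_g": 1.2e-9,
    "D_aq": 2.0e-9,
    "C_X": 10_000.0,
    "q_max": 3.54,  # gO2/gCOD/d; converted to per-second at construction
    "K": 0.2,
}


def make_system(overrides: dict[str, float] | None = None) -> GranuleSystem:
    """Construct the model system, optionally overriding individual fields.

    ``q_max`` is accepted in its reporting unit (per day) and converted to
    per-second exactly once, here.
    """
    values = dict(_SYSTEM_DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ValidationError(f"unknown system field(s): {sorted(unknown)}")
        values.update(overrides)
    for name, value in values.items():
        _require_positive(name, value)
    kinetics = MonodKinetics.from_per_day(
        C_X=values["C_X"], q_max_per_day=values["q_max"], K=values["K"]
    )
    return GranuleSystem(
        r_g=values["r_g"], D_g=values["D_g"], D_aq=values["D_aq"], kinetics=kinetics
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Per-method virtual experimental protocol.

    ``electrode_positions`` are signed distances from the granule surface
    [m]; negative values lie in the liquid outside the granule, positive
    values inside, increasing toward the centre.

    ``film_thickness`` is the stagnant-liquid boundary layer present in the
    microelectrode experiments (methods 4 and 5), through which the external
    concentration gradient develops.
    """

    method_id: int
    alpha: float
    C0_bulk: float
    C0_granule: float
    V_T: float
    V_G: float
    sample_times: np.ndarray = field(default_factory=lambda: np.array([]))
    electrode_positions: np.ndarray = field(default_factory=lambda: np.array([]))
    electrode_step: float = 0.0
    film_thickness: float = 0.0
    profile_time: float = 0.0
    bulk_slope_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.method_id not in range(1, 7):
            raise ValidationError(f"method_id must be 1..6, got {self.method_id}")
        for name in ("alpha", "V_T", "V_G"):
            _require_positive(name, getattr(self, name))
        if self.C0_bulk < 0 or self.C0_granule < 0:
            raise ValidationError("initial concentrations must be non-negative")
        alpha_implied = (self.V_T - self.V_G) / self.V_G
        if abs(alpha_implied - self.alpha) > 1e-9 * max(1.0, abs(self.alpha)):
            raise ValidationError(
                f"alpha={self.alpha} inconsistent with volumes "
                f"((V_T - V_G)/V_G = {alpha_implied})"
            )
        for name in ("sample_times", "electrode_positions"):
            grid = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, grid)
            if grid.size > 1 and not np.all(np.diff(grid) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if self.sample_times.size == 0 and self.electrode_positions.size == 0:
            raise ValidationError("design needs sample times or electrode positions")

    @property
    def V_L(self) -> float:
        """Liquid volume [m^3]."""
        return self.V_T - self.V_G

    def with_alpha(self, alpha: float) -> "ExperimentDesign":
        """Same protocol with a different liquid/granule volume ratio."""
        return replace(self, alpha=alpha, V_T=self.V_G * (1.0 + alpha))


def default_design(method_id: int, system: GranuleSystem | None = None) -> ExperimentDesign:
    """Literature-typical default protocol for each measurement method.

    * Method 1 (steady-state reaction): oxygen decline from air saturation
      (8 g/m^3) in a respirometric batch with liquid/granule ratio 10,
      sampled every 30 s for 20 min.
    * Methods 2/3 (transient uptake/release): alpha = 4, initial
      concentration 10 g/m^3 on the loaded side, bulk sampled every 60 s for
      1 h (roughly 20 finite-bath time constants).
    * Methods 4/5 (microelectrode steady-state): oxygen-sparged bath at
      40 g/m^3 to maximise the penetration depth, 50 um electrode steps
      spanning 400 um outside to 600 um inside the surface, with a 400 um
      stagnant boundary layer; method 5 additionally samples the bulk
      decline every 20 s for 10 min and takes its profile at 150 s.
    * Method 6 (centre step response): a single granule in a large stirred
      bath, centre concentration at 1 Hz for 1 h.
    """
    if system is None:
        system = make_system()
    v_granule = system.granule_volume

    if method_id == 1:
        alpha, V_G = 10.0, 1.0e-5
        return ExperimentDesign(
            method_id=1, alpha=alpha, C0_bulk=8.0, C0_granule=0.0,
            V_G=V_G, V_T=V_G * (1 + alpha),
            sample_times=np.arange(0.0, 1200.0 + 1e-9, 30.0),
        )
    if method_id in (2, 3):
        alpha, V_G = 4.0, 1.0e-5
        uptake = method_id == 2
        return ExperimentDesign(
            method_id=method_id, alpha=alpha,
            C0_bulk=10.0 if uptake else 0.0,
            C0_granule=0.0 if uptake else 10.0,
            V_G=V_G, V_T=V_G * (1 + alpha),
            sample_times=np.arange(0.0, 3600.0 + 1e-9, 60.0),
        )
    if method_id == 4:
        alpha, V_G, dx = 10.0, 1.0e-5, 50e-6
        return ExperimentDesign(
            method_id=4, alpha=alpha, C0_bulk=40.0, C0_granule=0.0,
            V_G=V_G, V_T=V_G * (1 + alpha),
            electrode_positions=np.arange(-400e-6, 600e-6 + 1e-12, dx),
            electrode_step=dx, film_thickness=400e-6,
        )
    if method_id == 5:
        alpha, V_G, dx = 10.0, 1.0e-5, 50e-6
        return ExperimentDesign(
            method_id=5, alpha=alpha, C0_bulk=40.0, C0_granule=0.0,
            V_G=V_G, V_T=V_G * (1 + alpha),
            sample_times=np.arange(0.0, 600.0 + 1e-9, 20.0),
            electrode_positions=np.arange(0.0, 600e-6 + 1e-12, dx),
            electrode_step=dx, film_thickness=400e-6, profile_time=150.0,
        )
    if method_id == 6:
        alpha = 1000.0
        V_G = v_granule
        return ExperimentDesign(
            method_id=6, alpha=alpha, C0_bulk=8.0, C0_granule=0.0,
            V_G=V_G, V_T=V_G * (1 + alpha),
            sample_times=np.arange(0.0, 3600.0 + 1e-9, 1.0),
        )
    raise ValidationError(f"method_id must be 1..6, got {method_id}")


@dataclass(frozen=True)
class UncertaintySpec:
    """Relative standard deviations of the uncertain experimental parameters.

    All parameters are modelled as independent normal variables centred on
    their nominal values; ``rsd`` maps parameter name to the fractional
    relative standard deviation.  The default map is the standard
    experimental-uncertainty budget (concentrations and total volume 1%,
    granule volume 5%, radius and electrode step 10%, biomass 25%,
    half-saturation 50%).
    """

    rsd: dict[str, float] = field(default_factory=lambda: dict(TABLE2_RSD))
    distribution: str = "normal"

    def __post_init__(self) -> None:
        unknown = set(self.rsd) - set(TABLE2_RSD)
        if unknown:
            raise ValidationError(f"unknown uncertain parameter(s): {sorted(unknown)}")
        for name, value in self.rsd.items():
            if not 0.0 <= value < 1.0:
                raise ValidationError(f"RSD for {name} must be in [0, 1), got {value}")
        if self.distribution != "normal":
            raise ValidationError("only the normal distribution family is supported")

    def subset(self, names: "list[str] | tuple[str, ...]") -> "UncertaintySpec":
        """Spec restricted to the given parameters (all others dropped)."""
        return UncertaintySpec(rsd={k: self.rsd[k] for k in names})

    def for_method(self, method_id: int) -> "UncertaintySpec":
        """Spec restricted to the parameters the method actually uses."""
        names = [p for p in METHOD_PARAMETERS[method_id] if p in self.rsd]
        return self.subset(names)


def sphericity_oblate(a: float, c: float) -> tuple[float, float]:
    """Sphericity and volume-equivalent radius of an oblate spheroid.

    Parameters are the semimajor (equatorial) axis ``a`` and semiminor
    (polar) axis ``c``, with a >= c > 0.  Sphericity is the surface area of
    the equal-volume sphere divided by the exact spheroid surface area

        S = 2 pi a^2 (1 + (1 - e^2)/e * atanh(e)),  e = sqrt(1 - c^2/a^2).
    """
    _require_positive("a", a)
    _require_positive("c", c)
    if a < c:
        raise ValidationError("prolate spheroids (a < c) are not supported")
    r_eq = (a * a * c) ** (1.0 / 3.0)
    if a == c:
        return 1.0, r_eq
    e = math.sqrt(1.0 - (c / a) ** 2)
    surface = 2.0 * math.pi * a * a * (1.0 + (1.0 - e * e) / e * math.atanh(e))
    sphere_surface = 4.0 * math.pi * r_eq * r_eq
    return sphere_surface / surface, r_eq


def sem_from_rsd(rsd: float, n: int) -> float:
    """Relative standard error of the mean of ``n`` replicates, in percent."""
    if n < 1:
        raise ValidationError(f"replicate count must be >= 1, got {n}")
    if rsd < 0:
        raise ValidationError(f"RSD must be non-negative, got {rsd}")
    return rsd / math.sqrt(n)


def load_config(path) -> tuple[GranuleSystem, dict[int, ExperimentDesign], UncertaintySpec]:
    """Load a TOML configuration with optional [system], [design.methodN] and
    [uncertainty] sections; anything omitted falls back to the defaults."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    system = make_system(cfg.get("system", {}))
    designs: dict[int, ExperimentDesign] = {}
    design_cfg = cfg.get("design", {})
    for m in range(1, 7):
        base = default_design(m, system)
        overrides = design_cfg.get(f"method{m}", {})
        if overrides:
            if "alpha" in overrides and "V_T" not in overrides:
                base = base.with_alpha(float(overrides.pop("alpha")))
            fields = {}
            for key, value in overrides.items():
                if key in ("sample_times", "electrode_positions"):
                    value = np.asarray(value, dtype=float)
                fields[key] = value
            base = replace(base, **fields)
        designs[m] = base
    unc = cfg.get("uncertainty", {})
    rsd = dict(TABLE2_RSD)
    rsd.update({k: float(v) for k, v in unc.items()})
    return system, designs, UncertaintySpec(rsd=rsd)
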