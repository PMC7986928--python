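# Methods

## The model system

All analyses run on one fixed "virtual truth": a spherical granular-sludge
granule of radius r_g = 1.5 mm with effective diffusivity
D_g = 1.2x10⁻⁹ m²/s for an oxygen-like solute, aqueous diffusivity
D_aq = 2.0x10⁻⁹ m²/s, and Monod uptake kinetics with biomass concentration
C_X = 10 000 gCOD/m³, maximum specific uptake rate q_max = 3.54 gO₂/gCOD/d
and half-saturation coefficient K = 0.2 g/m³ (the standard biofilm benchmark
parameterisation).  Internally everything is strict SI (m, s, g/m³); q_max
is converted from its per-day reporting unit exactly once, at construction
(`make_system`).  The invariant D_g ≤ D_aq is enforced: a biofilm matrix
cannot out-diffuse water.

With these values the Thiele modulus φ = r_g √(q_max C_X/(K D_g)) ≈ 62, so
an active granule is strongly diffusion-limited: oxygen penetrates only
δ ≈ √(2 D_g C_s/(q_max C_X)) ≈ 110–480 µm for surface concentrations between
2 and 40 g/m³.  Several design choices below follow from this single number.

## Forward models

**Finite-bath uptake/release** (methods 2/3). Spheres exchanging a
non-reactive solute with a well-stirred bath of finite volume, liquid/granule
volume ratio α, partition coefficient 1.  The fractional approach to
equilibrium is the classical eigenfunction series

    F(t) = 1 − Σₙ 6α(1+α) exp(−D q_n² t/r²) / (9 + 9α + q_n² α²),

with q_n the positive roots of tan q = 3q/(3 + α q²).  Roots are bracketed
in (nπ, nπ + π/2) using the pole-free form 3q cos q − (3+αq²) sin q and
polished to ~1e-15; the number of retained terms is chosen so the smallest
kept exponent is ≈ −36 at the earliest requested time.  Bulk concentration:
uptake C_b = C₀(1 − F/(1+α)), release C_b = C₀ F/(1+α).

**Centre step response** (method 6). C(0,t)/C_s = 1 + 2Σ(−1)ⁿ exp(−n²π²Fo)
with Fo = Dt/r².  For Fo ≤ 0.25 the Poisson-resummed dual form
(2/√(πFo)) Σ exp(−(n+½)²/Fo) is used, so both branches converge in a
handful of terms at any time; the branches agree to ~1e-12 at the crossover.

**Steady Monod diffusion–reaction** (methods 1/4/5 and the flux study).
D (r²C′)′/r² = q_max C_X C/(K+C) with a symmetric centre and C(r_g) = C_s,
nondimensionalised to (x²u′)′ = φ² x² u/(1+u).  Solved by damped Newton on a
conservative finite-difference scheme over 400 nodes, geometrically refined
toward the surface so the reaction layer (estimated from the slab first
integral u′(1) ≈ φ√(2(u_s − ln(1+u_s)))) is always resolved.  The initial
guess is parabolic when the centre stays wet, a quadratic (zero-order) layer
for u_s > 10 and an exponential (first-order) layer otherwise; steps are
limited to keep u > −0.9 (the Monod term is singular at u = −1).  The
surface gradient is recovered from the discrete global balance
u′(1) = φ² Σ V_i u_i/(1+u_i), which is exact for the conservative scheme.
The solver reproduces the three closed-form limits (zero-order shallow
penetration, reaction-limited, first-order) to 1–2%.

For Monte Carlo speed a dimensionless flux table ln g(ln φ, ln u_s) is built
once per process on a 56x64 grid spanning φ ∈ [0.5, 2x10⁴] and
u_s ∈ [10⁻⁴, 3x10⁴] and interpolated bilinearly (≲0.3% interpolation error;
below u_s = 10⁻⁴ the exact first-order closed form is used).  The
steady-state-reaction bulk decline dC_b/dt = −(A/V_L) J(C_b) is separable,
so the model curve is computed by one quadrature t(C) = (r/(βD))∫du/g(u)
rather than ODE integration, with the exact exponential first-order tail
appended below the resolved range.

## Transient finite-volume engines

One conservative formulation covers all geometries: cells with capacities
(volume x retardation) joined by face conductances, plus a single well-mixed
bath compartment.  The perfectly mixed reservoir is an ODE compartment
here, not a continuum with an artificially huge diffusivity —
the two agree to <10⁻⁴ relative (verified against a 10⁴-fold-faster
continuum shell), and the compartment is vastly better conditioned.
Crank–Nicolson marches a geometrically growing step schedule (first block
implicit Euler to damp the initial bath/granule discontinuity); total mass
capᵀc is conserved to round-off by construction and audited at every block
(residual < 10⁻³ is enforced, ~10⁻¹³ observed).  The 1-D spherical solver is
second-order in space (measured orders 2.0/1.9) and matches the Crank series
to <10⁻⁵ relative at 300 shells.

* **Boundary layer**: a stagnant shell of thickness L_f with D_aq between
  granule surface and bath; harmonic face conductances across the material
  interface.
* **Sorption**: instantaneous linear binding (bound = k x free) multiplies
  granule cell capacities by the retardation factor R = 1+k.  This maps the
  problem exactly onto the ideal solution with D → D/R and α → α/R
  (verified to <0.3%).
* **Size distribution**: one 1-D problem per granule (each remains
  spherically symmetric), all coupled to a shared bath through their summed
  surface fluxes.
* **Rough sphere**: 2-D axisymmetric spherical-polar grid (pole to equator,
  equatorial mirror symmetry) on r ≤ r₀ + A, with the granule boundary
  R(θ) = r₀ + A sin(2πwθ/(π/2)) — amplitude A = 50 µm and w = 10 full waves
  pole-to-equator by default, mean radius unchanged.  Cells straddling the
  interface carry exact radial volume fractions with series (harmonic)
  diffusivity along r and parallel (arithmetic) along θ; this sub-cell
  treatment makes the fitted-ratio change per mesh halving ≤0.03% (the
  plain staircase converged ~50x slower).  Valley liquid inside the maximum
  radius diffuses with D_aq (no convection) and is excluded from the bath
  volume.
* **Oblate spheroid**: boundary-fitted oblate-spheroidal coordinates
  (ρ = d cosh μ cos ν, z = d sinh μ sin ν, d = √(a²−c²)); the equal scale
  factors h_μ = h_ν cancel in the transmissibilities, leaving only
  h_φ = d cosh μ cos ν.  All z = 0 boundaries (focal disk and equatorial
  annulus) are no-flux by mirror symmetry.  Spheroids with |a−c| ≤ 10⁻¹² a
  dispatch to the 1-D sphere.

Meshed granule volumes are checked against the analytic volume of each
geometry (≤0.1% at default meshes, hard error at 0.5%).

## Virtual experiments and fitters

Each method's dataset is what an experimentalist would record.  The exact
sampling protocols are not published for the source study, so the defaults
are literature-typical and declared here (all configurable):

| method | protocol |
|---|---|
| 1 steady-state reaction | O₂ decline from 8 g/m³ (air saturation), α = 10, every 30 s for 20 min |
| 2/3 uptake/release | α = 4, 10 g/m³ initial on the loaded side, every 60 s for 1 h (~20 bath time constants) |
| 4 profile in/out | O₂-sparged bath at 40 g/m³, 400 µm stagnant film, 50 µm steps from 400 µm outside to 600 µm inside |
| 5 reaction + profile | same film/bath; bulk every 20 s for 10 min, interior profile at 150 s (the midpoint of the fitting window) |
| 6 centre response | single granule, large stirred bath (α = 1000), step to 8 g/m³, 1 Hz for 1 h |

The 40 g/m³ bath for methods 4/5 maximises the oxygen penetration depth
(≈480 µm) so the gradient windows are as well-conditioned as the physics
allows; the 400 µm film guarantees the outside window lies inside the
boundary layer.

Fitters: methods 1/2/3/6 minimise squared error over log₁₀D ∈ [−11, −8]
(bounded Brent, 10⁻⁴ tolerance in log₁₀D) against their forward model
evaluated at the analyst's *assumed* parameters; method 4 takes
D = D_aq x (outer slope)/(inner slope) from 4-point linear regressions
adjacent to the interface on each side; method 5 takes the flux from a
linear fit over the first 20% concentration drop of the bulk series and
divides by the 4-point interior slope.

Because the steady profile is curved on the scale of the penetration depth,
the 4-point linear windows (spanning 150 µm at 50 µm steps) systematically
underestimate the surface gradient.  In the slope *ratio* of method 4 the
inside and outside biases largely cancel (+2% net); in method 5 the flux is
measured independently, so the bias passes straight through (+42% at the
default design).  This is a property of the measurement procedure, not of
the implementation — no admissible oxygen experiment makes the window a
negligible fraction of the penetration depth — and it is what the Monte
Carlo reports as the large positive inherent inaccuracy of method 5.  A
curvature-free estimator could be substituted via the configurable window,
but the default deliberately models what practitioners actually compute.

## Monte Carlo precision analysis

One noise-free nominal dataset per method; 1000 Latin-hypercube rows
(stratified normal per column — exactly one draw per equal-probability bin,
independently permuted; draws that would be non-positive are redrawn inside
the positive-truncated part of their own bin, and a column needing more than
10% redraws is rejected).  Per row:

* parameter channels (V_G 5%, V_T 1%, r_g 10%, C_X 25%, K 50%, q_max 5%,
  dx 10%, each where the method uses them) perturb the analyst's assumed
  values;
* the bulk-concentration channel C_B (1%) acts twice for the mass-balance
  methods: as fresh independent per-point noise on the recorded series
  (measurement error) and as a scale error on the assumed initial
  concentration in the fitted model (the analyst knows the prepared
  concentration no better than 1%).  The scale component is what makes the
  uptake method so concentration-sensitive — its plateau mismatch is
  absorbed by sliding D with ~15-fold leverage — while the release method,
  whose signal is 100% of its plateau rather than 20%, is barely affected.
  Microelectrode readings (C_M, 1%) are per-point noise; the electrode-step
  error is a single systematic draw per profile, implemented equivalently as
  the analyst's assumed dx.

Outputs: RSD of the fitted D (precision), 100(mean−D_true)/D_true (inherent
inaccuracy), skewness (flagged above |0.5| — the steady-state-reaction
method is strongly right-skewed because D ∝ 1/C_X with C_X at 25% RSD),
and the failure count (must stay under 1%).  Sensitivity uses standardized
regression coefficients from a single OLS fit of D on all inputs
(β_i = b_i σ_xi/σ_y), per-point β² summed into one share per concentration
channel, with the R² ≥ 0.7 linearity gate and β² > 0.01 significance flag.
For method 6 the 3601 per-point columns exceed the sample count, so its
regression uses the parameter channels only (noted in the report).

Reference results at n = 1000 (default seed): RSDs 60/48/38/5/16/20% for
methods 1–6 — ordering 4 < 5 < 6 < 3 < 2 < 1 — and the radius-only runs
give 19.9% (methods 1/2/3/6) and 10.0% (method 5), the factor-two
amplification intrinsic to Fick's-2nd-law fitting.

## Systematic-error (accuracy) analysis

Each scenario forward-simulates the α = 4 transient-uptake experiment with
the corrupted physics/geometry and refits it naively with the ideal
smooth-sphere model at nominal parameters.  Typical parameterisations:
boundary layer 100 µm; roughness 50 µm/10 waves; oblate 1.80/1.04 mm
(sphericity 0.945, equal volume); size spread δ = 0.5 mm giving radii
{1.0, 1.5, 1.5, 2.0} mm.  Typical ratios D_obs/D_true at default meshes:
0.83, 0.92, 1.16, 0.76.

Sorption has no typical magnitude for an oxygen-like solute; its primary
result is the closed-form retardation ratio 1/(1+k).  Note that a naive fit
that *assumes* the nominal α does not return 1/(1+k): sorption also lowers
the bath equilibrium, and the plateau mismatch dominates the least-squares
fit.  The classical result applies to fits that take the equilibrium from
the data (standard uptake practice), which recover D/(1+k) within 2%.

Deactivation uses a Maxwell effective-medium model: the granule is a matrix
with cells at volume fraction φ whose relative diffusivity changes from
d_alive to d_dead upon permeabilisation; the measured ratio is
D_dead/D_alive.  Anchoring the living granule at D_g bounds the feasible
configurations (the implied matrix diffusivity may not exceed D_aq), which
caps the overestimation near D_aq/D_g ≈ 1.67 — the "up to ~60%" extreme.
The typical case (φ = 0.30, d_alive = 0.5, d_dead = 1 — oxygen partially
crosses living cell membranes) gives 1.20.

The headline combined error multiplies the *underestimating* simulated
errors (boundary layer x roughness x size spread = 0.58, a 42%
underestimation); the two overestimating errors (shape, deactivation) are
reported individually and in an all-five product (0.81).  Multiplying
opposing biases would suggest partial cancellation that no real experiment
can count on, since any subset of the errors may be present.

## Flux sensitivity

The steady Monod problem is solved at D_g and 1.1 D_g over surface
concentrations from 0.02 to 1000 g/m³ (penetration from ~115 µm to the full
radius).  The flux change is bounded by the square-root law
(√1.1 − 1 ≈ 4.9%) at shallow penetration and falls to zero at full
penetration — at most ~5–6% for a 10% change in D.  The same
weak dependence appears in both the asymptotic limits: first-order deep
penetration gives J ≈ C_s√(D k₁) and zero-order shallow penetration
J = √(2 D q_max C_X C_s), both ∝ √D.

## What the virtual experiments do and do not show

The generator produces idealised records: perfect electrode geometry apart
from the calibrated step error, no electrode response time or analyte
consumption, no stirring artifacts, no biological heterogeneity within or
between granules, and Gaussian multiplicative noise.  Passing tests
therefore demonstrate the *intrinsic* precision and bias of the data
processing chains under a known truth — real experiments can only be worse.
Conversely, absolute RSD values depend on the declared sampling protocols
(published protocols for the original study are not available), so the
robust conclusions are the structural ones: the factor-two amplification of
every input uncertainty in Fick's-2nd-law fits, the precision ordering of
the methods, the signs of the systematic errors, and the weak flux
sensitivity.

## Numerical choices and limitations

* Scalar fits are bounded to D ∈ [10⁻¹¹, 10⁻⁸] m²/s; objectives are
  unimodal over this bracket for all shipped designs (verified by grid
  scan).
* Default meshes: 300 shells (1-D), 220x320 (polar), 140x112 (oblate);
  scenario ratios change ≤0.03% per mesh halving.  The `--fast` pipeline
  flag and the test suite use coarser meshes (ratios shift ≲1%).
* Monte Carlo and scenario runs are fully seeded; identical
  seed + configuration reproduces every output bit-for-bit.
* No convection, no 3-D geometry, no moving boundaries, no multi-substrate
  kinetics, no pH/charge effects, no temperature corrections; transient
  simulations with active kinetics use BDF and are provided for
  completeness, not used by the headline analyses (method 1 is quasi-steady
  by construction, as in practice).
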