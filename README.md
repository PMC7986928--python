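# granudiff

Virtual diffusion-coefficient experiments in spherical biofilm granules.

Effective diffusion coefficients in biofilms and granular sludge are measured
with a handful of classical methods — mass-balance experiments (steady-state
reaction, transient uptake or release of a non-reactive solute) and
microelectrode experiments (steady concentration profiles, centre step
response).  Literature values for the same solute scatter widely, and part of
that scatter is the methods themselves.  `granudiff` quantifies this from
first principles, for researchers in biofilm/wastewater process engineering
and for anyone planning or interpreting such measurements:

* **Precision** — every method is run as a *virtual experiment* on a fully
  known model system (oxygen-like solute, granule radius r_g = 1.5 mm,
  granule diffusivity D_g = 1.2x10⁻⁹ m²/s, aqueous diffusivity
  D_aq = 2.0x10⁻⁹ m²/s, Monod kinetics q_max = 3.54 gO₂/gCOD/d,
  K = 0.2 g/m³, C_X = 10 kgCOD/m³).  A Latin-hypercube Monte Carlo analysis
  (n = 1000) perturbs the experimental inputs at their realistic relative
  standard deviations (granule volume 5%, total volume 1%, radius 10%,
  concentrations 1%, biomass 25%, half-saturation 50%, electrode step 10%)
  and refits D each time; the RSD of the fitted D is the method's precision
  and the offset of its mean is the inherent inaccuracy.  Standardized
  regression coefficients (β_i = b_i σ_xi/σ_y; β² shares with R² ≥ 0.7
  linearity check) attribute the variance to individual inputs.
* **Accuracy** — the transient-uptake experiment is forward-simulated with
  conservative finite-volume solvers under six systematic errors (solute
  sorption, biomass deactivation, a 100 µm mass-transfer boundary layer,
  50 µm sinusoidal surface roughness, oblate 1.80/1.04 mm shape, a ±0.5 mm
  granule size spread) and refitted naively with the ideal smooth-sphere
  Crank model; D_observed/D_true is the bias of each simplification.
* **Consequence** — a steady Monod diffusion-reaction study shows the flux
  into a granule changes by at most ~5–6% when D changes by 10%, i.e. the
  same weak sensitivity that frustrates the measurements also protects
  biofilm-model predictions.

The physics core: the finite-bath Crank series
C_b(t) = C₀(1 − F(t)/(1+α)) with
F(t) = 1 − Σₙ 6α(1+α) exp(−D q_n² t/r²)/(9+9α+q_n²α²),
tan q_n = 3q_n/(3+α q_n²); the centre step response
C(0,t)/C_s = 1 + 2Σ(−1)ⁿ exp(−n²π² Dt/r²) (θ-function dual form at small
Fourier number); the spherical Monod boundary-value problem
D (r²C′)′/r² = q_max C_X C/(K+C) solved by damped Newton on a
surface-refined conservative grid; and transient finite-volume solvers in
1-D spherical, 2-D polar (rough surfaces) and oblate-spheroidal coordinates,
all coupled to a well-mixed bath compartment with exact mass conservation.

## A worked example

```bash
python examples/04_radius_amplification.py
```

```
method 2 — transient uptake (Fick's 2nd law)
   RSD of fitted D: 19.95%   (input radius RSD: 10%)
method 6 — centre penetration (Fick's 2nd law)
   RSD of fitted D: 19.95%   (input radius RSD: 10%)
method 5 — reaction + internal profile (Fick's 1st law)
   RSD of fitted D: 10.03%   (input radius RSD: 10%)
```

A 10% uncertainty in the granule radius alone becomes a 20% uncertainty in
any diffusion coefficient fitted through Fick's 2nd law, because the fit
matches the diffusion time constant r²/D: the radius error enters squared.
Methods that evaluate Fick's 1st law directly (flux over gradient) pass the
error through linearly.  `examples/05_precision_table.py` runs the full
uncertainty budget (output below at n = 400); `examples/06_systematic_errors.py`
prints the systematic-error ratios (boundary layer 0.83, roughness 0.92,
shape 1.16, size spread 0.76, deactivation 1.20 — multiplying the
underestimating ones leaves an experiment reporting only ~58% of the true D).

```
                      method   RSD %  inaccuracy %   skew
1      steady-state reaction    56.9          15.8   4.40
2           transient uptake    47.1           6.0   0.91
3          transient release    40.2           4.2   1.88
4       micro profile in/out     5.3           2.1  -0.04
5         reaction + profile    15.0          41.0   0.36
6         centre penetration    20.0           1.0   0.33
```

The other examples cover the model system (`01`), the analytic solutions
(`02`), single-experiment fitting (`03`) and the flux-sensitivity study
(`07`).  The `granudiff` command runs the same analyses as a pipeline with
CSV/JSON outputs:

```bash
granudiff all --seed 42 --out study-output        # full study (~2 min)
granudiff precision --fast --out quick-look       # coarse quick look
```

All protocols (sampling schedules, volume ratios, uncertainty budget) are
configurable through a TOML file (`--config`); see
`granudiff.model_system.load_config`.

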