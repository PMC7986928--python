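"""Simulate a transient-uptake experiment and fit the diffusion coefficient.

A noise-free dataset round-trips to the true D exactly; with realistic 1%
bulk-concentration noise the single-experiment estimate already scatters,
and a 10% error in the assumed granule radius moves the estimate by 21%.
"""

from granudiff import (
    AssumedParams,
    UncertaintySpec,
    default_design,
    fit_diffusion,
    make_system,
    simulate_experiment,
)

system = make_system()
design = default_design(2, system)
truth = AssumedParams.truth(system, design)
D_TRUE = system.D_g

clean = simulate_experiment(2, system, design)
fit = fit_diffusion(clean, truth)
print(f"noise-free round trip : D_hat = {fit.D_hat:.4e} m^2/s "
      f"(truth {D_TRUE:.1e}, ratio {fit.D_hat/D_TRUE:.4f})")

for seed in (1, 2, 3):
    noisy = simulate_experiment(2, system, design, noise=UncertaintySpec(), seed=seed)
    f = fit_diffusion(noisy, truth)
    print(f"1% measurement noise  : D_hat = {f.D_hat:.4e} m^2/s "
          f"(ratio {f.D_hat/D_TRUE:.3f})  [seed {seed}]")

wrong_radius = fit_diffusion(clean, truth.perturb({"r_g": 1.10}))
print(f"radius assumed 10% big: D_hat = {wrong_radius.D_hat:.4e} m^2/s "
      f"(ratio {wrong_radius.D_hat/D_TRUE:.3f})")
print("-> the fitted D scales with the square of the assumed radius: every")
print("   uncertainty entering a Fick's-2nd-law fit is amplified by a factor ~2.")
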