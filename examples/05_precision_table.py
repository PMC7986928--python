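"""Full-budget Monte Carlo precision of all six measurement methods.

Propagates the complete experimental uncertainty budget (volumes, radius,
concentrations, kinetics, electrode step) through each method with Latin
hypercube sampling, printing the headline precision table.  n = 400 here
for a quick run; the reference analysis uses n = 1000.
"""

from granudiff import UncertaintySpec, default_design, make_system, run_monte_carlo

NAMES = {
    1: "steady-state reaction",
    2: "transient uptake",
    3: "transient release",
    4: "micro profile in/out",
    5: "reaction + profile",
    6: "centre penetration",
}

system = make_system()
spec = UncertaintySpec()

print(f"{'method':>28s}  {'RSD %':>6s}  {'inaccuracy %':>12s}  {'skew':>5s}")
rows = {}
for m in range(1, 7):
    res = run_monte_carlo(m, system, default_design(m, system), spec, n=400, seed=31 + m)
    rows[m] = res
    print(f"{m} {NAMES[m]:>26s}  {res.rsd:6.1f}  {res.inherent_inaccuracy:12.1f}"
          f"  {res.skewness:5.2f}")

order = sorted(rows, key=lambda m: rows[m].rsd)
print("\nmethods ordered by precision (best first):", order)
print("-> the microelectrode gradient methods are far more precise than the mass-")
print("   balance methods, but the gradient-window bias makes method 5 inaccurate;")
print("   the steady-state reaction method is both least precise and skewed.")
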