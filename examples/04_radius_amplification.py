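"""Radius-only Monte Carlo: the factor-two uncertainty amplification.

Only the granule radius is uncertain (10% RSD).  The Fick's-2nd-law methods
(transient uptake, centre response, ...) return a fitted D with ~20% RSD,
while the Fick's-1st-law method 5 passes the radius uncertainty through
linearly (~10% RSD).
"""

from granudiff import UncertaintySpec, default_design, make_system, run_monte_carlo

system = make_system()
spec = UncertaintySpec(rsd={"r_g": 0.10})
N = 500

for m, label in [(2, "transient uptake (Fick's 2nd law)"),
                 (6, "centre penetration (Fick's 2nd law)"),
                 (5, "reaction + internal profile (Fick's 1st law)")]:
    res = run_monte_carlo(m, system, default_design(m, system), spec, n=N, seed=17)
    print(f"method {m} — {label}")
    print(f"   RSD of fitted D: {res.rsd:5.2f}%   (input radius RSD: 10%)")

print("\n-> a 10% radius error rescales the diffusion time constant r^2/D, so the")
print("   transient fits double it to ~20%; the flux/gradient method sees only the")
print("   area-to-volume factor, which is linear in r.")
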