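"""Systematic errors: what a naive transient-uptake fit observes.

Forward-simulates the uptake experiment with each typical systematic error
(stagnant boundary layer, rough surface, spheroidal shape, granule size
spread, cell permeabilisation), fits it as if the granule were an ideal
smooth sphere, and prints D_observed/D_true.  Coarser meshes are used here
for speed; the reference analysis uses the default meshes.
"""

import numpy as np

from granudiff import default_design, make_system
from granudiff.error_scenarios import typical_scenarios

system = make_system()
design = default_design(2, system)
coarse = {"n_shells": 150, "n_r": 110, "n_theta": 160, "n_mu": 100, "n_nu": 80}

results = typical_scenarios(system, design, resolution=coarse)
for kind in ("mtbl", "roughness", "shape", "size_distribution", "deactivation"):
    r = results[kind]
    sign = "under" if r.ratio < 1 else "over"
    print(f"{kind:18s} D_obs/D_true = {r.ratio:.3f}  ({sign}estimates)")

under = np.prod([results[k].ratio for k in ("mtbl", "roughness", "size_distribution")])
print(f"\nproduct of the underestimating errors : {under:.3f} "
      f"({100*(1-under):.0f}% underestimation)")
print(f"product over all five typical errors  : {results['combined'].ratio:.3f}")
print("-> if the underestimating errors act together, a typical uptake experiment")
print("   reports barely 60% of the true diffusion coefficient.")
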