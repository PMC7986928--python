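"""Why imprecise diffusion coefficients barely matter for biofilm models.

Sweeps the surface concentration from reaction-limited (fully penetrated) to
deeply diffusion-limited and prints how much a +10% change in D changes the
steady substrate flux into the granule: never more than ~5-6%, approaching
the square-root law at shallow penetration and zero at full penetration.
"""

import numpy as np

from granudiff import flux_sensitivity_study, make_system

system = make_system()
table = flux_sensitivity_study(system, 0.10, np.geomspace(0.02, 1000.0, 13))

print(f"{'C_s [g/m^3]':>12s}  {'penetration [um]':>17s}  {'flux change [%]':>15s}")
for row in table.itertuples():
    print(f"{row.C_s:12.3f}  {row.penetration_depth*1e6:17.1f}  {row.pct_change:15.2f}")

print(f"\nmax flux change for +10% D: {table['pct_change'].max():.2f}%")
print("-> the same weak dependence that makes D hard to MEASURE with transient")
print("   methods makes biofilm-model predictions insensitive to its exact value.")
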