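"""Stability regions of the tumor-exponent coupling (model 2).

Scans the (g31, g32) plane at sigma = 0.05, classifying the Jacobian
spectrum at each grid point into nodes (all eigenvalues real negative),
spirals (complex pair with negative real part: damped oscillation),
center-like points (pure-imaginary pair: sustained cycle) and unstable
points.  The printed counts summarize the map; the reference coupling
(g31, g32) = (-0.10, 0) sits in the damped region.
"""

import numpy as np

from osteodyn import Variant, default_params, stability_region_scan

params, _ = default_params()
grid = np.linspace(-0.5, 0.48, 50)  # step 0.02 so 0.0 and -0.10 are on-grid
table = stability_region_scan(Variant.MODEL2, params, g31_grid=grid,
                              g32_grid=grid, sigma_grid=[0.05])

print(f"{len(table)} grid points at sigma=0.05:")
for cls, count in table.eig_class.value_counts().items():
    print(f"  {cls:14s} {count:5d}")

point = table[np.isclose(table.g31, -0.10) & np.isclose(table.g32, 0.0)]
row = point.iloc[0]
print(f"\n(g31, g32) = (-0.10, 0): {row.eig_class}, "
      f"Routh-Hurwitz stable = {bool(row.routh_hurwitz_stable)}")
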