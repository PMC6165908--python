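"""Build the three q-space sampling schemes and print their bookkeeping.

The Cartesian DSI grid (radius 5, b up to 6800 s/mm^2) carries 515
lattice samples of which 258 are antipodally unique; a 2.3-fold
compressed-sensing scheme measures 112 of the 257 unique DWIs; the
staggered 3-shell scheme places 30/40/50 directions at b = 1000/2000/3000.
"""

from csdsi import build_grid, generate_cs_scheme, generate_multishell_scheme
from csdsi.models import select_model_subset

grid = build_grid(radius=5, b_max=6800.0)
print(f"DSI grid: {grid.n_points} lattice points, "
      f"{len(grid.unique_points)} unique, "
      f"{len(grid.unique_nonzero_points)} unique DWIs")

cs = generate_cs_scheme(grid, accel=2.3, seed=0)
print(f"CS-DSI at 2.3x: {cs.n_measured} measured of {cs.n_dwis} DWIs "
      f"(+{cs.meta.n_b0} b=0)")

ms = generate_multishell_scheme([(1000, 30), (2000, 40), (3000, 50)], seed=0)
print(f"3-shell: {ms.n_dwis} DWIs (+{ms.meta.n_b0} b=0)")

for scheme, label in ((cs, "CS-DSI"), (ms, "3-shell")):
    dt = select_model_subset(scheme, "dt").n_dwis
    ku = select_model_subset(scheme, "kurtosis").n_dwis
    print(f"{label}: tensor model uses {dt} DWIs, kurtosis model {ku}")
# The counts are the sample budgets each diffusion model sees under the
# two protocols; the b-value rules decide which volumes qualify.
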