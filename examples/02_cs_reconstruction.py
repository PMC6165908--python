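"""Reconstruct a crossing-fiber voxel from 2.3x undersampled q-space data.

A two-tensor 90-degree crossing voxel is sampled on a CS-DSI scheme; ISTA
recovers the full 257-DWI set and the displacement propagator, whose
diffusion ODF exposes both fiber axes.  The printed NMSE compares the
recovery against simply leaving unmeasured samples at zero.
"""

import numpy as np

from csdsi import (Compartment, CSProblem, PhantomConfig, build_grid,
                   generate_cs_scheme, ista_reconstruct, nmse,
                   simulate_voxel_signal)
from csdsi.csrecon import (propagator_from_signal, signals_at_unique_points,
                           zero_filled_signals)
from csdsi.phantom import noise_free_attenuation
from csdsi.propagator import dodf, extract_peaks
from csdsi.qspace import ProtocolMeta

grid = build_grid(5, 6800.0)
meta = ProtocolMeta()
voxel = PhantomConfig(compartments=[
    Compartment(direction=(1, 0, 0), fraction=0.5),
    Compartment(direction=(0, 1, 0), fraction=0.5)])

scheme = generate_cs_scheme(grid, accel=2.3, seed=42)
signals = simulate_voxel_signal(voxel, scheme)
problem = CSProblem.from_signals(grid, scheme, signals)
result = ista_reconstruct(problem, meta=meta)

# ground truth E(q) on the full grid for scoring
pts = grid.points
bv = np.array([grid.b_of(p) for p in pts])
dirs = np.where(bv[:, None] > 0,
                pts / np.maximum(np.linalg.norm(pts, axis=1, keepdims=True),
                                 1e-12), 0.0)
E_true = np.zeros((11, 11, 11))
for p, e in zip(pts, noise_free_attenuation(voxel, bv, dirs)):
    E_true[p[0] + 5, p[1] + 5, p[2] + 5] = e
truth = signals_at_unique_points(E_true, grid)

print(f"measured {scheme.n_measured}/257 DWIs, "
      f"ISTA ran {result.n_iter} final-stage iterations")
print(f"reconstruction NMSE: {nmse(result.signals, truth):.2e}")
print(f"zero-filled   NMSE: {nmse(zero_filled_signals(problem), truth):.2e}")

prop = propagator_from_signal(result.E_grid, grid, meta=meta,
                              pad=3, window="hanning")
peaks = extract_peaks(dodf(prop))
print(f"dODF peaks: {len(peaks)}, crossing angle "
      f"{peaks.crossing_angle():.1f} degrees (truth: 90)")
# NMSE orders of magnitude below zero-filling and a ~90-degree crossing
# mean the undersampled acquisition still supports orientation mapping.
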