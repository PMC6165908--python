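# Methods

This note records the models, numerical choices and known limitations of
`csdsi`, in the order the pipeline uses them.

## Q-space model and grids

The toolkit treats diffusion-weighted MRI as sampling the 3-D Fourier
transform of the voxel-level displacement propagator: E(q) = ∫P(r)e^{2πi q·r}dr,
with antipodal symmetry E(q) = E(−q) for real P. DSI discretizes q-space
on an integer lattice truncated to a sphere of radius 5 (11×11×11 cube,
515 points). The b-value maps as b = b_max·|q|²/radius² with
b_max = 6 800 s/mm² at the boundary, so the lowest diffusion weighting on
the grid is 272 s/mm². Antipodal representatives keep the point whose
first nonzero coordinate is positive; grid enumeration is lexicographic in
(z, y, x) for stable file output.

Acquisition timing defaults are TE/TR = 101.4/5300 ms, Δ = 49.5 ms,
δ = 19.7 ms, giving an effective diffusion time τ = Δ − δ/3 ≈ 42.9 ms.
Physical q uses the q = γGδ/2π convention, so q_max = √(b_max/τ)/2π
≈ 63 mm⁻¹ and the displacement field of view is 1/Δq ≈ 79 µm. The
narrow-pulse approximation is marginal at δ = 19.7 ms; propagator metrics
are therefore available in both grid units and nominal mm.

### CS undersampling scheme

The published design this follows is specified only as "uniform angular,
random radial". Operationally: the 257 unique nonzero points group into
205 direction lines; a greedy farthest-point pass over the line sphere
picks ⌈257/accel⌉ lines for maximal angular uniformity, and the radial
position on each chosen line is drawn uniformly among its lattice points
from a seeded generator. At accel = 2.3 this measures 112 DWIs. The seed
is exposed so scheme-robustness studies are reproducible.

### Multi-shell scheme

Directions minimize an antipodally-symmetric Coulomb energy
Σ 1/|u_i−u_j| + 1/|u_i+u_j| with cross-shell pairs down-weighted by 0.5
(staggered design), by projected gradient descent with backtracking from a
seeded random start. This is a generalized electrostatic-repulsion
construction, not a bit-identical reproduction of any published table; the
energy decreases monotonically by construction and two directions on one
shell converge to orthogonal lines (verified against a brute-force energy
scan).

## Phantoms

Voxels are mixtures of Gaussian compartments:
E(g,b) = Σ f_i exp(−b gᵀD_i g). Fiber compartments default to
eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s and CSF-like compartments to
isotropic 3.0×10⁻³ mm²/s — standard healthy white-matter values chosen as
package defaults. Noise is Rician (magnitude MRI): both quadrature
channels receive N(0, σ²), with σ defined at S0 so SNR = S0/σ. Closed
forms for FA/MD/AD/RD of the Gaussian-average tensor and for the
directional mixture kurtosis 3·Var(D_g)/E[D_g]² serve as recovery oracles.
Test-retest replicates follow a one-way random-effects model with stated
between- and within-subject standard deviations; 5 subjects is the default
rescan subgroup size, tests use up to 200 when Monte-Carlo precision is
needed.

What the phantoms do **not** emulate: susceptibility/eddy-current
distortion, motion, spatially correlated noise, partial-volume geometry
beyond block regions, or exchange. Passing tests therefore demonstrate
correctness of the estimators, not robustness to scanner artifacts.

## CS reconstruction

The inverse problem is the LASSO
½‖R_Ω ℱp − y‖₂² + λ‖p‖₁ with ℱ the centered unitary DFT on the cube, R_Ω
the restriction to measured locations (each measured sample, its antipodal
mirror, and the origin; y is normalized to E(0) = 1 and symmetrized), and
λ = 5×10⁻⁶. A squared data term is used — it is the form whose gradient
step ISTA takes. The solver is plain ISTA: unit step (the masked unitary
DFT has Lipschitz constant 1), soft-threshold prox, real-part projection
each iterate (the symmetrized data make the minimizer real-symmetric).

Two numerical facts shaped the solver defaults:

- **Degeneracy at small λ.** For any non-negative data-consistent p, ‖p‖₁
  essentially equals the fixed DC value, so the λ = 5×10⁻⁶ objective is
  nearly flat over the feasible cone and bare ISTA drains ℓ1 mass only at
  ~λ per iteration — reaching a good reconstruction directly would take
  ~10⁶ iterations.
- **Continuation.** The default therefore runs the same ISTA through a
  warm-start λ schedule (1e−2 halving down to the target, 100 iterations
  per stage) before the final target-λ stage with the stopping rule
  (relative objective change < 1e−8 or 2 000 iterations). The logged
  objective trace is the final fixed-λ stage and is monotonically
  non-increasing. Continuation can be disabled to study the bare
  iteration; the independent-solver agreement test does so, comparing
  against a small-step matrix-coded proximal gradient started from the
  same zero-filled adjoint.

Non-negativity is not part of the objective; it is applied to the returned
propagator as a final projection (symmetrize, clip, renormalize), after
the reconstructed signals have been read off ℱp.

## Propagator metrics

The discrete propagator is obtained by zero-padding E(q) (default factor
3; finer displacement sampling, unchanged field of view) and inverse
transforming.

- **Moment metrics (MSD, RTOP)** use the *signed, un-windowed* transform:
  clipping truncation ringing before taking moments biases MSD severely
  (up to +94 % at d = 0.5×10⁻³ mm²/s, measured), whereas the signed
  estimator stays within 5 % of 6dτ and within 8.5 % of (4πdτ)^(−3/2)
  across d = 0.5–3×10⁻³ mm²/s. RTOP is P(0) divided by the
  displacement-voxel volume (equivalently Δq³ΣE(q)), reported with its
  cube root.
- **ODFs** use the non-negative projected propagator with a radial Hanning
  taper in q-space first — the classical DSI apodization; without it,
  truncation sidelobes create spurious dODF peaks that survive the
  0.1-fraction rule. The dODF is Φ(u) = ∫₀^{r_max} P(ru) r² dr with
  r_max = grid radius, radial step 0.5 grid units, and cubic-spline
  spatial interpolation: trilinear interpolation leaves ~2×10⁻³ cubic
  anisotropy in Φ for an isotropic voxel, cubic brings it below 10⁻³.

Peaks are local maxima over a subdivided-icosahedron tessellation (642
antipodally-paired vertices), greedily accepted by descending amplitude
subject to a 25° minimum line separation, then refined below the vertex
spacing by a baseline-subtracted amplitude-weighted principal-axis fit
over the vertex neighborhood (nearest-vertex error up to 4.4°, refined
error ≤ 1.8° over random orientations). A peak's "partial volume
fraction" is operationalized as its share of the summed extracted-peak
amplitude; the 0.1 detection threshold applies to that share.

## Model fitting

Both models use two-pass weighted linear least squares on the log signal
(weights = squared predicted signals). Internally b is scaled to ms/µm²
so all design columns are O(1); without this the constrained solver's
line search fails on the 10⁶-fold scale spread.

- **Tensor:** 6 unique elements + ln S0; negative eigenvalues are clamped
  to zero for metric computation and flagged. On the CS-DSI grid the fit
  uses lattice points with |q|² ≤ 5 (b ≤ ~1 360, 28 DWIs; the count, not
  a printed b-range, is treated as normative); on 3-shell data the
  b = 1000 shell (30 DWIs).
- **Kurtosis:** ln S = ln S0 − b·D(g) + (b²/6)·MD²·W(g) with the
  15-element fully-symmetric W. Apparent kurtosis is bounded to
  0 ≤ K(g) ≤ 3 and D(g) ≥ 0 on the fitted directions; the constrained
  refit (SLSQP, warm-started from the unconstrained solution) runs only
  when the unconstrained fit violates the bounds. K_max = 3 is a common
  robustness default; the constraint set of the original in-house
  implementation is not published. MK averages K(g) over 162 uniform
  directions (validated against a 40 000-direction brute-force average);
  AK/RK are taken along/perpendicular to the principal eigenvector.

## Shelling

Shell-based preprocessing requires near-shell b-values. Distinct nonzero
b-values are merged agglomeratively (closest adjacent pair first) as long
as no volume shifts more than `max_shift` (default 50 s/mm²) from its
cluster's count-weighted mean; a target shell count can be requested and
fails loudly with the blocking gap if unreachable under the bound.
Deterministic and idempotent by construction; assigned values are an
export view only — original b-values drive all model fitting. The exact
radius-5 grid yields 22 shells with zero shift (|q|² ≤ 25 excludes 7, 15,
23, the integers not expressible as three squares); a 20-shell relabeling
of scanner data implies scanner-rounded b-values, which the target-count
mode accommodates.

## Comparison statistics

- NMSE = ‖est − ref‖²/‖ref‖².
- Angular cross-correlation: normalized inner product of real
  even-order SH coefficient vectors with l = 0 excluded (otherwise two
  isotropic functions correlate trivially); by orthonormality this equals
  the functional correlation of the mean-removed functions.
- Peak comparison: minimum-total-angle assignment (Hungarian) on the
  line-angle matrix; crossing-angle deviation uses each set's two
  dominant peaks; the minimum prevalent crossing angle is the empirical
  lower quantile at the stated prevalence; the fiber count is the minimum
  over both sets of peaks above the fraction threshold, capped at 3.
- ICC(1,1) from the one-way ANOVA decomposition (cross-checked against
  pingouin); wsCV uses the Bland–Altman paired-difference form
  √(mean d²/2)/mean×100. The paired-difference rather than log form was
  chosen; for the small CVs involved the two agree closely.

## Problem sizes in the shipped checks

The test suite and the acceptance script use: 20 random schemes per
CS-recovery experiment (single-fiber and crossing voxels, noise-free),
radius-2 grids for solver-oracle agreement, 200 voxels for noise-bias
checks, and 50 replicates of 200 subjects for reliability recovery.
These sizes put Monte-Carlo error well below the asserted tolerances
while keeping a full run in the minutes range on one core.

## Known limitations

- The CS scheme and multi-shell optimizer reproduce design *principles*,
  not published gradient tables.
- MSD/RTOP here are discrete-propagator estimators; pipelines that derive
  these maps from continuous basis fits (e.g. MAP-type models) will not
  match numerically.
- The kurtosis constraint set and the reconstruction stopping rule are
  package choices where the source implementations are unpublished.
- At 2.3× undersampling a small fraction of random schemes yields
  crossing-peak errors above 5°; median behavior is ~2.5°.
- No artifact simulation (distortion, motion, gradient nonlinearity); see
  the phantom section.
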