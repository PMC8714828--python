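# Methods

## The model

The intravoxel incoherent motion (IVIM) model describes the normalized
diffusion-MRI signal of one voxel as a two-compartment bi-exponential,

    S(b)/S0 = f exp(-b D*) + (1 - f) exp(-b D),

with the perfusion fraction `f` (dimensionless), tissue diffusivity `D`
and pseudo-diffusion rate `D*` (both mm²/s, with `b` in s/mm² so that
`bD` is dimensionless). Two structural features make the fit hard:

* **Swap symmetry.** The model is invariant under
  `(f, D, D*) → (1−f, D*, D)`, so the least-squares surface is bimodal
  whenever both compartments are identifiable at all, and exactly
  degenerate on the axis `D = D*`, where `f` drops out of the model.
* **Flat valleys.** When `f` is small, the signal barely depends on
  `D*`; the objective has a near-flat valley of equally acceptable
  `D*` values, which is what makes conventional voxelwise `D*` maps
  noisy and unstable.

## Variable projection (Level 1)

For fixed rates `s = (D, D*)` the model is linear in the fractions,
which sum to one. Writing `φ₁ = exp(-bD*)`, `φ₂ = exp(-bD)`, the
constrained linear subproblem `y − φ₂ = (φ₁ − φ₂) f` is a scalar
least-squares problem solved in closed form and clipped to `[0, 1]`
(this enforces the sum-to-one constraint exactly; no pseudo-inverse
renormalization is needed). The reduced (VarPro) functional

    r(s) = min_f ‖y − φ(s) (f, 1−f)ᵀ‖²

is a function of the two rates only. Because the 1-D problem in `f` is
quadratic, the clipped closed form is its exact constrained minimizer
and `r(s)` coincides with a dense `f`-grid minimization of the full
residual (asserted to 1e−6 in the tests). On the axis `D = D*` the
projection is rank-deficient; `f = 0` is returned with a degeneracy
flag, since `f` is unidentifiable there.

## The simplicial-homology optimizer

The global step is a derivative-free optimizer that reads the objective
topology off a triangulated sample of the search box:

1. **Sampling.** A seeded scrambled Sobol sequence plus the `2ⁿ` box
   corners (corners guarantee that the convex hull of the sample covers
   the box). Sobol prefixes nest, so doubling the sample reuses the
   earlier points.
2. **Complex.** Delaunay triangulation of the sample (dimension ≤ 3
   here, so the cost is negligible); the objective is evaluated once
   per vertex, vectorized when the caller provides a batch evaluator.
3. **Minimizer pool.** Vertices whose value does not exceed any
   neighbor's. For a continuous objective each such vertex's *star*
   (the simplices containing it) bounds a locally convex sub-domain
   containing a stationary point; the axis-aligned bounding box of the
   star is handed to the local refiner as explicit bounds. Equal-valued
   candidate vertices (flat plateaus) form connected components and
   contribute one representative each (lowest index), so flat valleys
   do not flood the pool.
4. **Refinement.** Bounded Nelder–Mead descent (standard reflection /
   expansion / contraction / shrink coefficients, proposals clipped to
   the box), tolerance 1e−8 on the value spread and 1e−7 of the box
   width on the simplex diameter, at most 500 iterations. The refined
   value never exceeds the starting value.
5. **Polish.** With a finite sample, a tilted valley floor produces
   pool vertices whose star contains no true stationary point; their
   refinements stick to a star-box face. Any refined point that ends on
   a star-box face is therefore re-refined inside the full search box,
   which slides such artifacts to the true minimum of their basin.
   Points that converge strictly inside their star box are already
   local minima and skip this step.
6. **Deduplication and stopping.** Refined minima closer than 1e−3 of
   the box width per dimension merge (the smaller value wins). The
   sample is doubled until the deduplicated pool cardinality is
   unchanged across one doubling *and* the best value improved by less
   than 1e−10, with a hard cap of 4 rounds. The invariance of the pool
   under further sampling is what certifies that all basins have been
   seen; the plateau heuristic is our computable stand-in for the
   "adequately sampled" premise, which has no constructive criterion.

The optimizer is deterministic given (objective, bounds, n_points,
seed), and is cross-checked in the tests against dense-grid search and
against an independent reference implementation of the same algorithm
family (scipy's global optimizer) on analytic surfaces.

## TopoPro: the two-level fit

**Level 1** minimizes the reduced functional over the rate box
(`D ∈ [1e−5, 0.02]`, `D* ∈ [1e−5, 0.2]` mm²/s by default — deliberately
wide: a global optimizer needs a compact box, not a tight prior) and
projects `f` at the best rates. All deduplicated minima are retained;
there are typically two, one per symmetry valley.

**Level 2** takes the Level-1 candidate with the lowest penalized full
residual and minimizes the full 3-D functional plus penalty over a box
centered on it (half-width 0.5 of each global bound's width,
intersected with the global bounds, n = 32 sample points). The reported
residual never includes the penalty. If Level 2 fails to improve the
unpenalized misfit, the Level-1 solution is kept and flagged.

### The low-perfusion penalty

The penalty `λ D*²`, active when `f ≤ 0.2`, selects the physically
meaningful end of the flat `D*` valley in low-perfusion voxels. Three
implementation decisions matter:

* **Swap invariance.** The penalty is evaluated on the *physical*
  representative of the parameter point: the minority-perfusion form
  (`f ≤ 1/2`), with symmetry-axis points (rates within 5% of each
  other — closer than an IVIM acquisition can resolve, and flat to
  below refinement tolerance) mapped to `f = 0` (signal-preserving up
  to that unresolvable difference). Without this the
  optimizer evades the penalty through the mirror representation
  `f → 1−f` or through the axis, and pure-diffusion voxels come back
  with `f ≈ 1` or arbitrary `f`. Reported parameters use the same
  representative. It coincides with the `D* ≥ D` canonical form
  everywhere except at the degenerate boundary, where the penalty
  deliberately pins `D*` toward zero (below `D`).
* **Weight floor, λ = 0.001.** A constant weight strong enough to
  stabilize noisy valleys measurably biases weakly determined noiseless
  fits: direct minimization of the penalized functional shows a
  worst-case noiseless displacement of 42% at λ = 1, 2% at λ = 0.01 and
  0.22% at λ = 0.001 over the well-posed regime (f ≥ 0.05, D* ≤ 0.04,
  54-point scheme). The default floor is the largest power of ten that
  keeps this bias below the 0.5% recovery target; any positive weight
  still resolves exactly flat (noiseless degenerate) valleys.
* **Noise adaptivity, scale = 0.5.** A valley is only "flat" relative
  to the misfit the noise allows, so the effective weight grows with
  the voxel's Level-1 residual: it is chosen so that the penalty at the
  `D*` upper bound equals half that residual. Noiseless voxels
  therefore see only the floor (negligible bias), while at low SNR the
  penalty is commensurate with the band of statistically
  indistinguishable fits and pins the valley. This is our
  operationalization of applying the penalty "per detected sub-domain";
  a single fixed weight cannot serve both regimes.

**Volumes** are fitted voxel by voxel: normalize by the mean b=0 signal
(clipping negative excursions to zero, with flags), Level 1, Level 2.
Per-voxel seeds derive from the configured seed plus the flat voxel
index, so results are reproducible and independent of traversal order.
Diagnostics per voxel: number of Level-1 minima and a uint8 bitmask
(degenerate projection 1, clipped signal 2, non-positive S0 4, Level-2
non-improvement 8, non-convergence 16, empty voxel 32).

## Baseline fitters

* **Segmented:** log-linear regression of `log y` on `b` restricted to
  `b ≥ 200` s/mm² gives `D` (minus the slope) and `f = 1 − exp(intercept)`;
  then a 1-D bounded minimization over `D*` on all points with `f, D`
  fixed. Conventional narrow bounds `f ∈ [0, 0.9]`, `D ∈ [0, 0.004]`,
  `D* ∈ [0, 0.1]`. `f` is not refit in stage 2. Out-of-bounds values are
  clipped and flagged; no voxel discarding or neighbor interpolation,
  so per-voxel comparisons stay honest.
* **Bayesian:** random-walk Metropolis on `(f, D, D*)` with a flat
  prior equal to the indicator of those same bounds, initialized from
  the segmented fit, burn-in 1000 of 5000 samples, posterior mean
  reported. The Gaussian noise scale is profiled (σ² = SSR/m at the
  current point), which collapses the log-likelihood to `−m/2 log SSR`
  and keeps the chain three-dimensional. Proposal steps default to 2%
  of each bound's width; single chain, seeded. Sample count and
  proposal mechanism are our declared defaults, not literature values.
* **NLS:** bounded trust-region least squares from a given start — the
  conventional local solver, included to demonstrate the bimodal
  trapping failure mode.
* **SHGO:** the global optimizer applied directly to the full 3-D
  functional with neither VarPro reduction nor penalty — the ablation
  of the two-level design.

## The phantom

The classic ten-ellipse Shepp-Logan head geometry is rasterized at any
requested grid and binned into six tissue classes (rim → cavity, brain
interior → normal tissue, ventricles → CSF, large upper blob →
high-perfused tumor, mid-line blobs → infiltrating tumor, small bottom
blobs → low-perfused tumor). Default ground-truth triples
(f, D, D* in mm²/s): normal (0.10, 0.0008, 0.010), infiltrating tumor
(0.15, 0.0010, 0.015), low-perfused tumor (0.05, 0.0012, 0.008),
high-perfused tumor (0.30, 0.0012, 0.030), cavity and CSF (0, 0.0030, 0).
These are literature-plausible choices, fully configurable; everything
downstream reads the configured table, never these literals.

The default acquisition has 54 b-values: two b=0 (repeated b0
acquisitions are standard practice, and give each half of the
alternating test-retest split its own b0), nine perfusion-sensitive
values 10–90, and 43 values 100–1000 s/mm²; the proportions are kept
for other counts (27 → 2 + 4 + 21). S0 is 100 in tissue, 0 outside
(arbitrary scale; normalization removes it).

Noise emulates a multi-channel acquisition: each of 8 coils sees the
signal weighted by a smooth complex sensitivity map (Gaussian magnitude
profile around equally spaced angular positions, linear phase,
normalized to unit sum-of-squares), complex Gaussian noise of standard
deviation σ is added per channel, and channels are combined by
root-sum-of-squares. Background magnitudes are then chi-distributed
with 2·n_coils degrees of freedom (verified by a KS test). σ is set per
slice so that the mean noiseless normal-tissue b=0 signal divided by σ
equals the slice's nominal SNR, and is constant across b-values within
a slice.

**What the phantom does not emulate:** partial-volume mixing at class
boundaries, k-space/parallel-imaging correlations between coils, motion
and eddy-current artifacts, spatially varying tissue parameters within
a class, and T1/T2 relaxation contrast. Passing tests on this phantom
therefore demonstrate correctness of the estimators under the stated
noise model, not performance on real acquisitions.

**A consequence worth stating plainly:** root-sum-of-squares magnitude
data has a noise floor of about `sqrt(2·n_coils)·σ` — with 8 coils at
SNR 10, ≈ 40% of S0. At high b the floor mimics a very slow
compartment, which biases *every* fitter's `f` upward and compresses
the achievable accuracy advantage of any method on this phantom at low
SNR; the penalty cannot act on voxels whose apparent `f` is pushed
above its 0.2 threshold. See the benchmark notes in the README.

## Evaluation harness

Normalized RMSE = RMSE over the evaluation mask divided by the
ground-truth range over that mask (mean-normalization is available by
configuration; the choice is recorded in every report). The evaluation
mask is the tissue region; background behaviour is reported separately
as the mean absolute estimate over background voxels. Method-to-method
comparisons are ratios of these values. Test-retest splits the
b-values, sorted ascending, into alternating halves (even ranks / odd
ranks); a half without b=0 — only possible for single-b0 schemes — has
the b=0 measurement duplicated into it, flagged. Reliability is the
Pearson correlation of the two half-fits' parameter maps over the
tissue mask.

## Problem sizes

The shipped benchmark and tests run at desk scale: 64×64×1 voxels and
27 b-values for the noisy benchmark (≈2000 tissue voxels, ≈0.1 s per
voxel), 32×32×1 with 54 b-values for test-retest, with the full
256×256×5×54 protocol available through the same configuration objects.

## Known limitations

* The Level-2 box half-width (0.5 of each bound) and sample counts
  (64/32) trade thoroughness for per-voxel cost; pathological voxels
  could in principle hide a minimum outside the Level-2 box, though the
  Level-1 global pass makes this unlikely.
* The penalty threshold f ≤ 0.2 is a hard switch; estimates whose
  apparent f straddles it under noise alternate between penalized and
  unpenalized regimes across otherwise similar voxels.
* The Bayesian fitter's profiled-σ likelihood is extremely peaked on
  noiseless data, so chains started at an accurate init barely move;
  consistency checks there require small proposal steps.
* No noise-floor (Rician/chi bias) correction is applied before
  fitting; on multi-coil magnitude data at low SNR all fitters inherit
  the floor-induced bias described above.
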