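# Methods

## Problem setting and model

`modalign` addresses simultaneous multimodal single-cell assays: several
measurements per cell, each inducing its own notion of cell–cell similarity.
Every modality is reduced to a distance metric over a common sample `P` of
cell pairs.  The primary modality must decompose feature-wise — its squared
distance for a pair is a sum of `k` per-feature terms (squared differences for
numeric data, 0/1 mismatch indicators for symbolic data) — giving the
`|P| × k` matrix `D` with `D @ w` the transformed squared distances under
non-negative feature weights `w`.  Secondary modalities may use any of four
metrics (squared Euclidean, absolute difference, categorical mismatch,
Hamming), an optional elementwise monotone post-transform `f_j` (e.g. to
invert the direction of alignment), and a signed weight `γ_j`; a precomputed
per-pair distance vector is accepted as an escape hatch.

Alignment between metrics is measured by the Pearson correlation of pairwise
squared distances, with population (1/|P|) normalization throughout.  The
correlation itself is a quotient and not directly optimizable by quadratic
programming, so the fitted objective maximizes the covariance numerator while
penalizing the variance denominator and the departure from uniform weights:

```
maximize_w   Σ_j γ_j Cov(Dw, ρ_j) − α Var(Dw) − λ ‖w − 1‖²
subject to   Cov(Dw, ρ₁) ≥ β,   w ⪰ 0
```

Covariance is linear in `w` and variance quadratic:
`Cov(Dw, ρ_l) = ((1/|P|) a_l − (1/|P|²) b_l)ᵀ w` and
`Var(Dw) = wᵀ ((1/|P|) S − (1/|P|²) T) w`, with
`a_l = Σ_p ρ_l[p] D[p,:]`, `b_l = (Σ_p ρ_l[p]) (Σ_p D[p,:])`,
`S = Σ_p D[p,:] D[p,:]ᵀ`, and `T` the outer product of the column sums of
`D`.  `S` and `T` are `k × k`; `(1/|P|)S − (1/|P|²)T` is the population
covariance matrix of the columns of `D` and hence positive semidefinite (this
is asserted numerically in the test suite).  Everything downstream of the
single pass over the pair sample is `O(k)` or `O(k²)`, independent of the
number of cells.

An alternative regularizer `λ‖w‖²` (shrink toward zero rather than toward
uniform weights) is available via `regularizer="zero"`; the two give similar
results in practice and `‖w − 1‖²` is the default because it makes "no
information in the secondaries" map to "no change to the primary".

## User-facing constraints and the grid search

`λ`, `α`, `β` are nuisance parameters.  The interface exposes instead:

- `s ∈ [0, 1)` — minimum Pearson correlation between transformed and original
  primary distances.  This is the distortion budget and the main knob.
  Default 0.99; values ≥ 0.9 are recommended when a single value is used, and
  an ensemble over a wide range is recommended for feature selection.
- `q > 0` — bound `‖w‖_∞/‖w‖₁ ≤ q/k` on weight concentration.  Default 10³,
  deliberately loose so it almost never binds.

The engine solves the QP over a grid of `(λ, α, β)`, discards solutions
violating `s` or `q`, and among the survivors returns the one maximizing
`Σ_j γ_j Corr(Dw, ρ_j)` — correlation rather than covariance, because model
selection should be scale-free.  Ties keep the first grid point in iteration
order (λ outermost, β innermost).  The full feasibility table (one row per
grid point with both correlations and the objective) is attached to the
solution and written as TSV by the run layer.

### Grid normalization

Fixed numeric grids are meaningless across data scales: the covariance terms
scale as scale(D)·scale(ρ_j) while the variance term scales as scale(D)².
The default grids are therefore anchored to
`cov_unit = Σ_j |γ_j Cov(D·1, ρ_j)|`, the γ-weighted covariance magnitude at
uniform weights:

- `α ∈ {10⁻³, 10⁻², 10⁻¹, 1, 10} × cov_unit / Var(D·1)` — at the grid value 1
  the variance penalty equals the covariance term at `w = 1`;
- `λ ∈ {10⁻², 10⁻¹, 1, 10, 10², 10⁴, 10⁶} × cov_unit / k` — the regularizer is
  a dimensionless `O(k)` quantity.  The two largest values act as
  near-identity anchors: `w ≈ 1` satisfies any `s < 1`, so a tight distortion
  budget always has a grid point to fall back to and the search cannot fail
  on `s` alone;
- `β ∈ {0, 0.25, 0.5, 0.75, 1} × Var(D·1)` (recall
  `Cov(D·1, ρ₁) = Var(ρ₁)` at `w = 1`).

This anchoring was chosen after observing that a variance-scaled `α` (units of
scale(D)²) lets the variance penalty dominate by orders of magnitude whenever
the secondary distances are O(1) — e.g. binary label mismatches — which drives
the fit to shrink precisely the informative, high-variance features.  With the
covariance-anchored grids the default search is invariant to rescaling the
data or any secondary metric.

Users may pass explicit `lambda_grid` / `alpha_grid` / `beta_grid` values,
which are used raw.

## The QP solver

The problem is a strictly convex QP (for `λ > 0`) with nonnegativity bounds
and a single linear inequality.  It is solved exactly rather than iteratively
to tolerance:

1. The bound-constrained subproblem `min_{w⪰0} ½wᵀHw − cᵀw` is reduced via the
   Cholesky factor `H = RᵀR` to a nonnegative least squares problem
   `min_{w⪰0} ‖Rw − R⁻ᵀc‖²` and solved with the active-set NNLS algorithm.
2. If the covariance constraint is slack at that solution, it is optimal.
   Otherwise the constraint's multiplier `μ` is tracked parametrically:
   `g·w(μ)` is nondecreasing and piecewise linear in `μ`, so a doubling
   bracket plus a safeguarded secant/bisection finds `g·w(μ*) = β`, and a
   final KKT polish solves the equality-constrained system on the identified
   active set exactly (validated by multiplier signs and stationarity on the
   clamped coordinates; the polish is discarded if invalid).
3. The constraint is provably unattainable only when `g ⪯ 0` with `β > 0`
   (`g` being the primary covariance vector); that case is flagged infeasible
   rather than raised.

Solutions are clipped to `w ⪰ 0` exactly (entries in `(−tol, 0)` to zero).
Reported weights are additionally rescaled to mean 1 (`w_mean1`) for
comparability — Pearson correlations are invariant to this — with the raw
solver vector retained.  Against exhaustive grid optimization of the same
objective (10⁻³ resolution, adaptively extended domain), the solver agrees to
a few times 10⁻³ per coordinate, which is the grid's own resolution scale.

## Pair sampling

All distances are computed over a seeded uniform without-replacement sample of
unordered cell pairs; the default budget is `min(N(N−1)/2, 200,000)` pairs.
Sample correlations between distance vectors concentrate quickly, and at
N = 500 (≈ 125k possible pairs) correlations estimated from 20k sampled pairs
sit within 0.02 of the full-pair values across seeds (measured by the
acceptance script).  When the budget covers all pairs, the full lexicographic
list is used deterministically (seed-free).  Self-pairs are never sampled and
each unordered pair is used once.

## Preprocessing and score back-mapping

Expression-scale inputs are typically reduced before fitting: PCA (centered,
unscaled; deterministic full SVD), NMF (non-negative inputs; seeded NNDSVD-A
initialization), or truncated SVD (uncentered; works on sparse matrices,
seeded ARPACK).  The factor matrix becomes the primary modality; the retained
`d × G` loading matrix maps factor weights back to original variables via
softmax scoring: `score_g = Σ_i e^{w_i} loadings[i, g] / Σ_i e^{w_i}`,
parameter-free and dominated by the top-weighted factors.  The exponentiation
uses the mean-1 weight convention, making scores comparable across runs; cell
loadings can be scored identically by passing the observation-factor matrix.
No log transform or count normalization is applied implicitly — that is the
caller's decision, with a documented default of none.

Zero-variance primary features (dead components) are dropped with a warning
rather than an error, so reduced representations with degenerate factors still
run; feature names track identity through the drop.

## Ensembles and orientation

For feature selection, fits are repeated across an ensemble of `s` values
(default `{0.90, 0.925, 0.95, 0.975, 0.99}`); each sub-run's weight vector is
min-max normalized (lowest weight to 0, highest to 1 — invariant to the mean-1
rescale) and the normalized vectors are averaged.  Infeasible sub-runs are
dropped with a warning and recorded, never imputed; both the normalized mean
and the raw mean are reported.  For sequence analyses the natural reading is
inverted: a high weight marks a conserved position, so `1 − score` re-orients
the ranking to per-position variability tolerance.

## Domain builders

- **Spatial density**: a 2-D Gaussian KDE evaluated at each cell's own
  location, `density_i = (1/(M·2πh²)) Σ_j exp(−‖x_i − y_j‖²/(2h²))`, exact
  `O(NM)` evaluation.  The default bandwidth is Scott's rule for two
  dimensions, `h = M^{−1/6}·σ` with `σ` the root-mean coordinate variance
  (translation- and rotation-invariant).  The estimate may be fit on a labeled
  subset (e.g. one cell type) and evaluated on all cells.  Used with the
  absolute-difference metric: cells are similar when their neighborhoods are
  similarly dense.
- **CDR3 encoding**: sequences are truncated/padded to 20 residues with a
  dedicated null symbol distinct from all amino acids; null matches null
  (distance 0) and mismatches every residue.  Longer sequences truncate
  silently by default (a strict flag errors instead); non-standard residues
  error, or map to null under an explicit policy.  Per-position one-hot
  matrices (all-zero rows at null positions) support position-specific
  residue analyses, e.g. against a Boolean antigen-binding panel under the
  squared-Euclidean metric (which then counts discordant ligands).
- **Labels**: categorical mismatch on raw labels or on a binary is-target
  indicator; negative `γ` turns a label modality into a confounder penalty.

## Synthetic data

The generators produce the statistical structure the method assumes — a
secondary modality reflecting a feature subspace of the primary — not
realistic scRNA-seq counts (no negative binomial, no dropout):

- `make_planted_fixture(N, k, n_informative, noise_sd, seed)`: a latent
  `t ~ N(0,1)` per cell is copied into `n_informative` randomly chosen
  primary columns; remaining columns are independent standard normal.  The
  secondary is the scalar `t + ε`, `ε ~ N(0, noise_sd²)` (noise on the
  per-cell value, keeping metric axioms intact), under absolute difference
  with a squaring post-transform — at `noise_sd = 0` its pair distances are
  exactly proportional to the true-weighted primary squared distances
  (Pearson correlation 1).  Defaults used throughout the checks:
  N = 200, k = 20, 5 informative features, noise 0.1, `s = 0.90`.
- `make_categorical_fixture(N, k, n_types, seed, n_informative=4, shift=3)`:
  a Gaussian mixture where, on each informative feature, the types split into
  `±shift/2` groups (balanced sign design, so every informative feature
  separates types by `shift` and carries comparable signal); labels form the
  secondary.  `shift = 0` is a null fixture where weights should stay near 1.

Passing tests on these fixtures demonstrates recovery of a genuinely planted
low-dimensional cross-modal signal under the stated noise; they do not
demonstrate robustness to count overdispersion, batch structure, or dropout,
which real data adds on top.

## Numerical conventions and degenerate inputs

- Population normalization (1/|P|) for all covariances/variances.
- Feasibility slack: `s − 10⁻⁶` on the correlation, `q/k + 10⁻⁹` on
  concentration; PSD assertions at eigenvalue floor −10⁻⁸.
- Constant distance vectors (any modality) and all-zero `D` are rejected as
  degenerate — correlation is undefined there.
- `γ = 0` is rejected (the modality would be inert); negative `γ` is the
  supported way to penalize correlation.
- Indices are 0-based internally; external identifiers are preserved in
  feature names and row ids, and secondary tables are realigned to the
  primary's identifiers before fitting.
- Determinism: pair sampling, reductions, and fixtures all derive from the run
  seed; reruns of the same configuration are byte-identical, and the CLI and
  API share one code path so their outputs are too.

## Problem sizes in the checks

The bundled verification uses desk-scale problems chosen to exercise every
code path: QP-vs-exhaustive-grid comparisons at `k ≤ 3`, `|P| ≤ 50`
(10 instances); covariance/variance term checks on 100 random instances;
planted recovery over 50 seeds at N = 200, k = 20; pair-subsampling stability
at N = 500 over 20 seeds.  Grid resolution for the brute-force oracle is
10⁻³ per coordinate with a 5×10⁻³ agreement tolerance.

## Known limitations

- Only diagonal (scaling) transforms: general linear transforms would require
  semidefinite programming and are out of scope by design.
- The primary metric must decompose per feature (squared Euclidean or
  Hamming); arbitrary kernels are supported only on the secondary side.
- Feature weights are per-feature multipliers of squared differences: rankings
  are most interpretable when primary features are on comparable scales
  (as after PCA/SVD whitening-like reductions, or one-hot/positional
  encodings).  Heavily heteroscedastic raw features can make raw-weight
  rankings misleading.
- `Cov(Dw, ρ₁) ≥ β` controls the correlation constraint only indirectly; the
  grid search, not the solver, enforces `s`, so pathological grids supplied by
  the user can fail even when `w = 1` would satisfy `s` (the default grids
  cannot).
- The KDE density builder is exact `O(NM)`; for very large spatial datasets a
  tree-based evaluator would be preferable.
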