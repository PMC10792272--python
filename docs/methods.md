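# Methods

This note records the models implemented in covaritools, their assumptions,
the numerical choices that matter, and what the synthetic-data generators do
and do not emulate.

## Standardisation conventions

Every latent-space method here mixes an unsupervised term (feature
variance) with a supervised one (prediction quality), so both must live on
a comparable scale.  Two scalers are provided, both centering columns on
the fit data:

- `per_column`: each column to variance 1 (classic z-scoring; used for
  targets Y).
- `global`: one shared factor so the column variances *sum* to 1 (used for
  feature blocks, whose columns are components of one descriptor rather
  than unrelated covariates; per-column scaling would distort their
  internal geometry).

The variance denominator defaults to `ddof=0` so that a globally scaled
matrix satisfies `||X||_F² = n` exactly; this makes the "zero predictor
scores exactly 1" anchor of the reconstruction measures and the kernel
trace convention below exact rather than approximate.  Scaler statistics
are always taken from a fit (training) split and applied unchanged
elsewhere — the reconstruction protocol depends on this to avoid leakage.
Constant columns are a hard error in per-column mode and are tolerated in
global mode (they contribute zero variance).

Kernels are centered in feature space with the usual double-centering
identity and, inside the kernel estimators, rescaled so `trace(K_c)/n = 1`.
The trace convention mirrors "total variance 1" and makes the mixing
parameter comparable across kernels; for a linear kernel on a globally
scaled matrix the factor is exactly 1, which is what makes
`KernelPCovR(kernel="linear")` coincide with linear `PCovR`.

## Two-fold cross-validated ridge

The reconstruction measures need many small ridge fits with a tuned
regularizer.  `Ridge2FoldCV` splits rows into two halves, takes one thin
SVD per half (`X = U S Vᵀ`), and scores the whole regularizer grid by
rescaling singular values — `W(λ) = V diag(s/(s²+λ)) Uᵀ Y` — so no refit
per grid point is needed.  The validation metric is the relative squared
error `||Y_val − Ŷ||²_F / ||Y_val||²_F` averaged over the two directions;
the final weights are refit on all rows at the winning λ.

Choices: the default grid is 13 geometrically spaced values from 1e-10 to
1e2 (numerical noise to heavy shrinkage); ties break toward the smallest λ
(least bias); the default split is the deterministic even/odd interleave so
repeated runs agree exactly, with an optional seed for a shuffled split.  A
hard-cutoff variant (`method="cutoff"`: drop singular values with
`s² ≤ λ`, invert the rest) is available behind a flag but is not the
default.  Fits require n ≥ 4 and a non-degenerate Y (zero total variance is
rejected).

`OrthogonalRegression` solves `min_Q ||XQ − Y||_F` over orthogonal Q via
the SVD of `XᵀY` (the Procrustes solution, delegated to
`scipy.linalg.orthogonal_procrustes`).  Width mismatches are handled by
appending zero columns to the narrower matrix, never interleaving, so the
map is a square orthogonal matrix; inputs must be column-centered to 1e-8
because the orthogonal family contains no intercept.

## Feature reconstruction measures

All three measures share one protocol.  Rows are split into two outer folds
(deterministic interleave, or shuffled when a seed is given).  Per fold:
both feature sets are standardised with the *global* scaler fitted on the
training rows; the constrained map is fitted on the training rows; the fold
value is

    sqrt( Σ_test ||g_i − ĝ_i||² / Σ_test ||g_i||² ),

and the reported value is the root mean square of the two fold values.
Because G is centered and globally scaled on the training rows, the zero
map scores exactly 1 — "≈ 1" therefore genuinely means "no usable signal",
and values slightly above 1 indicate overfitting of the map, not a broken
normalization.  The scaler is configurable (any object with
`fit`/`transform`), as is the regression estimator for GFRE.

- **GFRE** fits `Ridge2FoldCV` (nested, on the training split only) from F
  to G.
- **GFRD** fits the orthogonal map instead, with no ridge penalty —
  orthogonal maps cannot overfit in the ridge sense and need no
  regularization.  With unequal widths the error is measured in the
  zero-padded space: predictions landing in padding columns count toward
  the numerator, while the denominator is unaffected by zero columns.
  Since orthogonal maps are a subset of linear maps, GFRD ≥ GFRE holds per
  fold up to the difference in regularization (the GFRE side carries a
  small CV-selected shrinkage).
- **LFRE** finds, for each test point, its `n_local_points` nearest
  training rows in the scaled F space, centers both F and G on the
  neighbourhood means, fits a `Ridge2FoldCV` there, and predicts
  `ĝ = ḡ_nbh + (f − f̄_nbh)·W` — an affine local map, which is what lets
  local reconstruction capture curvature that defeats any single global
  linear map.  `n_local_points` below p_F + 1 triggers a recorded warning
  (underdetermined local fits); a window as large as the training split
  degenerates to the global measure up to centering.

When per-sample contributions are requested, sample i of fold f contributes
`||g_i − ĝ_i||² / (2 · D_f)` with `D_f` the fold's total test norm, so the
reported value equals `sqrt(Σ pointwise)` exactly.

## Principal covariates regression and classification

`PCovR` eigendecomposes the modified Gram matrix
`G̃ = α XXᵀ + (1−α) ŶŶᵀ`, with Ŷ the predictions of a linear regressor
(default: intercept-free ridge with λ = 1e-8 — effectively least squares on
standardized inputs, recorded in the model).  The latent projection is
`T = U_m Λ_m^{1/2}` from the top-m eigenpairs, so `TᵀT = diag(Λ)`.  The
equivalent feature-space route eigendecomposes
`C̃ = α C + (1−α) C^{-1/2} XᵀŶ ŶᵀX C^{-1/2}` and is chosen automatically
when p < n (the smaller eigenproblem); the two routes share eigenvalues and
agree on T up to column signs whenever Ŷ lies in the column space of X,
which a linear regressor guarantees.

Numerical choices:

- Matrix square roots and inverses go through an eigendecomposition with a
  relative cutoff of 1e-12·λ_max; asking for more components than the
  attainable rank is an error naming that rank, never a silent truncation.
- Each latent column's sign is fixed so the largest-magnitude entry of its
  projector column is positive, making cross-route and cross-run
  comparisons deterministic.
- `P_TY` regresses the *true* Y (not Ŷ) onto T: the latent space exists to
  predict the actual targets.  At α = 0 this still reproduces the base
  regressor's predictions to within the λ-level algebra (the residual
  `Ŷᵀ(Y−Ŷ) = λ WᵀW` vanishes with the default λ).
- Inputs must arrive standardized (X centered, Y column-centered with no
  zero-variance column); the estimators check to 1e-8 and refuse otherwise
  rather than silently re-scaling — double standardisation would change the
  meaning of α.

`KernelPCovR` substitutes the centered, trace-normalized kernel for `XXᵀ`
and kernel ridge (default α_ridge = 1e-8 on the centered kernel) for the
regressor; out-of-sample projection centers cross-kernels with the training
statistics.  Kernels indefinite beyond −1e-10 (relative) after centering
are rejected.  α = 1 reproduces kernel PCA of the same centered kernel and
α = 0 kernel ridge regression.

`PCovC`/`KernelPCovC` replace Ŷ with the decision-function matrix Z of a
linear classifier (one column for binary problems, one per sorted class
label otherwise) — `ZZᵀ` acts as the class-likelihood proxy for `ŶŶᵀ`.
Four classifier families are built in (logistic, ridge classifier, linear
SVM, perceptron); the proxy classifier is fitted without an intercept so
`Z = X P_XZ` holds exactly (centered inputs make the intercept redundant),
which the eigendecomposition algebra requires.  Z enters `ZZᵀ` exactly as
the classifier returns it — families scale their decision values
differently, so the effective supervision strength at a given α depends on
the family; this is visible as genuinely different α = 0.5 maps across
families, while at α = 1 all coincide with PCA.  After the latent space is
built, a *fresh* classifier of the same family is refitted on (T, y) and
provides `predict` and `decision_function`.

`reconstruction_losses` reports `ℓX = ||X − X̂||²_F / ||X||²_F` and the
analogous `ℓY` — Frobenius-relative, hence unitless and comparable across
component counts and mixing values.

## Greedy selection

FPS keeps a per-candidate Hausdorff score (distance to the nearest selected
point) and repeatedly picks the argmax; ties break toward the smallest
index everywhere, a convention that also makes the Voronoi variant exactly
reproducible.  Selection starts from an explicit `initialize` list or a
seeded random point — there is no silent nondeterminism.  `score_threshold`
stops *before* making a pick whose score would fall below the threshold.
Initializer entries carry +inf in `selection_scores` (they were not chosen
by score) and serialize to JSON null.

The Voronoi variant maintains the owner (nearest center) of every
candidate; after adding center c*, only candidates owned by centers c with
`d(c, c*) < 2·radius(c)` can change owner, and all other cells are skipped.
The distances actually computed use the same formula as plain FPS, so
indices and scores are identical; a distance-evaluation counter exposes the
savings.

PCov-hybrids (`mixing < 1`) replace Euclidean distances with the metric
induced by the modified matrices — samples: `d²(i,j) = G̃_ii + G̃_jj −
2G̃_ij` with `G̃ = α XXᵀ + (1−α) ŶŶᵀ`; features: the same identity on the
modified covariance.  Ŷ is computed once up front from (X, Y) with a small
fixed ridge unless supplied directly.  `mixing = 1` reduces exactly to the
unsupervised algorithms.

CUR ranks candidates by the leverage score π — the squared projection onto
the top-k singular vectors of the *current* matrix (or the top-k
eigenvectors of the modified covariance/Gram matrix for the hybrid) — picks
the argmax, and then orthogonalizes the remaining candidates to the
selection: `X ← X − x_j (x_jᵀX)/(x_jᵀx_j)` for columns, analogously for
rows.  π is recomputed every `recompute_every` picks; in between the stale
scores are reused with selected entries masked.  For the feature-axis
hybrid the targets are deflated as `Y ← Y − x_j (x_jᵀx_j)^{-1} x_jᵀY`; on
the sample axis the orthogonalization acts purely on the feature
coordinates and induces no transformation of Y, so Y is left intact and Ŷ
is recomputed from the deflated matrix at each recomputation.  Candidates
whose residual norm falls below 1e-12 are degenerate (fully explained by
the selection); they are skipped and recorded rather than selected.
`score_threshold` for CUR compares π absolutely.

## Directional convex hull

The hull is built on 1–3 chosen columns of X plus the target as the
vertical axis: Qhull provides the omnidirectional convex hull, and facets
whose outward normal has a negative vertical component (relative tolerance
1e-12) are kept.  For one hull column this is exactly the classic lower
convex envelope; collinear interior points of a hull edge are not vertices
and are excluded.  Scoring locates the facet whose low-dimensional simplex
contains the query (barycentric coordinates with tolerance 1e-10 — a query
on a shared ridge is consistent because adjacent facets interpolate
identically there), interpolates the hull's target value, and returns the
signed difference — positive above, zero on, negative below the hull, so
out-of-sample points below the training hull are detectable.  Queries
outside the hull footprint are flagged with NaN and a warning instead of
being extrapolated.  `score_feature_matrix` interpolates the *unused*
feature columns across the containing facet's vertices and returns the
residuals; affine functions of the hull coordinates are reproduced exactly,
so those residuals isolate genuinely non-affine structure.

## Synthetic data

The generators plant the one structural property each method needs, with
independent streams derived from (seed, generator name) so results are
bit-reproducible and generators never perturb each other:

- `make_lowrank_regression`: `X = A·B` of exact rank r with a stored linear
  target map and optional Gaussian noise.
- `make_feature_pair`: pairs (F, G) related by a rotation (lossless and
  rigid), a shear (linear but not orthogonal), nesting (`G = [F·R | H]`
  with an independent block), or a curved 1-D manifold (`G = [t, 0.3t²]`).
- `make_labeled_blobs`: unit-variance Gaussian classes with means on a
  regular simplex scaled by `separation` (in within-class σ; 6 is
  practically separable, and labels are balanced to within one count).
  Coordinates beyond the class-mean plane carry no label information and
  are scaled by `nuisance_scale`; values above 1 emulate datasets whose
  dominant variance is unrelated to the labels — the regime in which
  unsupervised reduction discards class structure and supervised mixing
  pays off.  With isotropic noise (the default) PCA already recovers the
  class-mean plane and the supervised-vs-unsupervised comparison is
  uninformative by construction.
- `make_rings`: concentric annuli — linearly inseparable, trivially
  separable with an RBF kernel.
- `make_hull_cloud`: points on a strictly convex parabola (all of them
  lower-hull vertices, including both extremes) plus points strictly above,
  with the true vertex set stored.

What these fixtures do *not* emulate: correlated or heavy-tailed feature
noise, heteroscedastic targets, class imbalance, or the dimensionalities of
real descriptor sets (thousands of columns).  Passing tests demonstrate
algorithmic correctness — agreement with oracles and recovery of planted
structure — not performance claims about any particular real dataset.

## Problem sizes and verification

The test-suite and the acceptance script run on deliberately small
problems (n up to 1000, p up to a dozen, 10–100 random repetitions per
property) — large enough that the statistical anchors (e.g. GFRE ≈ 1 for
independent features) are stable, small enough that exhaustive oracles
(brute-force min-max scans, per-regularizer refits, monotone-chain
envelopes, random-orthogonal searches) remain feasible; everything
completes in seconds on one CPU.  The supervision-benefit comparison uses
3 classes, 300 samples, 5 features, separation 3 and nuisance scale 2, a
regime where the latent classifier and the PCA baseline differ markedly
(≈0.88 vs ≈0.40 holdout accuracy) and the sign of the comparison is stable
across seeds.

## Known limitations

- Dense matrices only; no sparse or out-of-core paths, no Nyström/sketched
  kernels.
- The PCovR regressor and the PCovC proxy classifier must be *linear* (the
  algebra needs `Ŷ = X·P_XY`); arbitrary nonlinear base models are not
  supported — that role belongs to the kernel variants.
- Hull construction supports 1–3 hull coordinates (Qhull degeneracies and
  the cost of barycentric search grow quickly beyond that).
- The supervised CUR/FPS hybrids compute Ŷ once up front rather than
  re-estimating the regression inside the selection loop.
- JSON serialization uses Python's shortest round-trip float representation
  (exact and deterministic); +inf scores become null.
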