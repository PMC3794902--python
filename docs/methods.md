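# Methods

## Model

Let p genes be observed through spatial expression patterns on a common
standardized embryo ellipse, discretized into m triangles of a fixed mesh.
The expression of the p genes at one spatial location (triangle) is modeled
as one draw from a multivariate Gaussian N(μ, Σ); the m triangles are
treated as i.i.d. samples from this distribution. Conditional independence
between two genes given all others corresponds exactly to a zero in the
precision matrix Θ = Σ⁻¹, so the gene-interaction network is the support of
Θ, and estimating the network is estimating a sparse Θ.

μ is absorbed by centering (the covariance kernel below centers each
summary vector), and Θ is estimated by minimizing the ℓ₁-penalized Gaussian
negative log-likelihood

    f(Θ) = tr(S Θ) − log det Θ + λ ‖Θ‖₁ ,

where S is the second-moment matrix about the mean (population convention,
1/m) or, for bags of images, the kernel matrix K described next. ‖Θ‖₁ is
the sum of absolute values over **all** entries, diagonal included; a
`penalize_diagonal=False` flag gives the common off-diagonal-only variant.
The problem is convex; the reported solution is the global optimum up to
tolerance.

### Bags of images and the statistic kernel

A gene is observed as a bag X_i of one or more per-image feature vectors.
Bags are compared by summarizing each bag with per-dimension order
statistics s(X_i) (mean, median, min, max, or a concatenation; with q
statistics the summary has length q·m) and applying the covariance base
kernel across the m spatial dimensions:

    K_ij = (1/m) Σ_l (s(X_i)_l − mean s(X_i)) (s(X_j)_l − mean s(X_j)).

With the mean statistic, K_ij equals the average of the base kernel over
all image pairs of the two bags (the normalized set kernel); this identity
is asserted to 1e−10 in the tests. K is PSD by construction up to
round-off; eigenvalues in [−1e−8·λ_max, 0) are clipped at zero before
estimation, and anything more negative is treated as an input error. The
default statistic is the single mean (robust when some images are noisy);
the median is exposed for over-stained corpora. Summary vectors are
centered per pair inside the base kernel rather than globally across
genes — for this base kernel the two conventions coincide.

### Solver

`fit_sparse_precision` implements the graphical-lasso block coordinate
descent: each column update solves an ℓ₁-penalized regression on the
current working covariance W by inner coordinate descent. Convergence is
declared when the maximum absolute change of W in a sweep falls below
tol = 1e−5·mean|S| (max 200 sweeps; non-convergence returns the best
iterate with `converged=False` and a warning). Θ is recovered from (W, B)
and symmetrized; determinism is exact for fixed inputs. Fits along a
penalty grid are warm-started from the next-larger λ (largest first);
tests check the warm-started path agrees with cold starts to 1e−4.

Two independent oracles guard the solver in the test suite: a proximal-
gradient (ISTA-type) minimizer of the same objective, and, for the
off-diagonal-penalty variant, scikit-learn's `graphical_lasso`.

Edges are off-diagonals with |Θ_ij| > zero_tol (default 1e−6 — below the
coordinate-descent tolerance such entries are numerically zero; exposed in
config).

### Penalty selection

The λ grid default is 21 values uniform on [0.5, 1], selecting the largest
λ whose network mean degree 2|E|/p lies in [2, 3] (falling back to the λ
closest to that band, approaching it from the appropriate side). Because
the per-image min-max normalization makes the kernel's overall magnitude a
property of pattern shape rather than of expression scale, the pipeline by
default interprets the grid **relative to the mean kernel diagonal**
(`scale_by_diagonal=True`): a grid value g means an effective penalty
g·mean(diag K). This keeps the canonical 0.5–1 grid meaningful across
feature scales; disable the flag to pass absolute penalties.

## Image featurization

The standardized embryo is a 2:1 ellipse (semi-major:semi-minor; embryo
proportions, configurable). The mesh is the Delaunay triangulation of a
hexagonal lattice clipped to the ellipse plus boundary points spaced
uniformly by arc length; the default element size 0.2155 (units of the
semi-minor axis) is calibrated once so the default mesh has exactly 311
near-equilateral triangles, and is kept as a checked constant. Mesh vertex
placement is therefore a package convention; only the triangle count and
the near-equilateral geometry are treated as fixed characteristics. The
summed triangle area reproduces the analytic ellipse area πab to within
0.4%.

Each raster frame spans the ellipse bounding box; a pixel center belongs to
the lowest-index triangle containing it (deterministic tie rule on shared
edges/vertices) or is "outside". A pattern's feature t is the median
intensity over the pixels of triangle t (even counts: mean of the two
middle values). Triangles left empty at coarse resolutions contribute 0 and
trigger a warning, preserving fixed dimensionality.

## Normalization and selection

Per image, features are min-max rescaled to [0, 255] (the 8-bit color
range) and transformed by log(1+e); log1p is used because raw log is
undefined at zero stain, and it maps 0 to 0. A constant (unstained or
fully saturated) image maps to all zeros — the behaviour when min = max is
otherwise unconstrained, and such images are removed next anyway.
Normalization follows triangulation, per image, matching the pipeline's
per-image processing order.

Images (rows) and triangle features (columns) with population variance
≤ τ (default 0.1, on log-intensity scale) are removed alternately —
starting with images — until every surviving row and column variance
exceeds τ. The procedure shrinks monotonically, terminates, and is
idempotent; on the crafted cascade instance in the tests the fixpoint is
unique across all removal orders. Genes whose images were all rejected are
dropped and logged; if nothing survives, the run aborts (no network can be
estimated).

## Synthetic data

### Dependent-sampling validation study

Real triangles are spatially correlated, violating the i.i.d. assumption.
The study quantifies the effect: rows of an n × p data matrix are drawn
from N(0, Σ) such that each row copies a fresh uniformly random subset of
⌊ρ·p⌋ coordinates from the previous row and draws the complement from the
exact conditional Gaussian (Schur complement). Every row is marginally
N(0, Σ) for any overlap ρ; ρ = 0 is i.i.d. and ρ = 1 repeats the first
row. Recovery (edge precision/recall of the graphical lasso vs. the known
support, empty-estimate precision convention 1.0, logged) is averaged over
replicates per ρ (default 50; the desk-scale acceptance test uses 10).

Defaults: p = 30, n = 300. The ground truth is the precision matrix of a
stationary AR(1) process with coupling φ = 0.6 (covariance φ^|i−j|, exactly
tridiagonal precision, well conditioned at every p). A constant-diagonal
tridiagonal chain is also provided (`ar1_precision`, diagonal 1,
off-diagonal 0.5), but at the default values it sits at the positive-
definiteness boundary for moderate p, which makes baseline recovery poor
regardless of penalty — a property of that matrix, not of the estimator —
so it is not used as the study default. The recovery penalty is tuned once
on i.i.d. pilot data by the same mean-degree heuristic used for real data
(λ whose average fitted mean degree over 5 pilot replicates is closest to
2.5), never by looking at the true edge set, and then held fixed across
the ρ sweep. In `grow_n` mode the sample count grows as
round(n/(1−ρ)) — an effective-sample-size heuristic — capped at 10n.

Expected behaviour (asserted in the acceptance tests): precision and
recall flat within 0.1 for ρ ≤ 0.5 at fixed n; a measurable drop at
ρ = 0.75; restoration to within 0.1 of the i.i.d. level under `grow_n`.

### Synthetic embryo corpus

`synth_embryo_dataset` draws an m × p expression matrix with i.i.d.
N(0, Σ) rows (one per mesh triangle), and renders 1–5 images per gene by
painting each triangle with the gene's value affinely mapped to [0, 255],
adding per-image Gaussian pixel noise (default sd 8 intensity units ≈ 3%
of the dynamic range), and quantizing to 8 bits. The default ground truth
(`planted_modules_precision`) partitions 40 genes into 8 modules of 5;
within a module the genes form a cycle with precision off-diagonal −0.45
and unit diagonal — diagonally dominant, hence well conditioned, with
every gene at degree exactly 2 (partial correlations ≈ 0.45, a strong but
realistic within-module coupling). Annotation terms mark the connected
components of the true network, giving planted enrichment structure.

What the generator emulates: registered single-embryo patterns on the
standard ellipse, uncalibrated intensities (the per-gene affine map is
arbitrary and removed again by normalization), bag-size imbalance, pixel
noise, and module-structured conditional dependence. What it does not
emulate: registration and stain-extraction failures, stage-label noise,
spatially localized (sparse) stain geometry, non-Gaussian marginals, and
spatial correlation between triangles (that mechanism is probed separately
by the dependence study). Passing end-to-end tests therefore demonstrates
the pipeline's correctness and its statistical behaviour under the model's
own assumptions, not performance on real corpora.

## Downstream analyses

- **Scale-free fit**: the degree CCDF P(k) (fraction of genes with ≥ k
  interactions) is evaluated at the distinct observed degrees and fit by
  least squares on log–log axes. Support points backed by fewer than 10
  genes are dropped by default: an empirical CCDF cannot fall below 1/p,
  so the extreme tail flattens artificially and biases the slope (when
  fewer than two points survive, all are kept, which preserves tiny-graph
  closed forms). An MLE fit is out of scope.
- **Spectral clustering**: symmetric-normalized Laplacian of the binary
  adjacency (|Θ| weights optional), k smallest eigenvectors, row
  normalization, k-means with fixed seed and 10 restarts (deterministic
  given the seed). Default k = 12.
- **Modularity proxy**: fraction of edges with both endpoints in the same
  cluster.
- **Enrichment**: upper-tail hypergeometric probability P(X ≥ k) per term
  with at least one annotated member; Bonferroni multiplier = number of
  terms tested in the same analysis (the natural family here); enriched
  means corrected p < 0.05.
- **Hubs**: all genes with degree ≥ the ceil(0.05·p)-th largest degree
  (ties at the threshold included, so the set can exceed 5%).
- **Neighbor regression**: per gene, OLS (with intercept) of its
  per-triangle expression on its network neighbors', after rescaling so
  the global maximum expression is 1; residuals are signed (true −
  predicted) and the mean absolute error summarizes fit quality. A gene
  with no neighbors is fit on the intercept alone. Residue maps paint the
  per-triangle mean residue with a ×10 display scaling (contrast only)
  on a diverging colormap.

## Numerical conventions and degenerate inputs

- Population (1/m) normalization throughout (variance filter, base
  kernel, second moment); a flag switches the kernel to 1/(m−1).
- Kernel eigenvalue clipping at zero only for round-off-scale negatives.
- Coordinate-descent tolerances as above; λ = 0 is rejected (the penalty
  also guarantees a well-posed objective for rank-deficient kernels).
- Ties: pixel-to-triangle assignment to the lowest triangle index; hub
  threshold ties all included; path selection prefers the largest
  qualifying λ.
- Degenerate inputs raise informative errors: empty manifests, empty bags,
  non-PD "precision" matrices, all-equal degree distributions (no slope),
  edgeless networks in ratio/CCDF computations, members outside the
  enrichment background.

## Problem sizes

Default test and validation sizes are chosen to exercise every code path
at desk scale: p = 30–40 genes, m = 311 triangles, n = 300 samples,
10-replicate dependence sweeps, p = 1000 configuration-model graphs for
the scale-free fit. The full-corpus analyses (thousands of genes) use the
same code paths; only λ grids and cluster counts are configuration.

## Known limitations

- The mesh matches the canonical triangle count, not any particular
  historical vertex placement; feature indices are therefore not
  comparable across tools, only within a run.
- Embryo registration and stain extraction are out of scope: inputs must
  already be standardized single-embryo patterns.
- The i.i.d.-triangles assumption is an approximation; the dependence
  study bounds its effect under the overlap-copy model only.
- Bonferroni correction is conservative when terms overlap heavily.
- The log1p(min-max) normalization discards absolute expression level by
  design; genes differing only in amplitude are indistinguishable.
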