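# Methods

## Model

`gtmphen` stratifies a cohort in two stages: a Generative Topographic
Mapping (GTM) produces a fine micro-segmentation of subjects, and Ward's
minimum-variance clustering of the GTM prototypes merges that segmentation
into a small number of macro-cluster phenotypes.

### Generative Topographic Mapping

GTM is a constrained Gaussian mixture. A regular `k × k` lattice of latent
nodes `u_l` spans `[-1, 1]²` with a uniform delta-function prior
`p(u) = (1/K) Σ_l δ(u − u_l)`, `K = k²`. A mapping
`y(u; W) = W φ(u)` lifts each node into data space, where it centres a
spherical Gaussian with precision `β` (we treat `β` throughout as the
*inverse variance* of the components, the standard convention). `φ` is a
Gaussian radial basis on an `m × m` lattice of centres over the same square
plus a constant bias column, so `W` is `D × (m² + 1)`. The data density is

    p(x | W, β) = (1/K) Σ_l N(x | y(u_l; W), β⁻¹ I)

and the fit maximises the log-likelihood of the observed rows penalised by
a weight-decay prior, `L(W, β) − (λ/2)‖W‖²_F`. Because the mixture is
parameterised through a smooth map of a 2-D lattice, nearby nodes have
nearby prototypes: the fitted model is simultaneously a clustering and an
interpretable 2-D projection.

Key assumptions: continuous variables on comparable scales (hence the
z-scoring step), spherical noise shared across components, and a data
manifold of roughly two intrinsic dimensions. Heavier-tailed noise or
higher intrinsic dimension degrade the map gracefully rather than
catastrophically; the synthetic generator's `heavy_tails` switch exists to
probe this qualitatively.

### EM

The E-step computes responsibilities
`r_nl ∝ exp(−β/2 ‖x_n − y_l‖²)` (rows normalised) and the log-likelihood
via log-sum-exp; a naive direct evaluation exists only in the test suite as
an oracle. The M-step solves the regularised weighted least-squares system

    (Φᵀ G Φ + (λ/β) I) W_newᵀ = Φᵀ Rᵀ X,   G = diag(Σ_n r_nl)

then re-estimates `β⁻¹` as the responsibility-weighted mean squared
residual over all `N·D` coordinates. Each double step cannot decrease the
penalised objective; the test suite asserts this to 1e-8 over many seeded
runs. `β⁻¹` is floored at 1e-8 so degenerate inputs (e.g. all points
identical) converge to the floor instead of diverging.

Initialisation follows the classical principal-component scheme: `W` is the
least-squares map of `Φ` onto the plane of the first two principal
components with lattice coordinates scaled by the PC score standard
deviations, and `β⁻¹` starts at the larger of the third eigenvalue and half
the mean squared distance between neighbouring initial prototypes. Rank-1
data make this degenerate and raise an error pointing at the seeded random
fallback (`W ~ 0.1·N(0,1)`, `β = 1`). Convergence: relative change in the
penalised objective below `tol` (default 1e-6), at most `max_iter` (default
200) EM updates; non-convergence is reported on the trace, never raised.

Node indexing is row-major from the top-left lattice corner, fixed so map
layers and serialised models are bit-comparable across runs. Figure
orientation is therefore a convention; a mirrored rendering of the same fit
is equally valid.

### Defaults

The default configuration — latent side 15 (225 nodes), 196 RBFs on a
14 × 14 grid, λ = 1 — is the configuration selected for the clinical
application this package operationalises, and 10-fold cross-validation is
the default for the tuner. The RBF width is the inter-centre spacing times
`width_factor` (default 1.0; no width was reported for the original
selection, so the standard spacing-equals-width choice is used). Smaller
grids in the documentation and tests (side 8, RBF side 7) keep the same
grid-to-basis ratio at desk scale.

### Model selection

`cv_score` shuffles subjects once with the seed, splits them into
near-equal contiguous folds, fits on each complement and evaluates the mean
per-subject negative log-likelihood on the held-out fold. All candidates in
a `grid_search` share the same partition (paired comparison). The published
selection criterion — strong held-out performance with minimal fold spread —
is operationalised as a one-standard-error rule: among candidates whose
mean NLL is within one standard error of the best mean, the smallest fold
standard deviation wins, with remaining ties broken toward fewer nodes,
then fewer RBFs, then stronger regularisation. A pure-mean mode
(`rule="mean"`) is available. The shipped default grid is illustrative; it
always contains the default configuration.

### Macro-clustering

Ward's method (Euclidean metric, via the standard Lance–Williams
agglomeration) clusters the `K` reference vectors in the standardized data
space — not the latent coordinates, and unweighted by node occupancy.
Merge heights are on the Euclidean-equivalent Ward scale (`√(2·ΔESS)`), so
dendrograms match other mainstream implementations height-for-height. The
test suite checks the merge sequence against an exhaustive O(K³) oracle
that recomputes every candidate merge's increase in within-cluster sum of
squares from scratch.

The number of phenotypes `k` is a user decision, as it was in the
motivating analyses (chosen by dendrogram inspection). `suggest_k` offers
the cut with the largest relative gap between successive merge heights
within a user range, falling back to the range minimum when heights are
flat; it is advisory and never applied silently. Cutting relabels clusters
contiguously by first leaf index; subjects inherit the phenotype of their
argmax node, and phenotypes that attract no subjects are reported, not
erased.

## Preprocessing

Pipeline order: validity/unit rules → missingness filters → log transform
of skewed variables → imputation → z-scoring.

- **Validity and units.** Cells outside a declared valid range become
  missing (e.g. negative heart rates); unit conversions multiply whole
  columns into the canonical unit.
- **Missingness filters.** Variables with missing fraction strictly above
  25 % are dropped first; then subjects strictly above 30 % over the
  surviving variables. Dropping sparse variables first avoids discarding
  subjects for missingness in doomed columns. Boundary cases are retained
  (strict inequality). Re-filtering an already-filtered table is a no-op in
  practice and is tested on seeded MCAR tables, though after subject removal
  a borderline variable's recomputed fraction can in principle cross the
  threshold.
- **Skew transform.** Continuous modelling variables with moment-based
  sample skewness above 1.0 get `log(1 + x)`, applied only when all
  observed values are nonnegative (the guard keeps the transform real and
  handles zeros). The transform is rank-preserving.
- **Imputation.** Chained-equation (MICE-style) round-robin regression via
  scikit-learn's `IterativeImputer` with a ridge estimator, 10 passes from
  column-mean initialisation, fixed seed. Only modelling variables are
  imputed; observed cells are never altered.
- **Standardisation.** Z-scoring (population sd) of continuous modelling
  variables, with stored parameters for the inverse transform. GTM's
  spherical-noise assumption makes comparable scales a practical necessity;
  the step is explicit and switchable (`scale=False`). Whether the log
  transform precedes imputation for every variable is a pipeline-order
  choice; the narrative order (transform, then impute) is implemented.

## Map layers

Maps are data first (a length-`K` vector aligned to node indexing plus
metadata); rendering is optional so everything tests headless. Membership
maps count argmax subjects per node; reference maps expose one coordinate
of every reference vector (standardized scale by default, original units
via the stored scaler); investigative maps average a withheld variable over
each node's members; probability maps are one subject's responsibility
distribution. Unoccupied nodes carry a missing marker, never zero — zero is
a valid data value. Rendering follows the grey→red convention for layers
derived from modelling variables and grey→teal for investigative overlays.
`second_best_neighbour_fraction` quantifies soft-assignment robustness: the
share of subjects whose runner-up node is a Chebyshev-1 lattice neighbour
of their argmax node.

## Characterisation

Continuous variables: median and IQR per phenotype (type-7 linear
interpolation quantiles, stated because quantile conventions differ across
software), compared by Kruskal–Wallis with midrank ties correction against
a chi-squared reference with `g − 1` df. Categorical (and one-hot encoded
ordinal) variables: counts and percentages, compared by Pearson chi-squared
without continuity correction. Raw two-sided p-values are flagged at 0.05
with no multiplicity adjustment, matching the procedure being
operationalised; Benjamini–Hochberg is available but off by default.

## Synthetic cohorts

The generator mirrors GTM's own generative assumption so likelihood-based
checks are well-posed: latent points from `n_clusters` unit-sd Gaussian
blobs whose adjacent centres sit `cluster_separation` apart (default 10,
i.e. a 10:1 separation-to-noise regime with the default `noise_sd = 1`),
lifted to `D` dimensions by a seeded low-order polynomial map (linear terms
dominate; mild quadratics bend the manifold) plus spherical noise. A
fraction of columns (default 0.2) is exponentiated to induce positive skew;
investigative columns carry planted-label mean shifts (default one
within-group sd per cluster step; the first is a binary categorical with
label-dependent prevalence). Missingness is injected completely at random,
with an optional fraction of columns elevated to 40 % to exercise the
filters. Single-cluster cohorts use a broader latent spread (sd 1.5) to
give a smooth cluster-free manifold.

Schema presets fix only column counts and names (67 = 40 genomic PCs + 27
assays for the biobank-like layout; 21 vitals/labs for the ICU-like
layout) for readability. The generator makes no attempt to reproduce the
real cohorts' marginal distributions, covariances, informative missingness
or measurement error — so passing recovery tests demonstrate correctness of
the machinery under the model's assumptions, not performance on real
clinical data.

## Problem sizes used in tests and the acceptance script

Planted-cluster recovery uses N = 600, D = 10, three blobs at 10:1
separation-to-noise, fitted at side 8 / RBF side 7 / λ = 1 (the default
configuration's shape at reduced scale), 10 seeds, success meaning adjusted
Rand index ≥ 0.9. EM-ascent checks use N = 200, D = 5 on a 6 × 6 grid with
16 RBFs across many seeds. Topology diagnostics use smooth single-manifold
cohorts (N = 500, D = 8, noise sd 0.5) fitted with a deliberately wide
basis (RBF side 4, width factor 3): smoothness is the regime in which the
neighbour property is meaningful, and a highly flexible basis would trade
it away for likelihood. Held-out NLL is reported from 5-fold CV at N = 300.

## Known limitations

- The latent space is fixed at two dimensions; no provision for `L ≠ 2`.
- Modelling variables must be continuous (ordinals enter via one-hot
  indicators); no native mixed-type likelihood.
- Ward clustering of reference vectors ignores node occupancy; a
  heavily-populated node counts the same as an empty interpolating one.
  This follows the published procedure, but boundary nodes between dense
  regions can attach to either side of a cut.
- The EM objective is non-convex; different seeds (or PCA vs random
  initialisation) can reach different local optima. All entry points are
  deterministic per seed.
- `suggest_k` is a height-gap heuristic and can be misled by chained
  merges; it is advisory only.
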