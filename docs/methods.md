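# Methods

## Setting

A UPLC total-plasma-N-glycome experiment quantifies each sample as 39 peak
areas expressed as percentages of the total integrated area, so each row of
the peak matrix is compositional (sums to 100). Case/control cohorts are
processed on multiple 96-well plates, which introduces location/scale
batch artifacts. The analysis chain implemented here is: batch correction →
median quotient normalization → rank transformation → derived traits →
univariate screening → correlation clustering → supervised multi-block
integration (sGCCA/DIABLO) → relevance networks.

## Synthetic glycome generator

Because cohort peak tables are rarely deposited, the package ships a
generator that reproduces the statistical structure the chain assumes, and
every behavioural guarantee in the test suite is stated with respect to it.

Latent log-abundances are Gaussian with a block-diagonal correlation
structure (default four blocks of sizes 16/16/4/3 with within-block
correlation 0.5 and log-scale SD 0.4 — a plausible rendering of the four
correlation clusters seen in plasma glycomes). Case samples receive an
additive shift (default 0.8) on a configurable subset of peaks (default
GP26, GP30, GP31, GP32, GP34, GP36 — tri/tetraantennary peaks of the kind
reported to separate T2DM from controls). Plates add a location shift and
inflate dispersion on the latent scale; the location shift is modulated
across peaks by a fixed mean-zero cosine pattern because a peak-constant
shift would cancel exactly under row renormalization. Finally the latent
values are exponentiated and each row renormalized to 100 (logistic-normal
composition). A Dirichlet model was rejected because it cannot encode
arbitrary positive inter-peak correlations.

Default cohort sizes are 219 controls / 232 cases with four plates,
round-robin assigned within each group so every plate contains both groups
(a stratified plate design).

What the generator does *not* emulate: chromatographic drift within a
plate, peak-integration error, missing values, covariate-linked effects
(age/sex trends), or realistic clinical covariates. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance on any particular cohort.

## Batch correction

Parametric empirical-Bayes location/scale adjustment. Each feature is
standardized by its grand mean and pooled residual variance from a linear
model containing plate indicators and, by default, the group label
(`preserve_group=True`), so balanced biological signal is not absorbed into
plate estimates. Per-plate location (γ̂) and scale (δ̂²) estimates are
shrunk toward plate-level priors — normal for locations, inverse-gamma for
scales, hyperparameters fitted by method of moments across features — by
iterating the two conditional posterior means to a 1e-6 fixed point, then
the data are back-transformed. With a single plate the operation is the
identity (γ\*=0, δ²\*=1).

Two properties of genuine EB shrinkage are worth stating because they are
often idealized away. First, the correction is *not* exactly idempotent:
shrinkage deliberately leaves a fraction of the raw between-plate mean
difference (roughly half the sampling noise of a plate mean when true plate
effects are homogeneous across features), so a second application still
finds a small nonzero estimate. The tests assert contraction — the second
pass changes the data by far less than the first — rather than strict
fixpointness. Second, the shrunk estimates approach the raw per-plate
standardization only when plate effects genuinely vary across features;
with homogeneous effects the moment-matched priors are tight and strong
shrinkage toward the common effect is the *correct* behaviour.

## Median quotient normalization

The reference spectrum is the feature-wise median across samples (an
explicit reference sample can be supplied). Each sample's dilution factor
is the median over features of value/reference, and the sample is divided
by its factor. Requires strictly positive data; by construction, the
post-normalization median quotient against the original reference is 1.

## Rank transformation

Three modes: raw average ranks (ties averaged), ranks standardized to zero
mean and unit variance per feature (the default used by the pipeline), and
Blom inverse-normal scores Φ⁻¹((rank − 3/8)/(n + 1/4)). The standardized
and inverse-normal modes reject constant features. Rank transforms are
invariant to any strictly monotone per-feature transformation.

The pipeline derives traits from the quotient-normalized (positive,
pre-rank) scale, since trait formulas involve sums and ratios of
abundances; ranks feed the screening and integration stages.

## Derived traits

Traits are declarative data — `trait_id,family,formula` rows parsed into a
restricted expression grammar (sums, differences, scalar multiples, one
ratio of linear forms; `TOTAL` denotes the panel sum) — because structural
assignments differ between laboratories. The shipped default is a
convention-based 21-trait table over six families built from a standard
peak-to-structure assignment (GP1–2 monoantennary, GP3–20 biantennary,
GP21–25/27–33 triantennary, GP26/34–39 tetraantennary, with galactosylation
and sialylation grades and core/antennary fucose flags). It is explicitly a
convention: any study with its own supplementary trait table should pass it
via `--traits-file`. Note that families deliberately overlap structurally
(G3 and TRIA summarise the same peaks; HB = TRIA + TETRA), so perfect
family separation by clustering derived traits is not achievable even in
principle.

## Univariate screening

Chi-square tests of independence are Pearson's statistic without continuity
correction (the convention under which published demographic tables
reproduce). Student's t defaults to the pooled-variance variant; Welch is
available. Mann–Whitney U uses the min-U convention, exact enumeration for
small tie-free samples (min group size < 8) and the tie- and
continuity-corrected normal approximation otherwise. The KS normality check
estimates mean/SD from the data and flags its p-value as approximate.
BH adjustment is the step-up rule q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j applied within
explicit test families (demographic tests, peak tests and trait tests are
separate families). Cluster summaries count K members and k raw-p
significant members per correlation cluster at level α.

## Clustering

Feature signatures are Spearman correlation matrices converted to
dissimilarity d = 1 − r and clustered with the Ward criterion
(Lance–Williams updates via standard linkage); partitions come from cutting
the tree at an explicit k (default 4 for peaks, 6 for traits; cut-by-count
chosen because it is reproducible without a height convention). The CIM
applies independent row and column Ward clusterings and reorders the matrix
by both leaf orders.

## sGCCA core

Blocks are centred and scaled to unit column variance; covariance uses the
1/(N−1) convention. For each dimension, block-coordinate ascent cycles the
blocks: the gradient direction z⁽ʲ⁾ = X⁽ʲ⁾ᵀ Σ_{h≠j} c_jh X⁽ʰ⁾ a⁽ʰ⁾ is
projected to the constraint set and normalized, until the largest loading
change drops below `tol` (default 1e-6, `max_iter` 100; non-convergence is
recorded in the diagnostics and the model still returned).

Sparsity is parameterized primarily by keepX (nonzero-loading count per
block, matching how shrinkage is operationally described for this model
family and the convention of reporting "top 10 of 39 peaks per component").
For the cardinality constraint the exact subproblem maximizer is hard
selection of the keepX largest-magnitude entries of z followed by L2
renormalization; because each update is the exact argmax of a linear
functional over the constraint set containing the previous iterate, the
objective is provably non-decreasing across iterations — the package
asserts this trace property in its tests. The popular alternative
(soft-thresholding at the (keepX+1)-th magnitude) changes the implicit L1
radius every iteration and measurably violates monotone ascent, so it is
not used for keepX; exact soft-thresholding *is* used for the explicit
L1-bound mode (`l1_bounds`, λ ≥ 1), where the bisection-found threshold
yields the exact maximizer.

Initialization is the leading right singular vector of each (deflated)
block, projected onto the constraint set so the recorded ascent starts from
a feasible point; random restarts are available because the problem is
non-convex. After each dimension the blocks are deflated by regressing out
their own component score, X_{d+1}⁽ʲ⁾ = X_d⁽ʲ⁾ − s_d⁽ʲ⁾ c_d⁽ʲ⁾ᵀ with
c_d⁽ʲ⁾ = X_d⁽ʲ⁾ᵀ s_d⁽ʲ⁾/(s_d⁽ʲ⁾ᵀ s_d⁽ʲ⁾); the regression vectors are stored
so held-out samples can replay the deflation. Loadings are sign-fixed so the
largest-magnitude entry is positive.

With two blocks, full design and no sparsity, the dimension-1 solution
coincides with the leading singular vectors of X⁽¹⁾ᵀX⁽²⁾; this closed form
and an exhaustive grid search on 2-variable blocks serve as oracles in the
tests. Near-degenerate singular gaps converge slowly (power-iteration
behaviour), which is why the oracle tests run with a much tighter `tol`.

## Supervised wrapper

The outcome enters as a centred/scaled dummy-indicator block. The default
design matrix connects data blocks to the outcome with weight 1 and to each
other with weight 0.1: with fully connected data blocks the first component
can lock onto the dominant inter-block covariance (e.g. peaks↔derived
traits, which share variables by construction) and ignore the class signal;
the weak data–data connection keeps components discriminative while still
integrating blocks. A full design remains the default for the unsupervised
`fit_sgcca`.

Prediction computes held-out component scores per data block (training
centring/scaling, stored deflation) and assigns the class of the nearest
training class centroid (Euclidean `centroid-dist` by default; `max-dist`
and `mahalanobis-dist` offered). The ensemble call is a vote weighted by
each block's mean absolute correlation between its training components and
the outcome components. The continuous score used for AUC is the
block-weighted difference of centroid distances (first class minus second),
and AUC itself is the tie-corrected rank statistic. Train/test splits are
stratified (default 80/20); cross-validation is stratified K-fold (default
K=5) with optional repeats and an optional keepX grid minimizing mean
balanced error (ties toward sparser models). K=5 was chosen as the common
default where only "K-fold" is specified.

## Relevance networks

The similarity between variable p of block i and variable q of block h is
sim(p,q) = Σ_d cor(x_p, z_d)·cor(x_q, z_d) with z_d the average of the two
blocks' dimension-d component scores — the standard latent-component
relevance-network construction; one component is used by default. Edges
with |sim| ≥ threshold (default 0.5, an interpretability convention) form a
signed bipartite graph; hubs are reported by degree with eigenvector
centrality as a tiebreaker. Circos-style edges are plain Spearman
correlations among selected variables with within/between-block flags and
per-variable higher-mean class annotations.

## Problem sizes used in validation

The shipped validation suite and `scripts/acceptance.py` use: 50 random
instances for each sGCCA oracle (grid at 0.1°, N=6, P=2+2; SVD closed form
at N=20, P=4+3); 20 seeds at n=100/100 and effect 0.8 for planted-peak
recovery; 20 seeds at n=50/50 for classifier calibration (permuted labels
and effect 2.0); 20 seeds at 300 samples/plate for batch-correction
guarantees; 100 random 8-point instances for the Ward oracle; 10 seeds of a
6-family/21-variable factor model for CIM recovery; and 20 seeds for hub
recovery. These sizes give stable pass/fail behaviour for the stated
thresholds while keeping the whole validation run in minutes on one core.

## Known limitations

* Missing values are rejected, not imputed.
* Only the covariance (Horst-type) sGCCA scheme is implemented.
* The trait table is convention-based; laboratory-specific supplementary
  tables should override it.
* EB batch correction assumes ≥2 samples per plate per feature and
  nonzero feature variance.
* Multiclass outcomes beyond two groups are accepted by the outcome block
  but AUC and several reports are binary-only.
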