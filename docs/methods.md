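# Methods

This note documents the models, conventions and numerical choices behind
`cognet`, and what the synthetic-data tests do and do not establish.

## Connectome model

A subject's structural connectome is a symmetric, nonnegative 90×90 matrix
over a cortical + subcortical parcellation. Edge values are mean tract
fractional anisotropy (FA) multiplied by the tract's streamline count, so
large tracts dominate and absent connections are exactly zero. When edge FA
is extracted from volumes, a connection's value is the arithmetic mean of FA
over voxels where the binary tract mask and the FA skeleton (FA > 0)
overlap; empty overlap yields zero. Voxel arrays are compared index-wise —
spatial registration is out of scope.

**Control-referenced thresholding.** For each edge, the mean `μ_ij` and
population-denominator SD `σ_ij` (switchable via `ddof`) are computed over
the healthy-control cohort, zeros included. At level `t` the survival rule
is `w_ij ≥ μ_ij − t·σ_ij`; the cutoff is applied literally, so negative
cutoffs keep every nonzero edge, and equality keeps the edge. Because the
cutoff *decreases* with `t`, the level-0.5 edge set is a subset of the
level-5.0 set. Ten levels (0.5…5.0 by 0.5) are always available; 2.5 is the
default reporting level. Thresholding operates on streamline-weighted
values, the weighting being the first preprocessing step.

## Graph measures

* Degree centrality is the binary count of surviving edges — after
  control-referenced thresholding it indexes dysconnectivity. Weighted
  strength is available as a documented alternative.
* Path lengths use the standard connectomics map `ℓ = 1/w`; disconnected
  pairs have infinite distance and contribute zero to efficiency sums,
  which keeps fragmented patient networks finite.
* Global efficiency is the mean inverse shortest-path length over ordered
  pairs. Local efficiency of node *i* is the global efficiency of the
  subgraph induced by its neighbours (zero below two neighbours) — the
  common toolbox convention; the neighbour-subgraph variant is the one
  implemented and tested against brute-force enumeration.
* Clustering uses the Onnela geometric-mean form on weights normalized by
  the network maximum, so values lie in [0, 1] and agree with the binary
  coefficient on unweighted graphs.
* Hubs are the `floor(0.2·N)` subnetwork nodes with the highest
  control-average degree (6 of 31, 5 of 26); ties break by member-list
  order, deterministically.

## Behavioural preprocessing and components

Task scores are residualized on {1, age, age², age³} by OLS, then mapped
through the rank-based inverse-normal transform with Blom offsets,
`Φ⁻¹((r − 3/8)/(n + 1/4))`, average ranks for ties. The component model is
a PCA of the correlation matrix: components with unrotated eigenvalue > 1
are retained (Kaiser), then varimax-rotated. Rotation uses the classic
iterative pairwise (planar) algorithm with Kaiser row-normalization; the
analytic per-pair angle makes it robust on symmetric loading patterns where
SVD-based fixed-point iterations can stall. Scores use the regression
method `Z R⁻¹ Λ`; each component is sign-flipped so its largest loading is
positive, and components are ordered by post-rotation variance. Patient-only
and pooled cohorts are both supported run modes; the pipeline derives
components from patients only.

## Association analyses

Group comparisons use pooled-variance t-tests by default (Welch optional),
with the sign convention control − patient. Correlations are Pearson
(Spearman optional). FDR control is Benjamini–Hochberg step-up within
families: all global measures form one family; nodal results form one
family per network × metric (× component for correlations) across nodes —
per-metric nodal families are a documented choice, since pooling metrics
would change q-values.

Dissociation declarations are directional: degree and global efficiency
count when significantly *positively* related to performance, local
efficiency and clustering when significantly *negatively* related —
pathological increases in segregation accompany worse outcomes. The nodal
scope is the sharper probe, because nodal FDR families contain no strong
anchor tests and therefore rarely pass step-up correction without real
signal.

## Canonical correlation

Whole-connectome nodal degrees are standardized and PCA-reduced to the
smallest component count reaching 90% variance; the classical canonical
decomposition (QR + SVD) of those scores against the two cognitive
components yields `min(2, k)` modes. Per-mode significance permutes the
row order of the connectome block and refits, `p = (1 + #{ρ*≥ρ})/(B + 1)`
with B = 10,000 by default; marginal per-mode nulls are used rather than
sequential Wilks-style testing, mirroring the procedure the pipeline
emulates even though modes are not independent. A row permutation of a
centred block permutes the rows of its orthonormal QR factor, so each
permutation draw needs only the singular values of a small matrix — nulls
are computed in vectorized batches. Modes are interpreted by Pearson
back-projection onto raw tasks and raw degrees (zero-variance columns give
NaN). Overfit is gauged by training on random subsamples at fractions
{0.5…0.9}, applying trained weights to held-out rows, and averaging
held-out mode correlations over 1000 iterations, with a row-permuted
reference; near-singular within-block covariance raises with condition
numbers rather than silently regularizing.

## Kernel ridge prediction

Nodal measures of one subnetwork predict one component score via kernel
ridge regression in the dual, `α = (K + λI)⁻¹ y`, linear kernel by default
(enabling primal weight maps `w = Xᵀα`, averaged over outer folds). Nested
5-fold cross-validation selects λ on inner folds by MSE from a 13-point
logarithmic grid 1e−3…1e3; outer-fold predictions are pooled into one
Pearson r. Features are standardized inside each training fold only.

The target is centred once, globally, and no per-fold intercept is fit:
the intended targets are component scores, zero-mean by construction, and
per-fold intercepts make the pooled out-of-fold correlation systematically
negative under the null (≈ −√(k/n) with k folds, ≈ −0.14 at n=200, because
training-fold and held-out-fold means anti-correlate). With global
centring, measured null bias is ≈ −0.02. Reported `R²` is the squared
pooled correlation (descriptive); normalized MSE is MSE divided by the
variance of the observed target, so 1 means no better than the mean.
Significance permutes the target and reruns the full nested procedure;
the feature kernels and fold assignment are target-independent, so their
eigendecompositions are cached and each of the 1000 permutations costs a
few matrix–vector products. The dual solve drops numerically-null kernel
modes from the prediction path only (their exact contribution is zero;
keeping them amplifies eigenvalue roundoff by 1/λ in the small-λ limit),
while returned dual coefficients match the closed form.

## Synthetic cohort generator

The generator plants the causal structure the analysis is designed to
detect, at the study's scale (105 controls, 92 patients by default).

* **Edges.** The atlas fixture fixes 90 labels, the two membership lists
  (the nine shared regions and the hub regions placed by name; remaining
  members are a fixture convention, as complete lists are not public), and
  a streamline matrix with density 0.3 and log-normal counts. Control edge
  FA is truncated-normal(0.5, 0.1) on (0, 1) — exact truncated sampling,
  distributionally identical to resampling — so FA stays physical.
* **Patients.** Each patient's edges are lowered by a global deficit
  (default 1.0 control SD, the diffuse-injury component) plus half-normal
  subnetwork severities (scale 0.7 SD) applied to subnetwork-*exclusive*
  edges. Shared edges carry only the global deficit: this keeps the two
  severities statistically independent despite the nine shared nodes, so
  the planted asymmetry is clean.
* **Integrity and abilities.** Subnetwork integrity is the mean edge FA
  over the induced subgraph, standardized against controls. For ability
  construction each integrity is restandardized to unit patient variance —
  couplings are standardized effects, and the two subnetworks' different
  edge counts would otherwise distort the planted ability correlation.
  The asymmetric preset is wm→wm 0.8, wm→rsn 0.45, rsn→rsn 0.8, rsn→wm 0.
  Abilities are standardized against the patient distribution (the group
  the analyses run in; cohort-wide scaling would let the control–patient
  gap dominate the variance and dilute the within-patient loadings).
* **Tasks.** Within-factor loadings (0.75, 0.70, 0.65), a cubic age trend
  (centred at 50 y, scaled by 15; β = −0.30, −0.10, 0.02) and residual
  noise SD 0.4 (communality ≈ 0.8, typical of composite computerized
  scores and sufficient for the Kaiser rule to retain both components
  reliably at n ≈ 200 — at noise 0.6 the second eigenvalue is marginal and
  the two-factor structure is not dependably identifiable).

**What the generator does not emulate.** Real connectomes have spatially
structured, distance-dependent edge weights, lesion-driven focal damage,
and rich correlated nodal variation; here nodal variation is driven by two
severity factors plus independent edge noise, so multivariate models
recover the planted factors with unrealistically high accuracy (e.g. the
degree-PCA needs ~40 components for 90% variance instead of a handful, and
canonical correlations are higher than typical empirical values). Passing
recovery tests therefore demonstrates the statistical machinery is correct
and calibrated, not that effect sizes of this magnitude occur in patients.

**A structural caveat on the one-way dissociation.** Because the two
abilities correlate (the wm→rsn coupling) while component scores are
near-orthogonal by construction, the working-memory component necessarily
carries a small *negative* loading on reasoning ability. Univariate nodal
correlations of reasoning-network degree with the working-memory component
are therefore slightly negative — the directional declaration rule
correctly ignores them — but multivariate prediction can detect this
compensatory signal at large n: the reasoning-degrees → working-memory
model attains permutation p < 0.05 in roughly a fifth of synthetic
replicates at n = 200. This is a property of orthogonalized component
scoring with correlated abilities, not a bug in the estimators; at the
study's actual size (n = 92) the leak is far below detectability.

## Sizes used in tests

The test suite runs the oracle comparisons on 200 random ≤8-node graphs,
behavioural recovery on 100 cohorts of 200 patients, CCA calibration on 200
null replicates at 500 permutations, and the dissociation recovery on 50
cohorts with 100-permutation prediction tests — sizes chosen to make the
Monte-Carlo bounds meaningful while the whole suite stays fast on one CPU.
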