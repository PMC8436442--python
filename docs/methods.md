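# Methods

This note documents the models, conventions and design choices behind
`wmconnect`, in the order the pipeline runs them.

## Data model

The unit of analysis is a subject's symmetric, nonnegative N x N
connectivity matrix, with nodes given by a fixed atlas ordering (the shipped
default is a 90-region cortical/subcortical parcellation) and edge weights
interpreted as mean fractional anisotropy (FA) of the tracts joining two
regions — unitless, bounded in [0, 1], with 0 meaning "no tract". Matrices
must be symmetric within 1e-9 and have an exactly zero diagonal; after
validation they are symmetrized as (M + Mᵀ)/2, which absorbs floating-point
export noise without hiding genuine asymmetries.

## Sparsity thresholding

Comparing raw weighted networks confounds topology with overall connection
strength, so every network is reduced to the same edge count before metric
computation. At sparsity S the K = round(S·N(N−1)/2) strongest edges are
kept (round half up). The total order on edges is (weight descending, then
node pair (i, j) ascending), which makes the selection deterministic under
ties and makes edge sets nested across S — a property the AUC summary
implicitly relies on.

The analysis range of S is chosen by two standard criteria, applied to
every subject: the mean nodal degree 2K/N must exceed 2·ln N, and the
small-worldness σ must exceed 1.1. The logarithm is natural, the convention
of the small-world thresholding literature; with N = 90 the degree bound is
≈ 9.00, so the first admissible grid point at 0.01 spacing is S = 0.11
(S = 0.10 gives mean degree 8.91). The bound is applied as written; users
who prefer a published range can pass an explicit grid. Metric curves over
the grid are summarized per subject by the trapezoidal area under the curve; a
left-rectangle variant is available (``metric_auc(..., method="rectangle")``)
for parity with toolboxes that integrate that way, but the group contrast is
insensitive to the choice at 0.01 spacing.

## Graph metrics

All metrics exist in binary and weighted forms; weighted is the default
since the networks are FA-weighted. Conventions:

* **distance** of an edge = 1/weight (stronger connection = shorter path);
* **clustering** (weighted): Onnela geometric-mean variant with weights
  normalized by the network maximum; binary: triangle density;
* **characteristic path length Lp**: mean over finite ordered pairs; on
  fragmented networks the count of infinite pairs is reported rather than
  silently dropped (a largest-component-only Lp would change the n across
  subjects);
* **global efficiency / nodal efficiency**: mean of 1/d with 1/∞ = 0, so
  disconnected nodes contribute zeros instead of breaking the mean;
* **local efficiency** of a node: global efficiency of its neighbor-induced
  subgraph, 0 below degree 2;
* **betweenness**: unnormalized Brandes counts with fractional credit on
  tied shortest paths (the group contrast is invariant to normalization);
* **degree**: strength (weight sum) in weighted mode.

Normalized metrics divide by the mean over degree-preserving random
references: γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ. References are
generated by Maslov–Sneppen double-edge swaps (attempted swaps = 10 per
edge by default); in the weighted case the topology is rewired and the
original weight multiset is reassigned to the rewired edges in random
order, preserving both the binary degree sequence and the weight
distribution. Defaults of 100 references suit final analyses; the tests and
the acceptance script use 3–10, which is enough because γ and λ are ratios
of means whose Monte-Carlo error enters both groups identically. The swap
kernel is JIT-compiled (numba) because it dominates the cost of the
metric-over-grid loop.

## Group statistics

Between-group differences of metric AUCs use a pooled-variance two-sample t
statistic with a permutation null built by relabeling group membership
(10,000 permutations by default). The p-value is the add-one estimator
(1 + #{|t*| ≥ |t|})/(n_perm + 1): it can never return 0 and is valid at any
permutation count. With covariates (e.g. the 8 head-motion parameters),
values are first residualized on [1, C] and the residuals are permuted
(Freedman–Lane-style); this is the standard valid scheme when the covariate
model is shared across groups. Tests are two-tailed; no multiplicity
correction is applied across the seven global metrics (raw p-values are
reported, as is conventional for this small fixed family).

Nodal findings follow a two-of-three rule: a region is reported only when
at least two of degree, betweenness and efficiency differ at α = 0.05 *in
the same direction*. This trades formal FWER control for power while
guarding against single-measure flukes; an optional Benjamini–Hochberg flag
tightens it per measure.

Clinical associations are partial Pearson correlations: both variables are
residualized by OLS on an intercept plus age, sex and illness duration, r
is the correlation of residuals, and p comes from the t distribution with
n − k − 2 degrees of freedom.

## Network-based statistic

Edge-level inference uses the NBS: edgewise two-sample t statistics on the
raw (unthresholded) FA weights, a primary height threshold of t = 2.62,
connected components of the surviving edges, and FWER-corrected p-values
from the permutation distribution of the maximum component edge count
(10,000 permutations by default). The two directions are analyzed
separately (a decreased-connectivity contrast is the primary clinical
hypothesis); only edges present in at least 50% of subjects enter the
analysis, because t statistics on near-absent tracts are unstable. Raw
weights rather than thresholded networks are tested so that the result does
not depend on a sparsity choice.

## Progression-rate classification

The baseline progression rate is (48 − ALSFRS-R)/months since onset,
binarized at 0.68 points/month into fast vs. slow. Features are the
N(N−1)/2 upper-triangle edge weights of the unthresholded matrix. The
classifier is PCA (components explaining 80% of training variance) followed
by a linear-kernel SVM. Accuracy is estimated by nested stratified
cross-validation: 10 outer folds score balanced accuracy
((sensitivity + specificity)/2), 5 inner folds choose C from
{10⁻³ … 10³}, ties to the smaller C. PCA and SVM are fitted strictly on
the training side of each fold; the test fold enters only through the
frozen transform. Fold counts are clamped (with a warning) when a class is
smaller than the requested k, which only matters for toy cohorts.

Significance comes from re-running the entire nested procedure — including
C re-tuning — on label-shuffled data (5000 shuffles by default;
conservative relative to fixing C). Edge importance is back-mapped from the
final model (refit on all patients with the modal best C): the 10
components with the largest |SVM weight| are selected and
importance(edge) = Σ |w_pc|·|loading_pc,edge|, reported as a ranked top-50
table with region names. Absolute loadings are used because the sign of a
principal axis is arbitrary; a signed sum would be seed-dependent.

## Synthetic cohorts

The generator emulates the statistical structure of a two-group FA
connectome study without any imaging:

* a shared backbone of 90 nodes in 6 modules (round-robin assignment),
  within-module edges present with p = 0.95 at mean weight 0.50, between-
  module edges with p = 0.30 at mean weight 0.35 (SD 0.10, truncated to
  (0, 1)); the higher within-module weights mean sparsity thresholding
  retains the clustered core, giving σ > 1.1 over the analysis range, and
  the raw density (≈ 0.40) stays above the densest analysis threshold;
* per-subject Gaussian jitter (SD 0.03) on backbone edges;
* patients: within-module weights scaled by 1 − group_effect
  (default 0.15), driving Cp, γ and σ down;
* a planted connected 5-edge path reduced additively by 0.10 in patients
  (the NBS target);
* 20 planted edges reduced by 0.045 in fast progressors (effect size
  d ≈ 1.5 against the subject jitter — a strong but attainable
  single-subject signal);
* clinical covariates matched to a typical sporadic-ALS sample: age
  ~ N(49.8, 8²), duration lognormal with mean ≈ 10.6 months, anxiety and
  depression scale scores, respiratory subscore fixed at its ceiling, and
  the functional-scale total back-computed from a drawn rate so the
  fast/slow split (40% fast) is exercised through the rate formula itself,
  with a guard band around the cut-off so integer rounding cannot flip a
  class.

What the generator does **not** model: spatial embedding and distance-
dependent connection probability, hemispheric symmetry, realistic
between-subject topology variation (all subjects share one backbone edge
set), site/scanner effects, and any true topology–severity coupling beyond
the planted effects. Passing tests therefore demonstrate that the pipeline
recovers known effects of realistic size under realistic noise — not that
it would produce the same numbers on real patient data.

## Problem sizes and numerical choices

The test suite and acceptance script scale simulations to keep runs quick:
cohorts of 30–60 subjects for replicate-heavy checks (the full 73 + 100
cohort is used where a single run suffices), sparsity grids at 0.04–0.06
spacing instead of 0.01, 3–10 random references, and 1000–2000
permutations instead of 10,000. Replicate counts and pass thresholds for
the validity checks (type-I error in [0.03, 0.07] at 500 replicates, NBS
family-wise error ≤ 0.07 at 200 replicates, etc.) are stated in the tests
themselves. Degenerate inputs are handled explicitly: zero-variance data
yield p = 1 with a warning, all-equal weights threshold deterministically,
NaNs in metric curves propagate to the AUC with a warning naming the
subject, and empty sparsity ranges raise an error carrying per-criterion
diagnostics.

## Known limitations

* The weighted σ of dense unstructured graphs sits slightly above 1 (the
  weight-shuffle reference lowers ⟨Cp_rand⟩ a little relative to the
  original), so the σ > 1.1 criterion, not σ > 1, is the meaningful
  small-world cut.
* Lp on fragmented networks mixes component scales; the infinite-pair count
  is reported so users can detect heavy fragmentation.
* The NBS edge universe (50% presence) is a pragmatic default; with very
  heterogeneous tractography a stricter universe may be warranted.
* The permutation null for the classifier re-tunes C per shuffle, which is
  conservative and costly; a fixed-C variant would run ~7x faster but
  slightly anti-conservative.
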