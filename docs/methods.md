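# Methods notes

This note records the modelling choices, defaults and known limitations of
`enterokit`, in the spirit of a package methods appendix. It describes what
the code computes; every number quoted here is produced by the test suite
or by `scripts/acceptance.py` at run time.

## Distances

Jensen–Shannon distance is the square root of the Jensen–Shannon
divergence computed with **base-2 logarithms**, so both divergence and
distance live on [0, 1] and the distance is a true metric (triangle
inequality property-tested). No pseudocounts are used: the mixture
m = (p+q)/2 is nonzero wherever p or q is, and terms with pᵢ = 0 contribute
zero by the x·log x → 0 limit. Bray–Curtis on compositions reduces to
1 − Σ min(pᵢ,qᵢ), which equals the classical 1 − 2W/(A+B) form. The
pairwise JSD matrix is computed through the entropy identity
JSD(p,q) = H(m) − (H(p)+H(q))/2, which is O(n²·t) with one pass per row.

Both metrics are first-class: the clustering records which metric produced
each partition, since the literature this workflow follows uses Bray–Curtis
in its methods and JSD in its results for the same operation.

## PCoA

Classical Torgerson scaling: double-centre −D²/2, eigendecompose, scale
eigenvectors by √λ. Axes with eigenvalue ≤ 1e-10 are dropped; negative
eigenvalues are **discarded** (no Lingoes/Cailliez correction) and their
total magnitude is recorded on the embedding, because the embedding is used
only for visualisation and for the Calinski–Harabasz computation.
Variance explained is relative to the positive-eigenvalue total.

## PAM and K selection

PAM is the classical BUILD (greedy seeding minimising total cost) plus SWAP
(best-improvement medoid/non-medoid exchange to a local optimum). All ties
break on the lowest sample index, making fits deterministic across runs and
platforms; the `seed` argument exists for interface symmetry only. On tiny
instances (C(n,K)·n ≤ 2·10⁵) the medoid problem is solved **exactly by
enumeration**: BUILD+SWAP is a local-search heuristic and can miss the
global optimum even at n = 6, whereas enumeration is cheap there and makes
the optimality contract unconditional. Cluster labels are canonicalised by
decreasing size (ties by lowest medoid index) so "E1" is stable.

Four validity indices are computed per K (default range 2–8):

* **Calinski–Harabasz** in the PCoA space of the same distance matrix
  (CH needs centroids, which a raw distance matrix lacks). W = 0 yields a
  +inf perfect-separation sentinel.
* **Mean silhouette** directly from the distance matrix; singletons score 0.
* **Davies–Bouldin**, medoid-based variant: scatter = mean member-to-medoid
  distance; separation = medoid-to-medoid distance (distance-matrix-native).
* **Dunn**: single-linkage separation / complete-diameter, the most common
  definition.

`chosen_K` is argmax CH with mean silhouette as tie-break (then the smaller
K). CH is the primary criterion of the canonical enterotyping procedure;
the full curves are always retained so a user can pin K per kingdom.

## Driver genera, BCA

The driver of a cluster is the taxon with the highest mean relative
abundance over its members; argmax ties resolve lexicographically by name
and are recorded. Between-class analysis is PCA of the size-weighted group
centroids of the column-centred sample×taxa matrix; samples are projected
onto the (orthonormal) centroid axes and the between/total inertia ratio is
reported.

## Dirichlet-multinomial mixture

EM with exact posterior responsibilities and Minka's fixed-point update for
the Dirichlet parameters (an MM step, hence the observed log-likelihood is
monotone non-decreasing — asserted every iteration in the tests).
Convergence at log-likelihood gain < 1e-4; best of 3 seeded restarts;
BIC = −2·loglik + p·log n with p = (K−1) + K·n_taxa. When only relative
abundances exist, counts are reconstituted at a configurable depth (default
10,000 reads/sample) by largest-remainder rounding, which preserves column
sums exactly.

## Differential features

Rank tests delegate to scipy (exact Mann–Whitney for small untied samples,
tie-corrected normal approximation otherwise; tie-corrected Kruskal–Wallis
with χ² p-values). BH-FDR uses the statsmodels step-up. Note the step-up is
*not* idempotent on arbitrary adjusted vectors — only flat adjusted vectors
are fixed points — so the tests assert monotonicity and the flat-vector
fixed point rather than general idempotence.

The LEfSe-style screen is an explicit, documented approximation of the
reference procedure (which publishes no closed formula): (1) per-feature
Kruskal–Wallis gate at α = 0.05 on BH-adjusted p-values; (2) rescale to a
per-sample sum of 10⁶; (3) 30 bootstrap rounds subsampling 2/3 of each
class and fitting a one-axis pooled-covariance discriminant with a ridge
term (1e-6) for compositional collinearity; per-feature effect per round is
|0.5·(w_f·Δ_axis + Δ_f)|; (4) score = log₁₀(1 + mean effect); retain
score > 2. All constants are arguments. `p_adjust="none"` exposes the raw
per-feature gate, which is what the type-I-error calibration tests measure
(with BH active the per-feature null rejection rate is far below α by
construction, which is the point of FDR control, not a calibration target).

PERMANOVA follows the adonis convention on squared dissimilarities with
free label permutation; the observed statistic is included in the null set,
so min p = 1/(1+n_perm). With duplicated samples, permutations can tie the
observed F, so the floor is only attainable when clusters are distinct.

## Pathway association

Enrichment is one-vs-rest Wilcoxon rank-sum per (pathway, enterotype) with
log₂ fold change of means, ε-floored at half the smallest nonzero table
value; BH within each enterotype's family. Correlation (Spearman on
mid-ranks or Pearson; both exposed since the source workflow names both)
uses the t-approximation p-value and BH across the pairs tested;
zero-variance vectors are reported as missing with a reason rather than
silently dropped. Cross-kingdom correlations cover between-kingdom panel
pairs only.

## Classification

Stratified 80/20 split; grid search (default: trees {200, 500}, depth
{unlimited, 8}, features/split {sqrt, 0.5}) by cross-validated AUC on the
training fold only; metrics on the held-out fold at probability threshold
0.5. The 100-replicate bootstrap resamples the **held-out predictions**
class-stratified (internal validation of the fixed model); refit-bootstrap
is available by flag. Importances are normalised impurity importances.
Class imbalance is handled by stratification only. Model comparison uses a
paired bootstrap over the shared test fold with percentile intervals on
AUC differences.

## Synthetic cohorts

The generator draws, per sample and kingdom, an enterotype from the
subgroup's mixing vector, a composition from that enterotype's Dirichlet
component (a shared power-law base profile with the driver's parameter
boosted), and integer counts multinomially at the kingdom's depth. The
default preset mirrors the study architecture: 295 samples
(CHP 78 / HHP 68 / CAP 106 / HAP 43); kingdom read fractions 97% bacteria,
0.01% fungi, 0.08% archaea of a 30,000-read desk-scale depth, with a
200-read floor so the minor kingdoms stay clusterable (pure realism at
0.01% of a desk-scale depth would leave ~3 reads/sample, which is
untypable at any scale); seven enterotypes whose driver mean shares follow
the reported cluster profiles (Prevotella 47%, Bacteroides 25%,
Saccharomyces 85%, Malassezia 16%, Methanobrevibacter 80%, Methanosarcina
31%, Methanosphaera 87%); and region-skewed mixing (E1 41.4% HP vs 18.5%
CP; E3 27.0% vs 18.5%; E5 29.7% vs 26.6%), with the mass not pinned by
those figures split in proportion to the reported enterotype sizes. The
within-cluster Dirichlet concentrations (total α = 80 bacteria / 25 fungi /
15 archaea) are not stated by the emulated study; they were chosen once so
that clusters are tight enough to be recoverable, consistent with the
study's report of clean enterotype separation, and sit in the range of
concentrations typically fitted to real genus tables. Pathways are linear
combinations of chosen genus abundances plus Gaussian noise (floored at 0)
over a lognormal background.

Randomness flows from a single seed through per-sample `SeedSequence`
substreams, so cohorts are bit-reproducible and extending a cohort never
perturbs existing samples. `inject_group_signal` multiplies chosen taxa in
target subgroups, renormalises, and re-derives counts by largest-remainder
rounding; tables are re-quantised from those counts so injected and
non-injected samples share the same count grid (otherwise a classifier can
detect off-grid values — a leakage artifact, not biology).

**What the generator does not emulate:** phylogenetic correlation among
taxa, overdispersion beyond the Dirichlet component, longitudinal
structure, batch effects, and the dozens of genuine genus-level
population differences real cohorts show beyond enterotype mixing.
Consequently the pure preset carries only weak genus-level region signal
(classifier AUCs near chance), and classification experiments use injected
signals with known ground truth; passing tests demonstrate correctness of
the machinery, not effect sizes attainable on real cohorts. The reference
AUCs reported by the emulated study (0.75–0.85) depend on its deposited
cohort and are documented reference points only.

## Pipeline determinism

Stage outputs are plain TSV/JSON in a flat run directory; every file's
sha256 goes into `manifest.json` along with the config snapshot. Wall-clock
notes are written to `run.log`, deliberately outside the manifest, so
rerunning with an identical config yields a byte-identical manifest.

## Problem sizes used in the tests

The acceptance-style tests run 20 preset cohorts of 295 samples for
recovery, 1,000-simulation calibration studies per test (PERMANOVA at
n_perm = 199), 200 exhaustive PAM comparisons at n ≤ 6, and scaled-down
pipeline runs (40 samples) for determinism — sizes chosen to make the
properties sharp while keeping the suite around a minute of compute.
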