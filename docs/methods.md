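# Methods

This note documents the statistical procedures implemented in `emtsig`,
the choices made where the analysis design was genuinely open, and what
the synthetic-data experiments do and do not demonstrate.

## Differential expression without replicates

The experimental design supplies exactly one RNA-seq library per cell
state per model, so no within-condition dispersion is estimable and
replicate-aware models (negative-binomial GLMs, shrinkage estimators)
are not identifiable. `diffexp.proportion_test` therefore uses the
two-library proportion z-test on read counts — the standard
replicate-free test that treats each gene's reads as a binomial draw
from the library — with the pooled-variance z statistic and a two-sided
normal p. Degenerate inputs (zero counts in both libraries, pooled
proportion with zero variance) return p = 1: absence of evidence, not
an error. The test is exactly antisymmetric in the two libraries.

A gene is called differential when it passes all three filters
simultaneously: |log₂ fold change| > 1, BH-adjusted FDR < 0.05, and
|CPM difference| > 5. Fold changes are computed on CPM with a
pseudocount of 1 CPM added to both states; this keeps ratios finite for
zero counts and is negligible at the ΔCPM > 5 scale where calls can
happen. Benjamini–Hochberg adjustment is implemented directly
(sorted p·m/rank with a reverse cumulative minimum, capped at 1) so the
output is exactly the step-up procedure, order-preserving and monotone.

The consensus signature is the per-direction intersection across
models: a gene must be called up in every model to enter the up list
(symmetrically for down). Genes significant everywhere but with
inconsistent directions are excluded and reported, never
majority-voted. Consequently adding a model can only shrink or preserve
the signature.

Overlap against a reference collection uses the query-normalized
fraction |Q ∩ B| / |Q| with Q the union of the up and down lists, and
disregards reference sets under 50 genes; the per-gene tally of how
many references contain each signature gene is reported alongside.

## Preranked gene-set enrichment

Rankings keep genes with raw p < 0.05 ordered by descending log₂ fold
change, with score ties broken lexicographically by gene id for
cross-platform determinism. The enrichment score is the weighted
Kolmogorov–Smirnov running sum: hits add |score|^w normalized by the
sum over hits (w = 1 by default, the classic weighted setting), misses
subtract 1/(N − m); the ES is the signed extremum, with a tie between
the positive and negative extremum resolved toward the positive. The
leading edge collects hit genes at or before a positive extremum (at or
after a negative one).

The null model is gene-label permutation — random same-size subsets of
the ranked universe — for every mode. With three samples per phenotype
class, phenotype permutation admits too few distinct relabelings to
support a permutation p-value, so the gene-permutation null is a
deliberate, uniform substitution. NES divides the observed ES by the
mean |ES| of same-signed null draws; the nominal p is the same-signed
exceedance fraction (flagged and reported as 1/n_perm when no null
shares the sign); FDR q follows the sign-stratified pooled-NES
convention, with monotonicity enforced so a more extreme NES never
receives a larger q. Per-set permutation streams are derived from the
seed and the set name, so collection iteration order cannot change any
number. Sets are restricted to the ranked universe and excluded outside
[15, 1000] members — 15 is the conventional minimum; 1000 the
configured maximum.

## Clustering and cluster-count selection

Both axes are clustered on the z-scored matrix (per-gene mean 0,
sample-SD 1 using the n−1 denominator; zero-variance genes are set to
zero, flagged, and removed before correlation distances) with
correlation distance d = 1 − Pearson r and complete linkage, via
scipy's agglomerative implementation. The same distance/linkage pair is
used for the stability scan and the final cut, so the selected k
applies to the partition actually reported. scipy's linkage is
deterministic for a fixed input, which is the property the pipeline
needs; no additional tie-breaking layer is imposed on merge order.
Cutting the same tree at k and k+1 always yields nested partitions.

Cluster-count selection scans k = 2..10 and computes three stability
indices per k:

* **connectivity** — Σᵢ Σⱼ₌₁..L 1/j over the L = 10 nearest neighbors
  of each item that land in a different cluster (0 is perfect; L is the
  conventional default of the stability-validation literature and is
  exposed as a flag). Distance ties in neighbor ranks resolve by index
  through a stable argsort.
* **Dunn index** — minimum between-cluster distance over maximum
  within-cluster diameter; singleton clusters contribute no diameter,
  and an all-singleton partition scores +∞ (never reached in the
  scanned range).
* **mean silhouette width** — (b−a)/max(a,b) averaged over items,
  computed by scikit-learn on the precomputed distance matrix;
  singletons receive 0.

Each index ranks the k values (connectivity ascending, the others
descending); the k with the best mean rank is recommended, ties go to
the smaller k and are flagged, and the full table is always returned so
a human can overrule the recommendation — subtype separation is
knowledge the indices do not see.

Gene clusters (the tree cut at 3) are annotated from frac_up, the
fraction of the cluster's genes on the consensus up list: EMT-up at
frac_up ≥ 0.75, EMT-down at ≤ 0.25, partial-EMT between. The published
analyses labeled clusters by inspection of the same composition (a 91%
up cluster reads as EMT-up); the thresholds make that call explicit,
are configurable, and the fractions are always reported next to the
labels.

## Survival, correlation, CNV, response

Kaplan–Meier estimation and the log-rank test are delegated to
lifelines. Display truncation "up to five years" is implemented as
administrative censoring at 1,826 days — observations beyond the
horizon re-enter as censored at the horizon, not excluded — which is
standard practice and keeps at-risk counts honest. A comparison with no
events anywhere returns p = 1 with a flag.

Driver correlation computes Pearson r between one gene (ZEB1, SNAI1,
…) and every labeled signature gene across samples, then compares the r
values across gene-cluster labels with the Kruskal–Wallis test
(chi-square approximation with tie correction; exact enumeration is
impractical at these group sizes). The driver is excluded from its own
group, since its self-correlation of 1 is uninformative.

Two-group expression comparisons default to the two-sided Mann–Whitney
U test (normal approximation with tie correction), robust for skewed
expression; a Welch t-test is available behind a flag. p-values map to
the conventional stars at 0.05/0.01/0.001/0.0001. Identical groups are
reported as p = 1 directly rather than through the continuity-corrected
approximation.

CNV summaries accept GISTIC-style thresholded calls in {−2,…,2}
(negative → deletion, 0 → normal, positive → amplification) or already
categorical labels, and report per-group counts and percentages.

Signature response asks, per signature gene and per condition versus a
baseline column, whether the expected direction is realized:
a consensus-up gene is *non-affected* when its log₂ change against
baseline exceeds +1 (the signature's own FC > 2 criterion, configurable)
and *affected* otherwise, symmetrically for down genes; per-direction
affected fractions are reported.

## Synthetic data: what it emulates

`simulate_models` draws a per-gene expected CPM from a log-normal,
multiplies the mesenchymal expectation by 2^(±lfc) for planted genes
(|lfc| uniform on 1.5–4), and draws Poisson counts at a 2M-read library
size — Poisson rather than negative binomial because with one library
per state no overdispersion is observable, matching the proportion-test
assumption. Three models share a planted core of 134 up and 131 down
genes and each adds 800 model-specific genes per direction, so the
consensus core is the intersection of the per-model sets by
construction.

Planted baselines are direction-specific: down-planted genes start high
(median ≈ 118 CPM) and up-planted genes start low (median ≈ 15 CPM),
with the two medians in the ratio E[2^lfc − 1]/E[1 − 2^−lfc] ≈ 7.9.
This mirrors the biology — epithelial program genes (CDH1, OCLN) are
abundant before the transition, mesenchymal program genes (VIM, CDH2)
are induced from a low base — and it balances the transcriptome mass
gained by induction against the mass lost to repression. The balance
matters: when thousands of genes move several-fold in one direction,
library-size normalization shifts every observed fold change by the
compositional log-ratio, which both biases unchanged genes toward
spurious calls and pushes weakly planted genes under the fold-change
filter. Down-regulated genes starting high also guarantees they clear
the ΔCPM > 5 detection floor, which a gene under ~8 CPM cannot.

`simulate_cohort` plants 6 sample clusters over 3 gene blocks
(90 EMT-up / 85 partial-EMT / 90 EMT-down genes): expression is block
mean + Gaussian noise (SD 1.0) on the log₂ scale, with the six cluster
profiles being the six orderings of (+2, 0, −2) over the blocks — every
cluster has a distinct correlation *shape*, which is the only thing a
correlation-distance clustering of z-scored data can see. At these
defaults the within-cluster Pearson correlation is ≈ 0.73 against
≤ ≈ 0.37 between clusters. Survival times are exponential with
per-cluster hazards (the basal-enriched cluster carries the highest),
censored at an independent uniform draw over ten years; subtypes and
CNV categories are multinomial per cluster, with one basal-dominated
cluster and amplification-heavy CNV in two clusters to give the
downstream summaries non-trivial structure.

`simulate_signature_db` builds reference sets of controlled overlap:
each set takes round(f·size) genes from the query core and the rest
from the background universe, making the measured overlap fraction
exact up to rounding.

A single integer seed fans out to named per-component RNG streams
(seed × CRC32 of the stream name), so identical configs reproduce
byte-identical outputs and adding a new generator never perturbs
existing draws.

**What passing these tests shows — and does not.** The synthetic
experiments demonstrate that the implementation recovers planted
structure under its own model assumptions: Poisson counts, log-normal
abundances, Gaussian block cohorts, exponential survival. Real data
violate all of these (overdispersion, batch effects, correlated genes
within pathways, non-proportional hazards), so recovery rates measured
here are upper bounds on real-data behavior, and the per-model DE
totals of any particular wet-lab study are not expected to reproduce.

## Numerical conventions and problem sizes

* All interchange formats are plain text (TSV, GMT, JSON); floats are
  written with `%.10g`, which round-trips the values relevant here and
  makes artifact checksums stable.
* Correlation distance matrices are symmetrized ((d + dᵀ)/2) and
  clipped to [0, 2] to remove floating-point asymmetry before linkage.
* Workflow manifests record the config, seed, package version and a
  SHA-256 checksum per artifact; determinism checks compare checksums.
* The test suite and the acceptance script run the derivation at the
  full default size (12,000 genes, 3 models, 2M reads), the cohort at
  1,000 samples × 265 genes, log-rank calibration at 2,000 null
  replicates (50 per arm) and power at 400 replicates (200 per arm),
  and cluster-count recovery over 25–50 independent cohorts; these
  sizes give the binomial margins the assertions rely on.

## Known limitations

* The DE test assumes Poisson sampling; on overdispersed real libraries
  its p-values are anti-conservative, and calls should be read as a
  ranking rather than calibrated inference.
* Gene-permutation GSEA nulls ignore inter-gene correlation and are
  typically liberal relative to phenotype permutation; with n = 1 per
  state there is no alternative.
* The quality gate requires ≥ 50% of signature genes in a cohort;
  below that the stratification aborts rather than silently thinning.
* No Cox regression or multivariable survival modeling; the survival
  module covers Kaplan–Meier and log-rank comparisons only.
* Microarray cohort matrices are accepted as already-numeric values
  with a scale tag; no platform-specific preprocessing is applied.
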