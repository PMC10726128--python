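# emtsig

Derivation of a consensus epithelial–mesenchymal transition (EMT)
gene-expression signature from paired epithelial/mesenchymal RNA-seq
libraries, and its use to stratify breast-cancer expression cohorts into
EMT-up, partial-EMT and EMT-down groups — with stability-validated
cluster counts, Kaplan–Meier survival comparison, EMT transcription
factor correlation, and knockout response scoring.

The package is aimed at computational biologists who want a tested,
reproducible re-implementation of this analysis style: every stage runs
on plain TSV/GMT inputs, and a synthetic-data module generates
realistic inputs with planted ground truth so the whole pipeline can be
exercised and validated without any external download.

## What it computes

**Workflow A — signature derivation.** Each EMT model contributes one
epithelial and one mesenchymal library (no replicates). Per gene the
two libraries are compared with the two-proportion z-test on counts,

```
z = (x₁/n₁ − x₂/n₂) / √(p₀(1−p₀)(1/n₁ + 1/n₂)),   p₀ = (x₁+x₂)/(n₁+n₂),
```

p-values are Benjamini–Hochberg adjusted, and a gene is called
differential when |log₂FC| > 1 (CPM scale, pseudocount 1), FDR < 0.05
and |ΔCPM| > 5. The consensus signature is the per-direction
intersection across all models; genes with conflicting directions are
excluded and reported. The signature is scored against a reference
gene-set collection (overlap fraction |Q∩B|/|Q|, sets under 50 genes
disregarded) and per-model rankings (significant genes ordered by
log₂FC) are fed to preranked GSEA: the classic weighted running-sum
enrichment score with a gene-permutation null, sign-stratified NES,
nominal p and FDR q.

**Workflow B — cohort stratification.** Signature genes are extracted
from the cohort matrix (absent genes dropped with a report; a <50%
coverage gate aborts), z-scored per gene, and both axes are clustered
hierarchically (correlation distance, complete linkage). The number of
sample clusters is scanned over k = 2..10 and ranked by three stability
indices — connectivity (lower better), Dunn index and mean silhouette
width (higher better) — and the best mean rank is recommended. Gene
clusters are annotated EMT-up / partial-EMT / EMT-down from their
fraction of consensus-up genes. Downstream: cluster-by-subtype
composition tables, Kaplan–Meier curves truncated at five years with
log-rank comparison, Pearson correlation of a driver gene (e.g. ZEB1)
with every signature gene compared across gene clusters by
Kruskal–Wallis, CNV category summaries, and signature-response scoring
of perturbation (e.g. knockout) profiles.

## Worked example

Simulate three EMT models with a planted 134-up/131-down core and run
the full derivation:

```python
from emtsig import synthetic, pipeline
from emtsig.pipeline import PipelineConfig

matrices, truth = synthetic.simulate_models(synthetic.ModelSimConfig(seed=7))
res = pipeline.run_derivation(matrices, "demo_out", config=PipelineConfig(seed=7))
sig = res["signature"]
print(f"consensus signature: {len(sig.up)} up, {len(sig.down)} down")
rec = (len(set(sig.up) & set(truth.core_up))
       + len(set(sig.down) & set(truth.core_down))) / 265
print(f"planted-core recovery: {rec:.1%}")
```

prints

```
consensus signature: 133 up, 131 down
planted-core recovery: 99.6%
```

i.e. the triple-filtered intersection recovers 264 of the 265 planted
core genes (one weakly induced gene misses the fold-change cut in one
model) and admits no gene outside the planted core. `demo_out/`
contains the per-model DE tables, the signature as GMT, and a
`manifest.json` with a SHA-256 checksum per artifact — rerunning with
the same seed reproduces the checksums bit for bit.

The same is available from the shell:

```bash
emt simulate --outdir sim --seed 7
emt all --outdir run --seed 7
emt stratify --signature run/derivation/signature.gmt \
    --matrix sim/cohort_matrix.tsv --annotation sim/cohort_annotation.tsv \
    --outdir strat --driver G00000
```

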