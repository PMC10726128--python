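"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators cover the study design end-to-end without any external
download:

* :func:`simulate_models` — paired epithelial/mesenchymal RNA-seq count
  libraries for several cell-line models (one library per state per
  model, i.e. no replicates), with a shared planted core of up/down
  genes plus model-specific differential genes.
* :func:`simulate_cohort` — a tumor cohort whose expression over the
  signature genes is block-structured (EMT-up / partial-EMT / EMT-down
  gene blocks crossed with sample clusters), plus subtype labels,
  exponential survival with uniform censoring, and thresholded CNV
  categories.
* :func:`simulate_signature_db` — a collection of reference gene sets
  with controlled overlap against a query signature, emulating a
  database of published EMT signatures.

All generators are driven by a single integer seed through named
sub-streams (see :mod:`emtsig._rng`): identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .matrix_io import ExpressionMatrix, GeneSetCollection

# The six default sample clusters are the six orderings of a
# (high, mid, low) profile over the three gene blocks: every cluster has a
# distinct correlation *shape*, which is what a correlation-distance
# clustering can see after per-gene z-scoring.
_DEFAULT_BLOCK_MEANS = [
    [2.0, 0.0, -2.0],
    [2.0, -2.0, 0.0],
    [0.0, 2.0, -2.0],
    [0.0, -2.0, 2.0],
    [-2.0, 2.0, 0.0],
    [-2.0, 0.0, 2.0],
]

_DEFAULT_SUBTYPES = ("luminal_A", "luminal_B", "HER2_enriched", "basal_like", "normal_like")

# Subtype mixtures loosely follow the breast-cancer cohort shape: one
# cluster dominated by basal-like tumors, one by luminal-B/HER2, the rest
# mixed luminal-A-heavy.
_DEFAULT_SUBTYPE_MIXTURE = [
    [0.35, 0.10, 0.10, 0.35, 0.10],
    [0.60, 0.15, 0.10, 0.05, 0.10],
    [0.60, 0.15, 0.10, 0.05, 0.10],
    [0.55, 0.20, 0.10, 0.05, 0.10],
    [0.10, 0.05, 0.05, 0.75, 0.05],
    [0.30, 0.40, 0.25, 0.02, 0.03],
]

# Event rates per cluster (per day). The basal-enriched cluster (index 4)
# carries the highest hazard so survival contrasts are exercised.
_DEFAULT_HAZARDS = [4e-4, 3e-4, 3e-4, 3e-4, 8e-4, 2.5e-4]

_DEFAULT_CNV_PROBS = [
    [0.02, 0.08, 0.90],
    [0.10, 0.60, 0.30],
    [0.10, 0.60, 0.30],
    [0.10, 0.60, 0.30],
    [0.02, 0.08, 0.90],
    [0.15, 0.65, 0.20],
]


@dataclass
class ModelSimConfig:
    """Configuration for the paired EMT-model library generator.

    Planted genes draw their epithelial baseline from direction-specific
    log-normals.  Down-planted genes start high (epithelial program genes
    are highly expressed before the transition) and up-planted genes
    start low (the mesenchymal program is induced from a low base).  The
    default means are set so the expected transcriptome mass gained by
    induced genes equals the mass lost by repressed ones: without that
    balance, library-size (CPM) normalization shifts every observed fold
    change by the compositional log-ratio, biasing calls on unchanged
    genes and attenuating weak planted effects.  Down genes starting high
    also guarantees they clear the CPM-difference detection filter.
    """

    n_genes: int = 12_000
    n_models: int = 3
    core_up: int = 134
    core_down: int = 131
    model_specific_up: int = 800
    model_specific_down: int = 800
    lfc_range: tuple[float, float] = (1.5, 4.0)
    library_size: int = 2_000_000
    baseline_log_mean: float = 3.4  # natural-log CPM, median ~30 CPM
    baseline_log_sd: float = 1.0
    # natural-log CPM medians: up ~15 CPM, down ~118 CPM; the ratio
    # E[2^lfc - 1] / E[1 - 2^-lfc] (~7.9 for lfc in 1.5..4) balances the
    # mass induced against the mass repressed
    planted_up_log_mean: float = 2.7
    planted_down_log_mean: float = 4.77
    planted_log_sd: float = 0.6
    seed: int = 0

    def n_planted(self) -> int:
        return self.core_up + self.core_down + self.n_models * (
            self.model_specific_up + self.model_specific_down
        )

    def validate(self) -> None:
        if self.n_planted() > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: {self.n_planted()} planted genes > {self.n_genes} total"
            )
        if self.lfc_range[0] < 0 or self.lfc_range[1] < self.lfc_range[0]:
            raise ValueError("lfc_range must be 0 <= low <= high")
        if self.n_models < 1:
            raise ValueError("need at least one model")


@dataclass
class CohortSimConfig:
    """Configuration for the block-structured tumor-cohort generator."""

    n_samples: int = 1000
    gene_blocks: dict[str, int] = field(
        default_factory=lambda: {"EMT-up": 90, "partial-EMT": 85, "EMT-down": 90}
    )
    n_sample_clusters: int = 6
    block_mean_matrix: list[list[float]] = field(
        default_factory=lambda: [row[:] for row in _DEFAULT_BLOCK_MEANS]
    )
    noise_sd: float = 1.0
    subtypes: tuple[str, ...] = _DEFAULT_SUBTYPES
    subtype_mixture: list[list[float]] = field(
        default_factory=lambda: [row[:] for row in _DEFAULT_SUBTYPE_MIXTURE]
    )
    hazard_per_group: list[float] = field(default_factory=lambda: list(_DEFAULT_HAZARDS))
    censor_max_days: float = 3650.0
    cnv_probs: list[list[float]] = field(
        default_factory=lambda: [row[:] for row in _DEFAULT_CNV_PROBS]
    )
    gene_ids: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        k = self.n_sample_clusters
        if len(self.block_mean_matrix) != k:
            raise ValueError("block_mean_matrix must have one row per sample cluster")
        nb = len(self.gene_blocks)
        if any(len(row) != nb for row in self.block_mean_matrix):
            raise ValueError("block_mean_matrix rows must have one entry per gene block")
        if len(self.subtype_mixture) != k or len(self.hazard_per_group) != k or len(self.cnv_probs) != k:
            raise ValueError("per-cluster parameter lists must have n_sample_clusters entries")
        for row in self.subtype_mixture:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("subtype mixture rows must sum to 1")
        for row in self.cnv_probs:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("cnv probability rows must sum to 1")
        if any(h <= 0 for h in self.hazard_per_group):
            raise ValueError("hazards must be positive")
        n_genes = sum(self.gene_blocks.values())
        if self.gene_ids is not None and len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal total block gene count")
        if n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least one gene and two samples")


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for recovery tests."""

    model_up: dict[str, list[str]] = field(default_factory=dict)
    model_down: dict[str, list[str]] = field(default_factory=dict)
    core_up: list[str] = field(default_factory=list)
    core_down: list[str] = field(default_factory=list)
    sample_cluster: pd.Series | None = None  # per-sample true cluster (1-based)
    gene_block: pd.Series | None = None  # per-gene true block label


def simulate_models(cfg: ModelSimConfig) -> tuple[dict[str, ExpressionMatrix], PlantedTruth]:
    """Simulate paired epithelial/mesenchymal count libraries for each model.

    Per gene, an expected epithelial CPM is drawn log-normal; for planted
    genes the mesenchymal expectation is multiplied by ``2**(+lfc)`` (up)
    or ``2**(-lfc)`` (down); counts are Poisson at the configured library
    size.  Each model's matrix has exactly one epithelial and one
    mesenchymal column.

    Returns a dict model name -> counts matrix, plus the planted truth.
    The consensus core is, by construction, the intersection of the
    per-model planted sets.
    """
    cfg.validate()
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    models = [f"model{i + 1}" for i in range(cfg.n_models)]

    # gene budget: core first, then disjoint model-specific stretches
    pos = 0
    core_up = genes[pos : pos + cfg.core_up]
    pos += cfg.core_up
    core_down = genes[pos : pos + cfg.core_down]
    pos += cfg.core_down
    spec_up: dict[str, np.ndarray] = {}
    spec_down: dict[str, np.ndarray] = {}
    for m in models:
        spec_up[m] = genes[pos : pos + cfg.model_specific_up]
        pos += cfg.model_specific_up
        spec_down[m] = genes[pos : pos + cfg.model_specific_down]
        pos += cfg.model_specific_down

    gene_index = pd.Index(genes)
    planted_up_mask = np.zeros(cfg.n_genes, dtype=bool)
    planted_down_mask = np.zeros(cfg.n_genes, dtype=bool)
    planted_up_mask[gene_index.get_indexer(core_up)] = True
    planted_down_mask[gene_index.get_indexer(core_down)] = True
    for m in models:
        planted_up_mask[gene_index.get_indexer(spec_up[m])] = True
        planted_down_mask[gene_index.get_indexer(spec_down[m])] = True

    rng_base = stream_rng(cfg.seed, "models.baseline")
    baseline = np.exp(rng_base.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))
    rng_planted = stream_rng(cfg.seed, "models.planted_baseline")
    baseline[planted_up_mask] = np.exp(
        rng_planted.normal(cfg.planted_up_log_mean, cfg.planted_log_sd, planted_up_mask.sum())
    )
    baseline[planted_down_mask] = np.exp(
        rng_planted.normal(cfg.planted_down_log_mean, cfg.planted_log_sd, planted_down_mask.sum())
    )
    truth = PlantedTruth(core_up=list(core_up), core_down=list(core_down))
    matrices: dict[str, ExpressionMatrix] = {}
    for m in models:
        up_set = np.concatenate([core_up, spec_up[m]])
        down_set = np.concatenate([core_down, spec_down[m]])
        truth.model_up[m] = list(up_set)
        truth.model_down[m] = list(down_set)

        rng_lfc = stream_rng(cfg.seed, f"models.{m}.lfc")
        lfc = np.zeros(cfg.n_genes)
        lo, hi = cfg.lfc_range
        lfc[gene_index.get_indexer(up_set)] = rng_lfc.uniform(lo, hi, len(up_set))
        lfc[gene_index.get_indexer(down_set)] = -rng_lfc.uniform(lo, hi, len(down_set))

        epi_expect = baseline
        mes_expect = baseline * np.exp2(lfc)
        rng_counts = stream_rng(cfg.seed, f"models.{m}.counts")
        epi = rng_counts.poisson(epi_expect / 1e6 * cfg.library_size)
        mes = rng_counts.poisson(mes_expect / 1e6 * cfg.library_size)
        df = pd.DataFrame(
            {f"{m}_epithelial": epi, f"{m}_mesenchymal": mes}, index=gene_index, dtype=float
        )
        matrices[m] = ExpressionMatrix(df, "counts")
    return matrices, truth


def simulate_cohort(cfg: CohortSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, PlantedTruth]:
    """Simulate a block-structured expression cohort with clinical annotations.

    Expression (log2 scale) is block mean + Gaussian noise.  Survival
    times are exponential with the cluster's hazard, censored at the
    minimum of the event time and an independent uniform censoring draw.
    CNV categories are multinomial per cluster.
    """
    cfg.validate()
    block_names = list(cfg.gene_blocks)
    block_sizes = [cfg.gene_blocks[b] for b in block_names]
    n_genes = sum(block_sizes)
    genes = cfg.gene_ids if cfg.gene_ids is not None else [f"SG{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    k = cfg.n_sample_clusters

    gene_block = pd.Series(
        np.repeat(block_names, block_sizes), index=pd.Index(genes, name="gene_id"), name="block"
    )
    block_of_gene = np.repeat(np.arange(len(block_names)), block_sizes)

    rng_assign = stream_rng(cfg.seed, "cohort.assign")
    cluster = rng_assign.integers(0, k, cfg.n_samples)  # 0-based internally

    means = np.asarray(cfg.block_mean_matrix)  # (k, n_blocks)
    mu = means[np.ix_(cluster, block_of_gene)].T  # genes x samples
    rng_expr = stream_rng(cfg.seed, "cohort.expression")
    values = mu + rng_expr.normal(0.0, cfg.noise_sd, size=(n_genes, cfg.n_samples))
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2cpm")

    rng_surv = stream_rng(cfg.seed, "cohort.survival")
    hazard = np.asarray(cfg.hazard_per_group)[cluster]
    event_time = rng_surv.exponential(1.0 / hazard)
    censor_time = rng_surv.uniform(0.0, cfg.censor_max_days, cfg.n_samples)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    rng_sub = stream_rng(cfg.seed, "cohort.subtype")
    mixture = np.asarray(cfg.subtype_mixture)
    subtype = np.array(
        [cfg.subtypes[rng_sub.choice(len(cfg.subtypes), p=mixture[c])] for c in cluster]
    )

    rng_cnv = stream_rng(cfg.seed, "cohort.cnv")
    cnv_levels = np.array(["deletion", "normal", "amplification"])
    cnv_probs = np.asarray(cfg.cnv_probs)
    cnv = np.array([cnv_levels[rng_cnv.choice(3, p=cnv_probs[c])] for c in cluster])

    annotation = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": "",
            "cohort": "synthetic",
            "subtype": subtype,
            "time_days": np.round(time, 1),
            "event": event,
            "cnv": cnv,
        }
    ).set_index("sample_id", drop=False)

    truth = PlantedTruth(
        sample_cluster=pd.Series(cluster + 1, index=pd.Index(samples, name="sample_id"), name="cluster"),
        gene_block=gene_block,
    )
    return matrix, annotation, truth


def cohort_config_for_signature(signature_up, signature_down, seed: int, n_samples: int = 1000) -> CohortSimConfig:
    """Cohort config whose gene universe is a given signature.

    Two thirds of the up genes form the EMT-up block and two thirds of
    the down genes the EMT-down block; the remaining thirds mix into the
    partial-EMT block, mirroring the mixed composition such a cluster
    shows in real cohorts.
    """
    up = list(signature_up)
    down = list(signature_down)
    n_up_block = max(1, (2 * len(up)) // 3)
    n_down_block = max(1, (2 * len(down)) // 3)
    partial = up[n_up_block:] + down[:len(down) - n_down_block]
    gene_ids = up[:n_up_block] + partial + down[len(down) - n_down_block:]
    return CohortSimConfig(
        n_samples=n_samples,
        gene_blocks={"EMT-up": n_up_block, "partial-EMT": len(partial), "EMT-down": n_down_block},
        gene_ids=gene_ids,
        seed=seed,
    )


def simulate_signature_db(
    core: list[str],
    k_sets: int,
    overlap_fracs: list[float],
    universe: list[str],
    seed: int,
    set_size: int | None = None,
) -> GeneSetCollection:
    """Build reference gene sets with controlled overlap against ``core``.

    Each generated set of size ``set_size`` (default ``len(core)``) takes
    ``round(frac * set_size)`` genes from the core and the remainder from
    the universe minus the core.  ``overlap_fracs`` is cycled over the
    ``k_sets`` generated sets.
    """
    if any(f < 0 or f > 1 for f in overlap_fracs):
        raise ValueError("overlap fractions must lie in [0, 1]")
    size = set_size if set_size is not None else len(core)
    core_arr = np.array(core)
    background = np.array(sorted(set(universe) - set(core)))
    rng = stream_rng(seed, "signature_db")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(k_sets):
        frac = overlap_fracs[i % len(overlap_fracs)]
        n_core = round(frac * size)
        n_bg = size - n_core
        if n_core > len(core_arr) or n_bg > len(background):
            raise ValueError("universe too small for the requested set size/overlap")
        members = list(rng.choice(core_arr, n_core, replace=False)) + list(
            rng.choice(background, n_bg, replace=False)
        )
        name = f"REF_SIG_{i + 1:03d}"
        sets[name] = members
        descriptions[name] = f"synthetic reference signature, overlap {frac:g}"
    return GeneSetCollection(sets, descriptions)
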