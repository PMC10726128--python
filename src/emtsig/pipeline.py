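"""End-to-end workflows with manifests and reproducibility guarantees.

Two orchestrated workflows mirror the study's structure:

* :func:`run_derivation` — paired model libraries -> per-model DE ->
  consensus signature -> preranked GSEA per model -> overlap report.
* :func:`run_stratification` — signature + cohort matrix + annotations
  -> z-scoring -> stability scan and k selection -> gene/sample
  clustering -> gene-cluster annotation -> composition, survival,
  driver-correlation and CNV reports.

Every run writes a ``manifest.json`` recording the configuration, seed
and a SHA-256 checksum of each artifact; reruns with the same inputs and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clustering, cohort_stats, diffexp, gsea, matrix_io

logger = logging.getLogger(__name__)


class QualityGateError(RuntimeError):
    """Raised when an input fails a pipeline quality gate (exit code 3 in the CLI)."""


@dataclass
class PipelineConfig:
    """Thresholds and knobs for both workflows (defaults = study settings)."""

    fc: float = 2.0
    fdr: float = 0.05
    delta_cpm: float = 5.0
    pseudocount: float = 1.0
    min_set_size: int = 50
    gsea_min_size: int = 15
    gsea_max_size: int = 1000
    n_perm: int = 1000
    rank_p_cut: float = 0.05
    k_min: int = 2
    k_max: int = 10
    neighbors_L: int = 10
    tau_up: float = 0.75
    tau_down: float = 0.25
    horizon_days: float = cohort_stats.FIVE_YEARS_DAYS
    response_threshold: float = 1.0
    min_signature_coverage: float = 0.5
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.fc > 1 and 0 < self.fdr < 1 and self.delta_cpm >= 0):
            raise ValueError("DE thresholds out of range")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("k range out of order")
        if not (0 <= self.tau_down <= self.tau_up <= 1):
            raise ValueError("annotation thresholds out of order")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig, stage: str, artifacts: list[Path], t0: float) -> Path:
    manifest = {
        "stage": stage,
        "emtsig_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "duration_s": round(time.time() - t0, 3),
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
    return path


def run_derivation(
    model_matrices: dict[str, matrix_io.ExpressionMatrix],
    outdir,
    config: PipelineConfig | None = None,
    gsea_collection: matrix_io.GeneSetCollection | None = None,
    reference_db: matrix_io.GeneSetCollection | None = None,
    signature_name: str = "MAMMARY_EMT",
) -> dict:
    """Workflow A: model libraries -> DE -> consensus signature -> GSEA -> overlap.

    Each model matrix must contain exactly one ``*_epithelial`` and one
    ``*_mesenchymal`` column.  ``gsea_collection`` and ``reference_db``
    are optional; the corresponding reports are skipped when absent.
    """
    config = config or PipelineConfig()
    config.validate()
    if len(model_matrices) < 2:
        raise ValueError("consensus derivation needs at least two models")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: list[Path] = []

    de_tables: dict[str, pd.DataFrame] = {}
    for name, m in model_matrices.items():
        epi = [c for c in m.sample_ids if c.endswith("_epithelial")]
        mes = [c for c in m.sample_ids if c.endswith("_mesenchymal")]
        if len(epi) != 1 or len(mes) != 1:
            raise ValueError(
                f"model {name!r} must have exactly one *_epithelial and one *_mesenchymal column"
            )
        table = diffexp.call_de_matrix(
            m, epi[0], mes[0],
            fc=config.fc, fdr=config.fdr, delta_cpm=config.delta_cpm,
            pseudocount=config.pseudocount,
        )
        de_tables[name] = table
        artifacts.append(_write_tsv(table, outdir / f"de_{name}.tsv"))
        logger.info("model %s: %d up, %d down", name,
                    (table["direction"] == "up").sum(), (table["direction"] == "down").sum())

    signature, conflicting = diffexp.consensus_signature(de_tables)
    sig_path = outdir / "signature.gmt"
    matrix_io.write_gmt(signature.to_collection(signature_name), sig_path)
    artifacts.append(sig_path)
    conflict_path = outdir / "conflicting_genes.tsv"
    _write_tsv(pd.DataFrame({"gene_id": conflicting}), conflict_path, index=False)
    artifacts.append(conflict_path)

    gsea_tables = {}
    if gsea_collection is not None:
        for name, table in de_tables.items():
            ranking = gsea.build_ranking(table, p_cut=config.rank_p_cut)
            result, excluded = gsea.run_collection(
                ranking, gsea_collection,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                n_perm=config.n_perm, seed=config.seed,
            )
            gsea_tables[name] = result
            artifacts.append(_write_tsv(result, outdir / f"gsea_{name}.tsv", index=False))
            if len(excluded):
                artifacts.append(
                    _write_tsv(excluded, outdir / f"gsea_{name}_excluded.tsv", index=False)
                )

    overlap = None
    if reference_db is not None:
        overlap = diffexp.overlap_analysis(signature, reference_db, min_size=config.min_set_size)
        artifacts.append(_write_tsv(overlap["per_set"], outdir / "overlap_per_set.tsv", index=False))
        artifacts.append(_write_tsv(overlap["gene_frequency"].to_frame(), outdir / "overlap_gene_frequency.tsv"))

    manifest = _write_manifest(outdir, config, "derivation", artifacts, t0)
    return {
        "de_tables": de_tables,
        "signature": signature,
        "conflicting": conflicting,
        "gsea": gsea_tables,
        "overlap": overlap,
        "manifest": manifest,
        "artifacts": artifacts,
    }


def run_stratification(
    signature: diffexp.SignatureSet,
    cohort: matrix_io.ExpressionMatrix,
    annotation: pd.DataFrame,
    outdir,
    config: PipelineConfig | None = None,
    driver_genes: tuple[str, ...] = (),
    k_override: int | None = None,
) -> dict:
    """Workflow B: signature + cohort -> stratification -> downstream reports.

    Aborts (QualityGateError) when less than ``min_signature_coverage``
    of the signature genes are present in the cohort matrix.  The sample
    axis is cut at the recommended k (or ``k_override``); the gene axis
    is cut at 3 clusters for EMT-up / partial-EMT / EMT-down annotation.
    """
    config = config or PipelineConfig()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: list[Path] = []

    sub, dropped = matrix_io.restrict_to_genes(cohort, signature.genes)
    coverage = len(sub.gene_ids) / len(signature.genes)
    if coverage < config.min_signature_coverage:
        raise QualityGateError(
            f"only {coverage:.0%} of signature genes found in cohort "
            f"(gate: {config.min_signature_coverage:.0%})"
        )
    logger.info("stratification: %d/%d signature genes in cohort", len(sub.gene_ids), len(signature.genes))

    if sub.scale == "counts":
        sub = matrix_io.log2_plus1(matrix_io.to_cpm(sub))
    zm, constant = matrix_io.row_zscore(sub)
    if constant:
        keep = [g for g in zm.gene_ids if g not in set(constant)]
        zm = matrix_io.ExpressionMatrix(zm.data.loc[keep], "zscore")

    k_range = range(config.k_min, config.k_max + 1)
    profile, sample_outcome = clustering.stability_scan(
        zm, axis="sample", k_range=k_range, L=config.neighbors_L
    )
    recommended_k, ranks, tie = clustering.select_k(profile)
    chosen_k = k_override or recommended_k
    artifacts.append(_write_tsv(profile.join(ranks, rsuffix="_rank"), outdir / "stability_profile.tsv"))

    sample_labels = sample_outcome.labels(chosen_k)
    artifacts.append(_write_tsv(sample_labels.to_frame(), outdir / "sample_clusters.tsv"))

    gene_d = clustering.correlation_distance(zm, axis="gene")
    gene_outcome = clustering.hcluster(gene_d, k_values=[3], axis="gene")
    gene_labels = gene_outcome.labels(3)
    annotation_table = clustering.annotate_gene_clusters(
        gene_labels, signature, tau_up=config.tau_up, tau_down=config.tau_down
    )
    artifacts.append(_write_tsv(gene_labels.to_frame(), outdir / "gene_clusters.tsv"))
    artifacts.append(_write_tsv(annotation_table, outdir / "gene_cluster_annotation.tsv"))

    results: dict = {
        "profile": profile,
        "ranks": ranks,
        "recommended_k": recommended_k,
        "chosen_k": chosen_k,
        "tie": tie,
        "sample_labels": sample_labels,
        "gene_labels": gene_labels,
        "gene_annotation": annotation_table,
        "dropped_genes": dropped,
        "coverage": coverage,
    }

    ann = annotation.reindex(sample_labels.index)
    if "subtype" in ann.columns and ann["subtype"].notna().all():
        comp = clustering.composition_table(sample_labels, ann["subtype"])
        for key, frame in comp.items():
            artifacts.append(_write_tsv(frame, outdir / f"composition_{key}.tsv"))
        results["composition"] = comp

    if {"time_days", "event"} <= set(ann.columns) and ann["time_days"].notna().all():
        groups = {
            str(c): (grp["time_days"].to_numpy(), grp["event"].to_numpy())
            for c, grp in ann.groupby(sample_labels)
        }
        curves = pd.concat(
            [
                cohort_stats.km_estimate(t, e, config.horizon_days, label=name)
                for name, (t, e) in groups.items()
            ]
        )
        artifacts.append(_write_tsv(curves, outdir / "km_curves.tsv"))
        lr = cohort_stats.logrank(groups, config.horizon_days)
        results["km_curves"] = curves
        results["logrank"] = lr
        artifacts.append(
            _write_tsv(pd.DataFrame([lr]), outdir / "logrank.tsv", index=False)
        )

    gene_cluster_of = annotation_table["label"].reindex(gene_labels.to_numpy())
    labeled_genes = pd.Series(gene_cluster_of.to_numpy(), index=gene_labels.index, name="cluster")
    correlations = {}
    for driver in driver_genes:
        if driver not in cohort.data.index:
            logger.info("driver %s absent from cohort; skipped", driver)
            continue
        corr = cohort_stats.driver_correlation(
            matrix_io.ExpressionMatrix(cohort.data, cohort.scale), driver, labeled_genes
        )
        correlations[driver] = corr
        artifacts.append(_write_tsv(corr["per_gene"], outdir / f"correlation_{driver}.tsv"))
    results["correlations"] = correlations

    if "cnv" in ann.columns and ann["cnv"].notna().all():
        cnv = cohort_stats.cnv_summary(ann["cnv"], sample_labels)
        artifacts.append(_write_tsv(cnv, outdir / "cnv_summary.tsv"))
        results["cnv"] = cnv

    results["manifest"] = _write_manifest(outdir, config, "stratification", artifacts, t0)
    results["artifacts"] = artifacts
    return results


def checksum_artifacts(paths) -> dict[str, str]:
    """SHA-256 of each artifact file, keyed by file name (determinism checks)."""
    return {Path(p).name: _sha256(Path(p)) for p in paths}
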