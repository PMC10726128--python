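"""Hierarchical co-clustering with stability-validated cluster counts.

Both axes (signature genes and cohort samples) are clustered with
correlation distance (1 - Pearson r) and complete linkage on the
z-scored matrix.  The number of clusters is chosen by scanning k = 2..10
and ranking three stability indices: connectivity (lower is better),
Dunn index and mean silhouette width (higher is better).  Gene clusters
are annotated EMT-up / partial-EMT / EMT-down from the fraction of
consensus-upregulated signature genes they contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .diffexp import SignatureSet
from .matrix_io import ExpressionMatrix


@dataclass
class ClusteringOutcome:
    """Dendrogram plus k-cut labels for one axis."""

    axis: str  # "gene" or "sample"
    item_ids: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels_at_k: dict[int, np.ndarray]
    distance: str
    linkage_method: str

    def labels(self, k: int) -> pd.Series:
        return pd.Series(self.labels_at_k[k], index=self.item_ids, name=f"cluster_k{k}")


def _axis_values(m: ExpressionMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "gene":
        return m.data.to_numpy(dtype=float), m.gene_ids
    if axis == "sample":
        return m.data.to_numpy(dtype=float).T, m.sample_ids
    raise ValueError(f"axis must be 'gene' or 'sample', got {axis!r}")


def correlation_distance(m: ExpressionMatrix, axis: str = "sample") -> pd.DataFrame:
    """Pairwise 1 - Pearson r over the requested axis; values in [0, 2]."""
    values, ids = _axis_values(m, axis)
    if len(ids) < 3:
        raise ValueError("need at least 3 items for a distance matrix")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant item {bad!r}: correlation undefined")
    d = 1.0 - np.corrcoef(values)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away rounding noise
    return pd.DataFrame(d, index=ids, columns=ids)


def hcluster(
    d: pd.DataFrame, linkage_method: str = "complete", k_values=range(2, 11), axis: str = "sample"
) -> ClusteringOutcome:
    """Agglomerative clustering of a distance matrix; cut at each requested k."""
    dm = d.to_numpy(dtype=float)
    if np.isnan(dm).any():
        raise ValueError("distance matrix contains NaN")
    z = linkage(squareform(dm, checks=False), method=linkage_method)
    n = dm.shape[0]
    labels_at_k = {}
    for k in k_values:
        if k > n:
            continue
        labels_at_k[int(k)] = fcluster(z, t=k, criterion="maxclust")
    return ClusteringOutcome(
        axis=axis,
        item_ids=list(d.index),
        merge_tree=z,
        labels_at_k=labels_at_k,
        distance="precomputed",
        linkage_method=linkage_method,
    )


def connectivity_index(d: np.ndarray, labels: np.ndarray, L: int = 10) -> float:
    """Connectivity stability index: sum over items of 1/j for each of the
    L nearest neighbors (rank j) assigned to a different cluster.  Lower
    is better; 0 means every item's L nearest neighbors share its cluster.
    """
    n = d.shape[0]
    L = min(L, n - 1)
    # stable argsort so distance ties resolve by index, deterministically
    order = np.argsort(d + np.eye(n) * (d.max() + 1.0), axis=1, kind="stable")
    total = 0.0
    for i in range(n):
        for j in range(L):
            if labels[order[i, j]] != labels[i]:
                total += 1.0 / (j + 1)
    return total


def dunn_index(d: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min between-cluster distance / max within-cluster diameter.

    Singleton clusters have diameter 0 and contribute nothing to the
    denominator; if every cluster is a singleton the index is infinite.
    """
    uniq = np.unique(labels)
    min_inter = np.inf
    max_intra = 0.0
    for a in uniq:
        ia = np.flatnonzero(labels == a)
        if len(ia) > 1:
            max_intra = max(max_intra, float(d[np.ix_(ia, ia)].max()))
        for b in uniq:
            if b <= a:
                continue
            ib = np.flatnonzero(labels == b)
            min_inter = min(min_inter, float(d[np.ix_(ia, ib)].min()))
    if max_intra == 0.0:
        return float("inf")
    return min_inter / max_intra


def silhouette_width(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed distance matrix (singletons get 0)."""
    return float(silhouette_samples(d, labels, metric="precomputed").mean())


def stability_scan(
    m: ExpressionMatrix,
    axis: str = "sample",
    k_range=range(2, 11),
    L: int = 10,
    linkage_method: str = "complete",
    distance: str = "correlation",
) -> tuple[pd.DataFrame, ClusteringOutcome]:
    """Scan k over ``k_range`` and report the three stability indices per k.

    Returns the profile (index k, columns connectivity/dunn/silhouette)
    together with the clustering outcome so the chosen cut can be reused
    without re-clustering.
    """
    if distance == "correlation":
        dmat = correlation_distance(m, axis)
    elif distance == "euclidean":
        values, ids = _axis_values(m, axis)
        from scipy.spatial.distance import pdist

        dmat = pd.DataFrame(squareform(pdist(values)), index=ids, columns=ids)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    n = dmat.shape[0]
    if n <= max(k_range):
        raise ValueError(f"{n} items cannot support k up to {max(k_range)}")
    outcome = hcluster(dmat, linkage_method, k_values=k_range, axis=axis)
    d = dmat.to_numpy()
    rows = []
    for k in k_range:
        labels = outcome.labels_at_k[int(k)]
        rows.append(
            {
                "k": int(k),
                "connectivity": connectivity_index(d, labels, L),
                "dunn": dunn_index(d, labels),
                "silhouette": silhouette_width(d, labels),
            }
        )
    profile = pd.DataFrame(rows).set_index("k")
    return profile, outcome


def select_k(profile: pd.DataFrame) -> tuple[int, pd.DataFrame, bool]:
    """Recommend the k with the best mean rank over the three indices.

    Connectivity is ranked ascending; Dunn and silhouette descending.
    Ties in mean rank go to the smaller k and are flagged.  The full
    rank table is returned so a human can overrule the recommendation.
    """
    ranks = pd.DataFrame(index=profile.index)
    ranks["connectivity"] = profile["connectivity"].rank(method="average")
    ranks["dunn"] = profile["dunn"].rank(method="average", ascending=False)
    ranks["silhouette"] = profile["silhouette"].rank(method="average", ascending=False)
    ranks["mean_rank"] = ranks.mean(axis=1)
    best = ranks["mean_rank"].min()
    winners = ranks.index[ranks["mean_rank"] == best]
    tie = len(winners) > 1
    return int(winners.min()), ranks, tie


def annotate_gene_clusters(
    labels: pd.Series, sig: SignatureSet, tau_up: float = 0.75, tau_down: float = 0.25
) -> pd.DataFrame:
    """Label gene clusters EMT-up / partial-EMT / EMT-down by up-gene fraction.

    ``frac_up`` is the fraction of a cluster's signature genes that come
    from the consensus up list.  Label is EMT-up iff frac_up >= tau_up,
    EMT-down iff frac_up <= tau_down, else partial-EMT.  The fractions
    are always reported alongside the labels.
    """
    up = set(sig.up)
    down = set(sig.down)
    unknown = [g for g in labels.index if g not in up and g not in down]
    if unknown:
        raise ValueError(f"gene {unknown[0]!r} is not in the signature")
    rows = []
    for cluster, genes in labels.groupby(labels).groups.items():
        n_up = sum(g in up for g in genes)
        frac_up = n_up / len(genes)
        if frac_up >= tau_up:
            label = "EMT-up"
        elif frac_up <= tau_down:
            label = "EMT-down"
        else:
            label = "partial-EMT"
        rows.append(
            {
                "cluster": cluster,
                "n_genes": len(genes),
                "n_up": n_up,
                "frac_up": frac_up,
                "label": label,
                "tau_up": tau_up,
                "tau_down": tau_down,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def composition_table(sample_labels: pd.Series, subtype: pd.Series) -> dict[str, pd.DataFrame]:
    """Cluster-by-subtype contingency counts with row and column percentages."""
    aligned = subtype.reindex(sample_labels.index)
    if aligned.isna().any():
        missing = aligned.index[aligned.isna()][0]
        raise ValueError(f"sample {missing!r} has no subtype label")
    counts = pd.crosstab(sample_labels, aligned)
    counts.index.name = "cluster"
    counts.columns.name = "subtype"
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return {"counts": counts, "row_pct": row_pct, "col_pct": col_pct}
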