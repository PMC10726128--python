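"""Per-model differential expression, consensus signature, and overlap scoring.

The study design has exactly one library per cell state per model, so no
replicate-aware dispersion model is identifiable.  Differential calls
therefore use the two-library proportion z-test on read counts (the
standard replicate-free test on count proportions), followed by
Benjamini-Hochberg FDR control and a triple filter: fold change > 2
(|log2 FC| > 1 with a 1-CPM pseudocount), FDR < 0.05, and |CPM
difference| > 5.  The consensus signature is the per-direction
intersection across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import ExpressionMatrix, GeneSetCollection

DE_COLUMNS = (
    "cpm_epithelial",
    "cpm_mesenchymal",
    "log2_fold_change",
    "delta_cpm",
    "p_value",
    "fdr",
    "direction",
)


@dataclass
class SignatureSet:
    """Disjoint up/down gene lists forming a consensus signature."""

    up: list[str]
    down: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            clash = sorted(set(self.up) & set(self.down))[0]
            raise ValueError(f"gene {clash!r} is in both up and down lists")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def to_collection(self, name: str = "SIGNATURE") -> GeneSetCollection:
        return GeneSetCollection(
            {f"{name}_UP": list(self.up), f"{name}_DOWN": list(self.down)},
            {f"{name}_UP": "consensus upregulated", f"{name}_DOWN": "consensus downregulated"},
        )

    @classmethod
    def from_collection(cls, coll: GeneSetCollection) -> "SignatureSet":
        up_names = [n for n in coll.sets if n.endswith("_UP")]
        down_names = [n for n in coll.sets if n.endswith("_DOWN")]
        if len(up_names) != 1 or len(down_names) != 1:
            raise ValueError("signature GMT must contain exactly one *_UP and one *_DOWN set")
        return cls(up=list(coll[up_names[0]]), down=list(coll[down_names[0]]))


def proportion_test(x1, x2, n1, n2):
    """Two-library proportion z-test on counts; returns (z, two-sided p).

    z = (x1/n1 - x2/n2) / sqrt(p0 (1-p0) (1/n1 + 1/n2)) with pooled
    p0 = (x1+x2)/(n1+n2).  Degenerate inputs (both counts zero, or pooled
    proportion 1 with equal rates) give z = 0, p = 1: no evidence.
    Accepts scalars or aligned arrays.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = float(n1)
    n2 = float(n2)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if (x1 < 0).any() or (x2 < 0).any() or (x1 > n1).any() or (x2 > n2).any():
        raise ValueError("counts must satisfy 0 <= x <= n")
    p0 = (x1 + x2) / (n1 + n2)
    var = p0 * (1.0 - p0) * (1.0 / n1 + 1.0 / n2)
    diff = x1 / n1 - x2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, diff / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values;
    monotone non-decreasing after sorting and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_de(
    epi: pd.Series,
    mes: pd.Series,
    fc: float = 2.0,
    fdr: float = 0.05,
    delta_cpm: float = 5.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential-expression table for one model (mesenchymal vs epithelial).

    ``epi`` and ``mes`` are raw count columns over the same gene index.
    The signed log2 fold change is computed on CPM with a pseudocount:
    log2((cpm_mes + c)/(cpm_epi + c)).  A gene is called ``up`` iff
    log2FC > log2(fc), FDR < ``fdr`` and delta CPM > ``delta_cpm``;
    symmetric for ``down``; otherwise ``none``.
    """
    if not epi.index.equals(mes.index):
        raise ValueError("epithelial and mesenchymal columns have mismatched gene lists")
    n_epi = float(epi.sum())
    n_mes = float(mes.sum())
    if n_epi <= 0 or n_mes <= 0:
        raise ValueError("library totals must be positive")
    cpm_epi = epi.to_numpy(dtype=float) / n_epi * 1e6
    cpm_mes = mes.to_numpy(dtype=float) / n_mes * 1e6
    lfc = np.log2((cpm_mes + pseudocount) / (cpm_epi + pseudocount))
    delta = cpm_mes - cpm_epi
    _, p = proportion_test(mes.to_numpy(), epi.to_numpy(), n_mes, n_epi)
    q = bh_adjust(p)
    lfc_cut = np.log2(fc)
    up = (lfc > lfc_cut) & (q < fdr) & (delta > delta_cpm)
    down = (lfc < -lfc_cut) & (q < fdr) & (delta < -delta_cpm)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {
            "cpm_epithelial": cpm_epi,
            "cpm_mesenchymal": cpm_mes,
            "log2_fold_change": lfc,
            "delta_cpm": delta,
            "p_value": p,
            "fdr": q,
            "direction": direction,
        },
        index=epi.index.rename("gene_id"),
    )


def call_de_matrix(m: ExpressionMatrix, epi_col: str, mes_col: str, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: run :func:`call_de` on two columns of a counts matrix."""
    if m.scale != "counts":
        raise ValueError("differential calling runs on raw counts")
    return call_de(m.data[epi_col], m.data[mes_col], **kwargs)


def consensus_signature(per_model: dict[str, pd.DataFrame]) -> tuple[SignatureSet, list[str]]:
    """Intersect per-model DE calls into the consensus signature.

    ``up`` is the set of genes called up in every model, ``down``
    likewise.  Genes significant in every model but with inconsistent
    directions are excluded and returned as the second element.
    """
    if len(per_model) < 2:
        raise ValueError("consensus needs at least two models")
    ups = []
    downs = []
    called = []
    for name, table in per_model.items():
        d = table["direction"]
        ups.append(set(table.index[d == "up"]))
        downs.append(set(table.index[d == "down"]))
        called.append(set(table.index[d != "none"]))
    up = set.intersection(*ups)
    down = set.intersection(*downs)
    everywhere_called = set.intersection(*called)
    conflicting = sorted(everywhere_called - up - down)
    models = list(per_model)
    provenance = {g: models for g in sorted(up | down)}
    return SignatureSet(up=sorted(up), down=sorted(down), provenance=provenance), conflicting


def overlap_analysis(
    query: SignatureSet, refs: GeneSetCollection, min_size: int = 50
) -> dict:
    """Score the query signature against a reference collection.

    Reference sets with fewer than ``min_size`` genes are disregarded.
    The overlap fraction for a retained set B is ``|Q & B| / |Q|`` where
    Q is the union of the query's up and down lists (query-normalized
    convention).  Also tallies, per query gene, how many retained
    references contain it.
    """
    q = set(query.genes)
    if not q:
        raise ValueError("query signature is empty")
    rows = []
    gene_freq = {g: 0 for g in sorted(q)}
    for name, members in refs.items():
        if len(members) < min_size:
            continue
        inter = q & set(members)
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": len(inter),
                "fraction": len(inter) / len(q),
            }
        )
        for g in inter:
            gene_freq[g] += 1
    per_set = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "fraction"])
    mean_fraction = float(per_set["fraction"].mean()) if len(per_set) else float("nan")
    freq = pd.Series(gene_freq, name="n_references").rename_axis("gene_id")
    return {
        "per_set": per_set,
        "mean_fraction": mean_fraction,
        "gene_frequency": freq,
        "n_retained": len(per_set),
        "n_disregarded": len(refs) - len(per_set),
    }
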