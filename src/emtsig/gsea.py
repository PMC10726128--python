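"""Preranked gene-set enrichment: running-sum ES, permutation NES/p/FDR.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranking, hits add |score|^w normalized by the sum
over hits, misses subtract 1/(N - m); the ES is the signed extremum of
the running sum.  The null model is gene-label permutation (random
same-size gene sets drawn from the ranked universe): with one library
per phenotype per model, phenotype permutation is degenerate, so the
gene-permutation null is used throughout.  NES, nominal p and FDR q
follow the sign-stratified conventions of the original method.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .matrix_io import GeneSetCollection


@dataclass
class RankedList:
    """Genes ordered by descending score, ties broken by gene id."""

    genes: np.ndarray  # ordered gene ids
    scores: np.ndarray  # scores aligned with genes, descending

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.genes.shape != self.scores.shape:
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids in a ranking must be unique")
        if (np.diff(self.scores) > 0).any():
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, genes, scores) -> "RankedList":
        genes = np.asarray(genes)
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((genes, -scores))
        return cls(genes[order], scores[order])


def build_ranking(de: pd.DataFrame, p_cut: float = 0.05) -> RankedList:
    """Rank significant genes (raw p < ``p_cut``) by descending log2 fold change."""
    keep = de[de["p_value"] < p_cut]
    if keep.empty:
        raise ValueError(f"no gene passes p < {p_cut}")
    return RankedList.from_scores(keep.index.to_numpy(), keep["log2_fold_change"].to_numpy())


def _hit_mask(r: RankedList, gene_set) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in r.genes), dtype=bool, count=len(r))


def running_sum(r: RankedList, hits: np.ndarray, weight_p: float = 1.0) -> np.ndarray:
    """Running P_hit - P_miss along the ranking for a boolean hit mask."""
    n = len(r)
    m = int(hits.sum())
    if m == 0:
        raise ValueError("gene set has no member in the ranked universe")
    if m == n:
        raise ValueError("gene set covers the whole ranking; P_miss undefined")
    w = np.abs(r.scores) ** weight_p
    nr = w[hits].sum()
    if nr == 0:
        raise ValueError("all hit scores are zero; weighted running sum undefined")
    step = np.where(hits, w / nr, -1.0 / (n - m))
    return np.cumsum(step)


def enrichment_score(
    r: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list]:
    """Enrichment score, running sum, and leading edge for one gene set.

    The ES is the running-sum value of maximum absolute magnitude (the
    positive extremum wins an exact tie).  The leading edge is the hit
    genes at or before the extremum for positive ES, and at or after it
    for negative ES.
    """
    hits = _hit_mask(r, gene_set)
    rs = running_sum(r, hits, weight_p)
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    if rs[i_max] >= -rs[i_min]:
        es = float(rs[i_max])
        leading = list(r.genes[: i_max + 1][hits[: i_max + 1]])
    else:
        es = float(rs[i_min])
        leading = list(r.genes[i_min:][hits[i_min:]])
    return es, rs, leading


def _null_es(r: RankedList, m: int, n_perm: int, seed: int, weight_p: float) -> np.ndarray:
    """Null ES from ``n_perm`` random size-``m`` gene sets (gene-label permutation)."""
    n = len(r)
    rng = stream_rng(seed, "gsea.permutation")
    w = np.abs(r.scores) ** weight_p
    out = np.empty(n_perm)
    miss_step = -1.0 / (n - m)
    for b in range(n_perm):
        idx = rng.choice(n, m, replace=False)
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        nr = w[hits].sum()
        if nr == 0:  # pathological all-zero draw; classic KS fallback
            step = np.where(hits, 1.0 / m, miss_step)
        else:
            step = np.where(hits, w / nr, miss_step)
        rs = np.cumsum(step)
        hi, lo = rs.max(), rs.min()
        out[b] = hi if hi >= -lo else lo
    return out


def _nes_and_p(es: float, null: np.ndarray) -> tuple[float, float, bool]:
    """Sign-stratified NES and nominal p against a null ES sample."""
    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    flagged = len(same_sign) == 0
    if flagged:
        return float("nan"), 1.0 / len(null), True
    denom = np.abs(same_sign).mean()
    nes = es / denom if denom > 0 else float("nan")
    p = float((np.abs(same_sign) >= abs(es)).sum() / len(same_sign))
    return float(nes), p, False


def permutation_null(
    r: RankedList, gene_set, n_perm: int = 1000, seed: int = 0, weight_p: float = 1.0
) -> dict:
    """Permutation null for one gene set: NES, nominal p, and the null sample.

    Deterministic for a fixed seed.  If no null ES shares the observed
    sign, p is reported as 1/n_perm with ``flagged`` set.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    hits = _hit_mask(r, gene_set)
    es, _, leading = enrichment_score(r, gene_set, weight_p)
    null = _null_es(r, int(hits.sum()), n_perm, seed, weight_p)
    nes, p, flagged = _nes_and_p(es, null)
    null_nes = _normalize_null(null)
    return {
        "es": es,
        "nes": nes,
        "p_nominal": p,
        "leading_edge": leading,
        "null_es": null,
        "null_nes": null_nes,
        "flagged": flagged,
    }


def _normalize_null(null: np.ndarray) -> np.ndarray:
    """Normalize a null ES sample by the sign-stratified mean magnitudes."""
    pos = null[null >= 0]
    neg = null[null < 0]
    out = null.astype(float).copy()
    if len(pos):
        mp = np.abs(pos).mean()
        if mp > 0:
            out[null >= 0] = pos / mp
    if len(neg):
        mn = np.abs(neg).mean()
        if mn > 0:
            out[null < 0] = neg / mn
    return out


def _fdr_q(observed_nes: np.ndarray, pooled_null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified FDR q over a family of tested sets.

    For a set with NES* >= 0, q = [frac of pooled null NES >= NES*] /
    [frac of observed NES >= NES*], clipped to [0, 1]; mirrored for
    negative NES*.  Monotone within each sign (a more extreme NES never
    gets a larger q).
    """
    q = np.full(len(observed_nes), np.nan)
    for sign in (1, -1):
        sel = observed_nes >= 0 if sign == 1 else observed_nes < 0
        if not sel.any():
            continue
        null_side = pooled_null_nes[pooled_null_nes >= 0] if sign == 1 else pooled_null_nes[pooled_null_nes < 0]
        obs_side = observed_nes[sel]
        for i in np.flatnonzero(sel):
            v = observed_nes[i]
            if np.isnan(v):
                continue
            if len(null_side) == 0:
                q[i] = 0.0
                continue
            null_frac = (null_side >= v).mean() if sign == 1 else (null_side <= v).mean()
            obs_frac = (obs_side >= v).mean() if sign == 1 else (obs_side <= v).mean()
            q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        # enforce monotonicity: a more extreme NES never gets a larger q
        idx = np.flatnonzero(sel & ~np.isnan(observed_nes) & ~np.isnan(q))
        order = idx[np.argsort(-np.abs(observed_nes[idx]))]
        best = np.inf
        for j in order:
            best = min(best, q[j])
            q[j] = best
    return q


def run_collection(
    r: RankedList,
    collection: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every admissible set in a collection; sort by NES.

    Sets whose intersection with the ranked universe falls outside
    [min_size, max_size] are excluded and reported in the second frame.
    Per-set permutation streams are derived from the seed and the set
    name, so results do not depend on iteration order.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(r.genes)
    rows = []
    excluded = []
    pooled_null = []
    for name, members in collection.items():
        restricted = [g for g in members if g in universe]
        if not min_size <= len(restricted) <= max_size:
            reason = "empty in universe" if not restricted else (
                f"size {len(restricted)} outside [{min_size}, {max_size}]"
            )
            excluded.append({"set": name, "size": len(restricted), "reason": reason})
            continue
        set_seed = (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)
        res = permutation_null(r, restricted, n_perm=n_perm, seed=set_seed, weight_p=weight_p)
        pooled_null.append(res["null_nes"])
        rows.append(
            {
                "set": name,
                "size": len(restricted),
                "es": res["es"],
                "nes": res["nes"],
                "p_nominal": res["p_nominal"],
                "leading_edge": ",".join(map(str, res["leading_edge"])),
                "flagged": res["flagged"],
            }
        )
    if not rows:
        raise ValueError("all gene sets were excluded")
    table = pd.DataFrame(rows)
    table["fdr_q"] = _fdr_q(table["nes"].to_numpy(), np.concatenate(pooled_null))
    table = table.sort_values("nes", ascending=False, kind="stable").reset_index(drop=True)
    table["n_permutations"] = n_perm
    table["seed"] = seed
    excluded_df = pd.DataFrame(excluded, columns=["set", "size", "reason"])
    return table, excluded_df


def read_rnk(path) -> RankedList:
    """Read a two-column (gene, score) RNK-style TSV into a RankedList."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    return RankedList.from_scores(df["gene"].astype(str).to_numpy(), df["score"].to_numpy())
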