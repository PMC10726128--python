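"""Downstream cohort statistics: survival, driver correlation, CNV, response.

Kaplan-Meier estimation and the log-rank test are delegated to
lifelines; the module adds the conventions the pipeline needs —
administrative censoring at a display horizon (five years = 1826 days by
default), degenerate-input handling, and fixed output schemas.  Driver
correlation (Pearson r of an EMT transcription factor against every
signature gene, compared across gene clusters with Kruskal-Wallis) and
signature-response scoring for perturbation data are implemented here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .clustering import ClusteringOutcome  # noqa: F401  (re-export convenience)
from .diffexp import SignatureSet
from .matrix_io import ExpressionMatrix, restrict_to_genes

logger = logging.getLogger(__name__)

FIVE_YEARS_DAYS = 1826.0

_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_code(p: float) -> str:
    """Map a p-value to the conventional significance stars ('ns' if >= 0.05)."""
    for cut, stars in _STARS:
        if p < cut:
            return stars
    return "ns"


def _truncate(times, events, horizon):
    """Administratively censor observations beyond the horizon (not exclude)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if horizon is not None:
        over = t > horizon
        t = np.where(over, horizon, t)
        e = np.where(over, 0, e)
    return t, e


def km_estimate(times, events, horizon_days: float | None = FIVE_YEARS_DAYS, label: str = "") -> pd.DataFrame:
    """Kaplan-Meier survival curve as a step-function table.

    Returns a DataFrame indexed by time with columns ``survival``,
    ``at_risk``, ``events``, ``censored`` and the group ``label``.
    Observations past ``horizon_days`` are censored at the horizon.
    """
    t, e = _truncate(times, events, horizon_days)
    if len(t) == 0:
        raise ValueError("empty group")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=label or "group")
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": table["at_risk"].to_numpy(),
            "events": table["observed"].to_numpy(),
            "censored": table["censored"].to_numpy(),
        },
        index=table.index.rename("time_days"),
    )
    out["group"] = label
    return out


def logrank(groups: dict[str, tuple], horizon_days: float | None = FIVE_YEARS_DAYS) -> dict:
    """Log-rank comparison of >= 2 groups of (times, events).

    Returns chi-square statistic, degrees of freedom and p.  If no event
    occurs in any group the comparison is vacuous: p = 1 with a flag.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    all_t, all_e, all_g = [], [], []
    for name, (times, events) in groups.items():
        t, e = _truncate(times, events, horizon_days)
        if len(t) == 0:
            raise ValueError(f"group {name!r} is empty")
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.repeat(name, len(t)))
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    g = np.concatenate(all_g)
    df = len(groups) - 1
    if e.sum() == 0:
        logger.info("logrank: no events in any group; p = 1 by convention")
        return {"statistic": 0.0, "df": df, "p": 1.0, "flagged": True}
    res = multivariate_logrank_test(t, g, e)
    return {"statistic": float(res.test_statistic), "df": df, "p": float(res.p_value), "flagged": False}


def driver_correlation(
    m: ExpressionMatrix, driver: str, gene_cluster_labels: pd.Series
) -> dict:
    """Correlate a driver gene with every labeled signature gene; test clusters.

    Pearson r of the driver's expression against each signature gene
    across samples, then a Kruskal-Wallis test of the r values grouped
    by gene-cluster label.  The driver itself is excluded from its own
    group (flagged), since its self-correlation of 1 is uninformative.
    """
    if driver not in m.data.index:
        raise ValueError(f"driver gene {driver!r} not in matrix")
    d = m.data.loc[driver].to_numpy(dtype=float)
    if d.std() == 0:
        raise ValueError(f"driver gene {driver!r} is constant across samples")
    genes = [g for g in gene_cluster_labels.index if g in m.data.index]
    dropped = [g for g in gene_cluster_labels.index if g not in m.data.index]
    values = m.data.loc[genes].to_numpy(dtype=float)
    sd = values.std(axis=1)
    dc = d - d.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (values - values.mean(axis=1, keepdims=True)) @ dc / (
            np.sqrt((dc**2).sum()) * sd * np.sqrt(values.shape[1])
        )
    table = pd.DataFrame(
        {"r": r, "cluster": gene_cluster_labels.reindex(genes).to_numpy()},
        index=pd.Index(genes, name="gene_id"),
    )
    driver_excluded = driver in table.index
    test_table = table.drop(index=driver) if driver_excluded else table
    test_table = test_table.dropna(subset=["r"])
    groups = [grp["r"].to_numpy() for _, grp in test_table.groupby("cluster")]
    if len(groups) >= 2:
        h, p = stats.kruskal(*groups)
    else:
        h, p = float("nan"), float("nan")
    return {
        "per_gene": table,
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "driver_excluded": driver_excluded,
        "dropped_genes": dropped,
    }


def group_expression_test(values_a, values_b, method: str = "mannwhitney") -> dict:
    """Two-group expression comparison with significance stars.

    Default is the two-sided Mann-Whitney U test (normal approximation
    with tie correction), robust for skewed expression; a Welch t-test
    is available behind the ``method`` flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if method == "mannwhitney":
        if np.array_equal(np.sort(a), np.sort(b)):
            stat, p = float(len(a) * len(b) / 2.0), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
    elif method == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": stat, "p": min(p, 1.0), "stars": star_code(min(p, 1.0))}


def cnv_summary(categories: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group deletion/normal/amplification counts and percentages.

    Accepts either thresholded integer calls in {-2, -1, 0, 1, 2}
    (negative -> deletion, 0 -> normal, positive -> amplification) or
    already-categorical strings.
    """
    cats = categories.reindex(groups.index)
    if cats.isna().any():
        raise ValueError("every sample in groups needs a CNV value")
    if pd.api.types.is_numeric_dtype(cats):
        vals = cats.astype(float)
        if not vals.isin([-2.0, -1.0, 0.0, 1.0, 2.0]).all():
            bad = vals[~vals.isin([-2.0, -1.0, 0.0, 1.0, 2.0])].iloc[0]
            raise ValueError(f"thresholded CNV value out of range: {bad}")
        cats = pd.Series(
            np.where(vals < 0, "deletion", np.where(vals > 0, "amplification", "normal")),
            index=cats.index,
        )
    else:
        allowed = {"deletion", "normal", "amplification"}
        bad = set(cats.unique()) - allowed
        if bad:
            raise ValueError(f"unknown CNV category {sorted(bad)[0]!r}")
    counts = pd.crosstab(groups, cats)
    for col in ("deletion", "normal", "amplification"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["deletion", "normal", "amplification"]]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    out = counts.join(pct, lsuffix="_n", rsuffix="_pct")
    out.index.name = "group"
    return out


def signature_response(
    reference: SignatureSet,
    conditions: ExpressionMatrix,
    baseline: str,
    threshold: float = 1.0,
) -> dict:
    """Classify whether each signature gene's expected shift is realized.

    For every non-baseline condition, a consensus-up gene is
    ``non-affected`` if its log2 change versus baseline exceeds
    ``threshold`` (i.e. the expected induction happened) and
    ``affected`` otherwise; symmetric for down genes.  The matrix may be
    on the cpm scale (log-ratios computed with a pseudocount of 1) or
    already log2 (differences taken directly).

    Returns per-gene classes and per-condition affected fractions.
    """
    if baseline not in conditions.data.columns:
        raise ValueError(f"baseline condition {baseline!r} not in matrix")
    sub, dropped = restrict_to_genes(conditions, reference.genes)
    if dropped:
        logger.info("signature_response: dropped %d absent signature genes", len(dropped))
    if conditions.scale == "cpm":
        log_expr = np.log2(sub.data + 1.0)
    elif conditions.scale in ("log2cpm", "zscore"):
        log_expr = sub.data
    else:
        raise ValueError("signature_response expects cpm or log2 scale")
    base = log_expr[baseline]
    up = [g for g in reference.up if g in log_expr.index]
    down = [g for g in reference.down if g in log_expr.index]
    per_gene_frames = []
    fractions = []
    for cond in log_expr.columns:
        if cond == baseline:
            continue
        ratio = log_expr[cond] - base
        up_ok = ratio.loc[up] > threshold
        down_ok = ratio.loc[down] < -threshold
        classes = pd.concat(
            [
                pd.Series(np.where(up_ok, "non-affected", "affected"), index=up),
                pd.Series(np.where(down_ok, "non-affected", "affected"), index=down),
            ]
        )
        frame = pd.DataFrame(
            {
                "condition": cond,
                "expected": ["up"] * len(up) + ["down"] * len(down),
                "log2_change": pd.concat([ratio.loc[up], ratio.loc[down]]),
                "class": classes,
            }
        )
        frame.index.name = "gene_id"
        per_gene_frames.append(frame.reset_index())
        fractions.append(
            {
                "condition": cond,
                "up_affected_frac": float((~up_ok).mean()) if up else float("nan"),
                "down_affected_frac": float((~down_ok).mean()) if down else float("nan"),
                "n_up": len(up),
                "n_down": len(down),
            }
        )
    if not fractions:
        raise ValueError("matrix has no non-baseline condition")
    return {
        "per_gene": pd.concat(per_gene_frames, ignore_index=True),
        "fractions": pd.DataFrame(fractions).set_index("condition"),
        "dropped_genes": dropped,
        "threshold": threshold,
    }
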