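"""Independent brute-force reference implementations used only by tests.

Each function here is written as plainly as possible, straight from the
textbook definition, and is deliberately kept independent of the package
code paths it cross-checks.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(p):
    """Benjamini-Hochberg step-up adjusted p-values, literal procedure."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


def gsea_running_sum(scores, hits, weight):
    """Literal weighted KS running sum: loop over positions."""
    n = len(scores)
    m = int(np.sum(hits))
    nr = sum(abs(scores[i]) ** weight for i in range(n) if hits[i])
    out = []
    acc = 0.0
    for i in range(n):
        if hits[i]:
            acc += abs(scores[i]) ** weight / nr
        else:
            acc -= 1.0 / (n - m)
        out.append(acc)
    return np.array(out)


def gsea_es(scores, hits, weight):
    rs = gsea_running_sum(scores, hits, weight)
    hi, lo = rs.max(), rs.min()
    return float(hi if hi >= -lo else lo)


def connectivity(d, labels, L):
    """Connectivity index by literal double loop over items and neighbor ranks."""
    n = len(labels)
    total = 0.0
    for i in range(n):
        others = [(d[i, j], j) for j in range(n) if j != i]
        others.sort(key=lambda t: (t[0], t[1]))
        for rank, (_, j) in enumerate(others[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def dunn(d, labels):
    """Dunn index by literal pairwise loops."""
    n = len(labels)
    min_inter = np.inf
    max_intra = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                max_intra = max(max_intra, d[i, j])
            else:
                min_inter = min(min_inter, d[i, j])
    return min_inter / max_intra if max_intra > 0 else np.inf


def silhouette(d, labels):
    """Mean silhouette width by literal per-item computation (singletons -> 0)."""
    labels = np.asarray(labels)
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = np.inf
        for c in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([d[i, j] for j in members]))
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def km_survival(times, events, t):
    """Product-limit estimate S(t) by literal loop over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for ti in sorted(set(times[events == 1])):
        if ti > t:
            break
        n_at_risk = int((times >= ti).sum())
        d_i = int(((times == ti) & (events == 1)).sum())
        s *= 1.0 - d_i / n_at_risk
    return s


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
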