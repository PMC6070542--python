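"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (triple-loop Floyd-Warshall, exhaustive
triangle enumeration, first-principles ANOVA sums of squares) kept separate
from, and structurally unlike, the library code they check.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge length 1/w, by triple loop."""
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                d[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    d = floyd_warshall(W)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def characteristic_path_length(W: np.ndarray) -> tuple[float, int]:
    n = W.shape[0]
    d = floyd_warshall(W)
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    if not finite:
        return float("nan"), 0
    return float(np.mean(finite)), len(finite)


def clustering_coefficient(W: np.ndarray) -> float:
    """Onnela clustering by exhaustive enumeration of node triples."""
    n = W.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if W[j, h] > 0:
                    s += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * s / (k * (k - 1))
    return float(c.mean())


def local_efficiency(W: np.ndarray) -> float:
    """Direct per-node evaluation with Floyd-Warshall subgraph distances."""
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub)
        s = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    s += (W[i, nbrs[a]] * W[i, nbrs[b]] / d[a, b]) ** (1.0 / 3.0)
        total += s / (k * (k - 1))
    return total / n


def icc_a1_anova(table: np.ndarray) -> float:
    """ICC(A,1) from first-principles two-way ANOVA sums of squares."""
    n, k = table.shape
    grand = table.mean()
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (table[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (table[:, j].mean() - grand) ** 2
    ss_total = float(((table - grand) ** 2).sum())
    ss_resid = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_resid / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    return (ms_r - ms_e) / denom
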