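"""Weighted-network construction: symmetrization, group thresholding, sparsity.

Edges with small connection probability are dominated by tracking noise, so
group-level connectivity thresholds remove them before network analysis: an
edge is dropped when the group mean plus two standard deviations of its
connectivity falls below the threshold.  Two strategies are supported:

* ``common``   -- the rule is evaluated on all scans pooled (both sessions),
  giving one mask shared by every scan, hence identical edge positions and
  identical sparsity for all subjects and sessions;
* ``separate`` -- the rule is evaluated per session, so the two sessions of
  a test-retest pair may end up with slightly different masks and sparsity.

The edge universe is the strict upper triangle of an undirected simple graph
(no self-loops): an n-node network has n(n-1)/2 possible edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .cohort import ConnectomeScan

__all__ = [
    "EdgeMask",
    "symmetrize",
    "group_threshold_mask",
    "threshold_sweep",
    "sparsity",
    "apply_mask",
    "cost_normalize",
]

Strategy = Literal["common", "separate"]

_ENDPOINT_TOL = 1e-9


@dataclass(frozen=True)
class EdgeMask:
    """Boolean symmetric matrix of retained edges for one threshold.

    ``session_scope`` records which scans the group statistic was computed
    on: ``"pooled"`` for the common strategy, a session id for separate.
    """

    mask: np.ndarray
    threshold: float
    strategy: Strategy
    session_scope: str = "pooled"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"mask must be square, got shape {m.shape}")
        if not np.array_equal(m, m.T):
            raise ValueError("mask is not symmetric")
        if np.any(np.diagonal(m)):
            raise ValueError("mask diagonal must be false")
        object.__setattr__(self, "mask", m)

    @property
    def n_nodes(self) -> int:
        return self.mask.shape[0]


def symmetrize(p_forward: np.ndarray, p_backward: np.ndarray) -> np.ndarray:
    """Average directed tracking probabilities into one symmetric matrix.

    Probabilistic tractography yields two estimates for every region pair
    {i, j}: one seeding at i (``p_forward[i, j]``) and one seeding at j
    (``p_backward[j, i]``).  The undirected connection probability is their
    arithmetic mean, assigned symmetrically:
    ``out[i, j] = out[j, i] = (p_forward[i, j] + p_backward[j, i]) / 2``
    for i < j, with a zero diagonal.
    """
    fw = np.asarray(p_forward, dtype=float)
    bw = np.asarray(p_backward, dtype=float)
    if fw.shape != bw.shape or fw.ndim != 2 or fw.shape[0] != fw.shape[1]:
        raise ValueError(
            f"shape mismatch: p_forward {fw.shape} vs p_backward {bw.shape}"
        )
    n = fw.shape[0]
    iu = np.triu_indices(n, k=1)
    pair_mean = 0.5 * (fw[iu] + bw[iu[1], iu[0]])
    out = np.zeros((n, n))
    out[iu] = pair_mean
    out[(iu[1], iu[0])] = pair_mean
    return out


def _edge_stats(matrices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge mean and sample sd (ddof=1) over a stack of matrices."""
    mean = matrices.mean(axis=0)
    sd = matrices.std(axis=0, ddof=1)
    return mean, sd


def group_threshold_mask(
    scans: Iterable[ConnectomeScan],
    threshold: float,
    strategy: Strategy = "common",
) -> EdgeMask | dict[str, EdgeMask]:
    """Build the retained-edge mask(s) for one connectivity threshold.

    An edge is removed iff ``mean(P_ij) + 2 * sd(P_ij) < threshold`` where
    the statistics run over the scans in scope (all scans pooled for
    ``common``; per session for ``separate``, which returns one mask per
    session id).  The sd is the sample standard deviation (n-1 denominator).
    Ties (statistic == threshold) retain the edge.
    """
    scans = list(scans)
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if strategy == "common":
        return _mask_from_scans(scans, threshold, "common", "pooled")
    if strategy == "separate":
        sessions = sorted({s.session_id for s in scans})
        return {
            ses: _mask_from_scans(
                [s for s in scans if s.session_id == ses],
                threshold,
                "separate",
                ses,
            )
            for ses in sessions
        }
    raise ValueError(f"unknown strategy {strategy!r}")


def _mask_from_scans(
    scans: Sequence[ConnectomeScan],
    threshold: float,
    strategy: Strategy,
    scope: str,
) -> EdgeMask:
    if len(scans) < 2:
        raise ValueError(
            f"need >= 2 scans to evaluate the threshold rule, got {len(scans)}"
        )
    stack = np.stack([s.matrix for s in scans])
    mean, sd = _edge_stats(stack)
    mask = mean + 2.0 * sd >= threshold
    np.fill_diagonal(mask, False)
    return EdgeMask(mask=mask, threshold=threshold, strategy=strategy, session_scope=scope)


def threshold_sweep(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic threshold sequence ``start, start+step, ..., stop``.

    The endpoint is included when (stop - start) is an integer multiple of
    step within 1e-9.  The default study design, 0.01 to 0.10 in 0.0025
    steps, yields 37 thresholds.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if start > stop:
        raise ValueError(f"start {start} must be <= stop {stop}")
    n_steps = int(np.floor((stop - start) / step + _ENDPOINT_TOL))
    return start + step * np.arange(n_steps + 1)


def sparsity(mask: EdgeMask | np.ndarray) -> float:
    """Fraction of possible edges retained: upper-triangle count / (n(n-1)/2)."""
    m = mask.mask if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(m[iu].sum() / (n * (n - 1) / 2))


def apply_mask(scan: ConnectomeScan | np.ndarray, mask: EdgeMask | np.ndarray):
    """Zero out edges not retained by the mask; retained edges are unchanged."""
    m = mask.mask if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    if isinstance(scan, ConnectomeScan):
        if scan.matrix.shape != m.shape:
            raise ValueError(
                f"shape mismatch: scan {scan.matrix.shape} vs mask {m.shape}"
            )
        return ConnectomeScan(
            scan.subject_id, scan.session_id, np.where(m, scan.matrix, 0.0)
        )
    matrix = np.asarray(scan, dtype=float)
    if matrix.shape != m.shape:
        raise ValueError(f"shape mismatch: matrix {matrix.shape} vs mask {m.shape}")
    return np.where(m, matrix, 0.0)


def total_cost(matrix: np.ndarray) -> float:
    """Sum of edge weights over the strict upper triangle (the network cost)."""
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return float(m[iu].sum())


def cost_normalize(scan: ConnectomeScan | np.ndarray) -> np.ndarray:
    """Scale weights so every network has the same total cost (sum of 1).

    Each weight is divided by the sum of weights over the strict upper
    triangle (each undirected edge counted once), so the output's
    upper-triangle sum is exactly 1 and zero edges stay zero.  The result is
    a plain weight matrix: entries may exceed 1 and it no longer represents
    probabilities.
    """
    matrix = scan.matrix if isinstance(scan, ConnectomeScan) else np.asarray(scan, float)
    cost = total_cost(matrix)
    if cost <= 0.0:
        raise ValueError("cost normalization undefined for an all-zero matrix")
    return matrix / cost
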