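"""Test-retest reproducibility statistics: CV, ICC, similarity, binning.

All indices operate on a subject x session table of one measured quantity
(an edge's connectivity, or a network metric):

* ``cv_within``  -- mean over subjects of the across-session sample sd,
  divided by the grand mean, in percent (CV_ws);
* ``cv_between`` -- mean over sessions of the across-subject sample sd,
  divided by the grand mean, in percent (CV_bs);
* ``icc_a1``     -- two-way, single-measures, absolute-agreement intraclass
  correlation ICC(A,1) from the two-way ANOVA decomposition (McGraw-Wong):

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

  with MS_R the between-subjects, MS_C the between-sessions and MS_E the
  residual mean square; negative estimates are reported as-is.

Per-edge variants apply the same estimators independently to every edge of
a cohort, and edges can be binned by mean connectivity to summarize how
reproducibility varies with connection strength.

Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "RepeatedMeasures",
    "EdgeReliability",
    "cv_within",
    "cv_between",
    "icc_a1",
    "icc_classify",
    "edge_reliability",
    "bin_edges_by_connectivity",
    "similarity",
]

#: ICC classification bands; lower bound owns the boundary.
ICC_CLASS_BOUNDS = (("poor", 0.5), ("moderate", 0.75), ("good", 0.9))


@dataclass
class RepeatedMeasures:
    """A subjects x sessions table of one measured quantity (no missing cells)."""

    values: np.ndarray
    quantity_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (subjects x sessions), got {v.ndim}-D")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain missing or non-finite cells")
        self.values = v


def _as_table(data: RepeatedMeasures | np.ndarray) -> np.ndarray:
    if isinstance(data, RepeatedMeasures):
        return data.values
    return RepeatedMeasures(np.asarray(data, dtype=float)).values


# ---------------------------------------------------------------------------
# vectorized cores: tables of shape (n_subjects, n_sessions, ...) where the
# trailing axes index independent quantities (e.g. edges).


def _cv_within_nd(values: np.ndarray) -> np.ndarray:
    grand = values.mean(axis=(0, 1))
    within_sd = values.std(axis=1, ddof=1).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(grand != 0.0, 100.0 * within_sd / grand, np.nan)


def _cv_between_nd(values: np.ndarray) -> np.ndarray:
    grand = values.mean(axis=(0, 1))
    between_sd = values.std(axis=0, ddof=1).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(grand != 0.0, 100.0 * between_sd / grand, np.nan)


def _icc_a1_nd(values: np.ndarray) -> np.ndarray:
    n, k = values.shape[0], values.shape[1]
    grand = values.mean(axis=(0, 1))
    row_means = values.mean(axis=1)  # (n, ...)
    col_means = values.mean(axis=0)  # (k, ...)
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=0)
    resid = values - row_means[:, None] - col_means[None, :] + grand
    ss_resid = (resid**2).sum(axis=(0, 1))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_resid / ((n - 1) * (k - 1))
    num = ms_r - ms_e
    den = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0.0, num / den, np.nan)


# ---------------------------------------------------------------------------
# scalar interface


def cv_within(data: RepeatedMeasures | np.ndarray) -> float:
    """Within-subject coefficient of variation, in percent."""
    values = _as_table(data)
    if values.mean() == 0.0:
        raise ValueError("CV undefined: grand mean is zero")
    return float(_cv_within_nd(values))


def cv_between(data: RepeatedMeasures | np.ndarray) -> float:
    """Between-subject coefficient of variation, in percent."""
    values = _as_table(data)
    if values.mean() == 0.0:
        raise ValueError("CV undefined: grand mean is zero")
    return float(_cv_between_nd(values))


def icc_a1(data: RepeatedMeasures | np.ndarray) -> float:
    """ICC(A,1): two-way single-measures absolute-agreement intraclass correlation.

    May be negative; degenerate tables with zero total variance return nan.
    """
    values = _as_table(data)
    return float(_icc_a1_nd(values))


def icc_classify(icc: float) -> str:
    """Map an ICC value to the conventional reproducibility class.

    Bands: poor (< 0.5), moderate [0.5, 0.75), good [0.75, 0.9),
    excellent (>= 0.9).  nan maps to "undefined".
    """
    if np.isnan(icc):
        return "undefined"
    for label, upper in ICC_CLASS_BOUNDS:
        if icc < upper:
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# per-edge reliability


@dataclass
class EdgeReliability:
    """Per-edge reproducibility matrices for a test-retest cohort.

    Symmetric n x n matrices (nan on the diagonal and for undefined edges,
    i.e. edges whose grand-mean connectivity is zero) plus the cohort-mean
    connectivity matrix used for binning.
    """

    mean: np.ndarray
    cv_ws: np.ndarray
    cv_bs: np.ndarray
    icc: np.ndarray
    n_undefined_edges: int


def _to_symmetric(n: int, iu: tuple, edge_values: np.ndarray) -> np.ndarray:
    m = np.full((n, n), np.nan)
    m[iu] = edge_values
    m[(iu[1], iu[0])] = edge_values
    return m


def edge_reliability(cohort: Cohort) -> EdgeReliability:
    """Apply CV_ws, CV_bs and ICC(A,1) independently to every edge.

    Each strict upper-triangle edge contributes one subject x session table;
    results are returned as symmetric matrices.  Edges that are zero in all
    scans are flagged undefined (nan).
    """
    values = cohort.upper_stack()  # (S, R, E)
    n = cohort.n_nodes
    iu = np.triu_indices(n, k=1)
    grand = values.mean(axis=(0, 1))
    cv_ws = _cv_within_nd(values)
    cv_bs = _cv_between_nd(values)
    icc = _icc_a1_nd(values)
    undefined = grand == 0.0
    for arr in (cv_ws, cv_bs, icc):
        arr[undefined] = np.nan
    return EdgeReliability(
        mean=_to_symmetric(n, iu, grand),
        cv_ws=_to_symmetric(n, iu, cv_ws),
        cv_bs=_to_symmetric(n, iu, cv_bs),
        icc=_to_symmetric(n, iu, icc),
        n_undefined_edges=int(undefined.sum()),
    )


def bin_edges_by_connectivity(
    mean_matrix: np.ndarray,
    index_matrices: dict[str, np.ndarray] | None = None,
    bin_start: float = 0.0,
    bin_stop: float = 0.3,
    bin_step: float = 0.01,
) -> pd.DataFrame:
    """Group edges by cohort-mean connectivity and summarize indices per bin.

    Bins are half-open ``[b, b + step)`` from ``bin_start`` to ``bin_stop``
    plus one overflow group for values >= ``bin_stop`` (31 groups at the
    defaults).  Each upper-triangle edge is assigned by its cohort-mean
    connectivity; per bin the edge count and the mean and sample sd of every
    reproducibility index are reported.  Edges with undefined indices (nan)
    are excluded from that index's mean/sd but still counted.
    """
    if bin_step <= 0:
        raise ValueError(f"bin_step must be > 0, got {bin_step}")
    mean_matrix = np.asarray(mean_matrix, dtype=float)
    n = mean_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    mean_edges = mean_matrix[iu]
    edges = {
        name: np.asarray(m, dtype=float)[iu] for name, m in (index_matrices or {}).items()
    }

    lows = np.arange(bin_start, bin_stop - 1e-12, bin_step)
    rows = []
    for low in lows:
        rows.append((low, low + bin_step, (mean_edges >= low) & (mean_edges < low + bin_step)))
    rows.append((bin_stop, np.inf, mean_edges >= bin_stop))

    records = []
    for low, high, sel in rows:
        rec: dict[str, float] = {
            "bin_low": low,
            "bin_high": high,
            "n_edges": int(sel.sum()),
        }
        for name, vals in edges.items():
            in_bin = vals[sel]
            in_bin = in_bin[np.isfinite(in_bin)]
            rec[f"{name}_mean"] = float(in_bin.mean()) if in_bin.size else np.nan
            rec[f"{name}_sd"] = (
                float(in_bin.std(ddof=1)) if in_bin.size > 1 else np.nan
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# similarity


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def similarity(
    cohort: Cohort, between_sessions: str | None = None
) -> tuple[float, float]:
    """Within- and between-subject similarity of connectivity matrices.

    Within: mean over subjects of the Pearson correlation between the two
    sessions' vectorized upper triangles.  Between: mean Pearson correlation
    over all unordered subject pairs, computed per session and averaged
    across sessions (pass a session id as ``between_sessions`` to restrict
    the between-subject average to that session).
    """
    values = cohort.upper_stack()  # (S, R, E)
    S, R, _ = values.shape
    if R != 2:
        raise ValueError(f"similarity requires exactly 2 sessions, got {R}")
    within = float(
        np.mean([_pearson(values[s, 0], values[s, 1]) for s in range(S)])
    )
    sessions = cohort.session_ids
    if between_sessions is not None:
        session_idx = [sessions.index(between_sessions)]
    else:
        session_idx = list(range(R))
    between_per_session = []
    for r in session_idx:
        corrs = [
            _pearson(values[a, r], values[b, r])
            for a in range(S)
            for b in range(a + 1, S)
        ]
        between_per_session.append(float(np.mean(corrs)))
    return within, float(np.mean(between_per_session))
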