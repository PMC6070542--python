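"""Integration of network metrics over the sparsity range.

Metrics computed across a sweep of connectivity thresholds form a curve of
metric value versus network sparsity.  Summarizing the curve by its integral
over the sparsity range removes the arbitrariness of any single threshold;
normalizing by the range turns the integral into a sparsity-weighted mean,
so the summary keeps the metric's own units and stays comparable between
subjects whose sparsity ranges differ slightly (as they do under the
separate thresholding strategy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reproducibility import cv_between, cv_within, icc_a1, icc_classify

__all__ = ["MetricCurve", "integrate_curve", "summarize_cohort", "METRIC_COLUMNS"]

METRIC_COLUMNS = ("E_glob", "E_loc", "C_w", "L_w")


@dataclass
class MetricCurve:
    """One subject/session metric-versus-sparsity curve."""

    sparsity: np.ndarray
    values: np.ndarray
    strategy: str = "common"

    def __post_init__(self) -> None:
        s = np.asarray(self.sparsity, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("sparsity and values must be 1-D and equal-length")
        if s.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(v))):
            raise ValueError("curve contains non-finite points")
        self.sparsity, self.values = s, v


def _collapse_sorted(s: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by sparsity and average metric values at duplicate sparsities."""
    order = np.argsort(s, kind="stable")
    s, v = s[order], v[order]
    uniq, inverse = np.unique(s, return_inverse=True)
    if uniq.size == s.size:
        return s, v
    sums = np.zeros(uniq.size)
    counts = np.zeros(uniq.size)
    np.add.at(sums, inverse, v)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


def integrate_curve(
    curve: MetricCurve | tuple[Sequence[float], Sequence[float]],
    normalize: bool = True,
) -> float:
    """Trapezoidal integral of a metric over sparsity.

    Points are sorted by sparsity first; duplicate sparsity points (two
    thresholds yielding the identical mask) are collapsed by averaging the
    metric.  With ``normalize=True`` (default) the integral is divided by
    the sparsity range, yielding a sparsity-weighted mean in the metric's
    own units; ``normalize=False`` returns the raw integral.

    Raises ValueError when all sparsity values coincide (degenerate range).
    """
    if isinstance(curve, MetricCurve):
        s, v = curve.sparsity, curve.values
    else:
        s = np.asarray(curve[0], dtype=float)
        v = np.asarray(curve[1], dtype=float)
    s, v = _collapse_sorted(s, v)
    if s.size < 2:
        raise ValueError("degenerate sparsity range: all points coincide")
    area = float(np.trapezoid(v, s))
    if not normalize:
        return area
    return area / float(s[-1] - s[0])


def summarize_cohort(
    records: pd.DataFrame, normalize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate each subject's metric curves and assess their reliability.

    ``records`` is the long-format metric table with columns ``subject``,
    ``session``, ``strategy``, ``cost_normalized``, ``threshold``,
    ``sparsity`` and one column per metric (E_glob, E_loc, C_w, L_w).  Every
    subject/session must have a row at every threshold of its strategy.

    Returns ``(summary, integrated)``:

    * ``integrated`` -- one row per subject/session/strategy/normalization
      with the integrated value of each metric;
    * ``summary`` -- one row per strategy/normalization/metric with the
      per-session mean and sd of the integrated values plus CV_bs, CV_ws,
      ICC(A,1) and the ICC class (the study's summary-table layout).
    """
    required = {"subject", "session", "strategy", "cost_normalized", "threshold", "sparsity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table is missing columns: {sorted(missing)}")
    metrics = [m for m in METRIC_COLUMNS if m in records.columns]
    if not metrics:
        raise ValueError("records table contains no metric columns")

    _check_complete(records)

    integrated_rows = []
    for (strategy, normalized, subject, session), group in records.groupby(
        ["strategy", "cost_normalized", "subject", "session"], sort=True
    ):
        row: dict[str, object] = {
            "strategy": strategy,
            "cost_normalized": normalized,
            "subject": subject,
            "session": session,
        }
        s = group["sparsity"].to_numpy()
        for m in metrics:
            row[m] = integrate_curve((s, group[m].to_numpy()), normalize=normalize)
        integrated_rows.append(row)
    integrated = pd.DataFrame.from_records(integrated_rows)

    summary_rows = []
    for (strategy, normalized), group in integrated.groupby(
        ["strategy", "cost_normalized"], sort=True
    ):
        table = group.pivot(index="subject", columns="session")
        sessions = sorted(group["session"].unique())
        for m in metrics:
            values = table[m][sessions].to_numpy()
            rec: dict[str, object] = {
                "strategy": strategy,
                "cost_normalized": normalized,
                "metric": m,
            }
            for ses in sessions:
                col = table[(m, ses)].to_numpy()
                rec[f"mean_ses{ses}"] = float(col.mean())
                rec[f"sd_ses{ses}"] = float(col.std(ddof=1))
            rec["cv_bs"] = cv_between(values)
            rec["cv_ws"] = cv_within(values)
            icc = icc_a1(values)
            rec["icc"] = icc
            rec["icc_class"] = icc_classify(icc)
            summary_rows.append(rec)
    summary = pd.DataFrame.from_records(summary_rows)
    return summary, integrated


def _check_complete(records: pd.DataFrame) -> None:
    gaps = []
    for (strategy, normalized), group in records.groupby(["strategy", "cost_normalized"]):
        thresholds = set(group["threshold"].unique())
        for (subject, session), sub in group.groupby(["subject", "session"]):
            have = set(sub["threshold"])
            miss = thresholds - have
            if miss:
                gaps.append(
                    f"{strategy}/norm={normalized} subject {subject} session {session}: "
                    f"missing thresholds {sorted(miss)[:5]}"
                )
    if gaps:
        raise ValueError("incomplete metric table:\n" + "\n".join(gaps))
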