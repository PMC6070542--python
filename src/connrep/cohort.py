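"""Containers and delimited-text I/O for test-retest connectivity cohorts.

A cohort is a collection of symmetric node x node connectivity-probability
matrices, one per (subject, session) scan.  Matrices live on disk as plain
TSV/CSV files (one per scan) under::

    cohort_dir/
        nodes.tsv               # one node label per line, header "label"
        sub-<id>/ses-<id>.tsv   # square numeric matrix with a label header row

Values are connection probabilities in [0, 1] with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeScan",
    "Cohort",
    "validate_connectivity_matrix",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
]

_SYM_ATOL = 1e-9


def validate_connectivity_matrix(matrix: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check that ``matrix`` is a valid connectivity-probability matrix.

    Requirements: 2-D square, finite, symmetric, zero diagonal and all
    entries in [0, 1].  Returns the matrix as a float array.

    Raises
    ------
    ValueError
        If any requirement is violated; the message names the offending
        property.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square 2-D, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains non-finite entries")
    if not np.allclose(m, m.T, atol=_SYM_ATOL, rtol=0.0):
        raise ValueError(f"{name} is not symmetric")
    if np.any(np.diagonal(m) != 0.0):
        raise ValueError(f"{name} has a non-zero diagonal")
    if m.min() < 0.0 or m.max() > 1.0:
        raise ValueError(f"{name} has entries outside [0, 1]")
    return m


@dataclass
class ConnectomeScan:
    """One symmetric weighted connectivity matrix for one subject/session.

    Entries are connection probabilities P_ij in [0, 1]; the edge weight of
    the weighted network is w_ij = P_ij.
    """

    subject_id: str
    session_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = validate_connectivity_matrix(
            self.matrix, name=f"scan ({self.subject_id}, {self.session_id})"
        )

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def upper_values(self) -> np.ndarray:
        """Strict upper-triangle entries as a flat vector (edge universe)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.matrix[iu]


@dataclass
class Cohort:
    """The full subject x session collection of scans plus node metadata."""

    scans: dict[tuple[str, str], ConnectomeScan]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("cohort has no scans")
        n = next(iter(self.scans.values())).n_nodes
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise ValueError(
                f"{len(self.node_labels)} node labels for {n}-node matrices"
            )
        sessions_by_subject: dict[str, set[str]] = {}
        for (sub, ses), scan in self.scans.items():
            if (scan.subject_id, scan.session_id) != (sub, ses):
                raise ValueError(f"scan key {(sub, ses)} disagrees with scan ids")
            if scan.n_nodes != n:
                raise ValueError("scans have inconsistent node counts")
            sessions_by_subject.setdefault(sub, set()).add(ses)
        session_sets = {frozenset(s) for s in sessions_by_subject.values()}
        if len(session_sets) != 1:
            raise ValueError("every subject must have the same set of sessions")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def subject_ids(self) -> list[str]:
        return sorted({sub for sub, _ in self.scans})

    @property
    def session_ids(self) -> list[str]:
        return sorted({ses for _, ses in self.scans})

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)

    def scan(self, subject_id: str, session_id: str) -> ConnectomeScan:
        return self.scans[(subject_id, session_id)]

    def stack(self) -> np.ndarray:
        """All matrices as one (n_subjects, n_sessions, n, n) array.

        Subjects and sessions are in sorted-id order, which fixes the row
        and column order used by the reproducibility statistics.
        """
        out = np.empty(
            (self.n_subjects, self.n_sessions, self.n_nodes, self.n_nodes)
        )
        for i, sub in enumerate(self.subject_ids):
            for j, ses in enumerate(self.session_ids):
                out[i, j] = self.scans[(sub, ses)].matrix
        return out

    def upper_stack(self) -> np.ndarray:
        """Strict upper-triangle edges as (n_subjects, n_sessions, n_edges)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        stacked = self.stack()
        return stacked[:, :, iu[0], iu[1]]

    def session_scans(self, session_id: str) -> list[ConnectomeScan]:
        return [self.scans[(sub, session_id)] for sub in self.subject_ids]

    def all_scans(self) -> list[ConnectomeScan]:
        return [self.scans[k] for k in sorted(self.scans)]


# ---------------------------------------------------------------------------
# text I/O


def write_matrix(path: Path | str, matrix: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a square matrix as TSV with a node-label header row."""
    m = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = [f"node{i:03d}" for i in range(m.shape[0])]
    df = pd.DataFrame(m, columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_matrix(path: Path | str) -> tuple[np.ndarray, list[str] | None]:
    """Read a square numeric matrix from delimited text (TSV/CSV autodetect).

    Returns ``(matrix, labels)``; ``labels`` is None when the file has no
    header row.  Raises ValueError for ragged or non-numeric content.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    first = path.read_text().lstrip().splitlines()[0]
    has_header = any(
        not _is_number(tok) for tok in first.split(sep) if tok.strip() != ""
    )
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse matrix file {path}: {exc}") from exc
    values = df.to_numpy()
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path} is not square: shape {values.shape}"
        )
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path} contains non-numeric entries")
    labels = [str(c) for c in df.columns] if has_header else None
    return values.astype(float), labels


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_cohort(cohort: Cohort, cohort_dir: Path | str) -> None:
    """Write one TSV matrix per scan under ``cohort_dir`` plus nodes.tsv."""
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"label": cohort.node_labels}).to_csv(
        cohort_dir / "nodes.tsv", sep="\t", index=False
    )
    for (sub, ses), scan in sorted(cohort.scans.items()):
        sub_dir = cohort_dir / f"sub-{sub}"
        sub_dir.mkdir(exist_ok=True)
        write_matrix(sub_dir / f"ses-{ses}.tsv", scan.matrix, cohort.node_labels)


def read_cohort(cohort_dir: Path | str) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (strict validation)."""
    cohort_dir = Path(cohort_dir)
    nodes_path = cohort_dir / "nodes.tsv"
    labels: list[str] | None = None
    if nodes_path.exists():
        labels = pd.read_csv(nodes_path, sep="\t")["label"].astype(str).tolist()
    scans: dict[tuple[str, str], ConnectomeScan] = {}
    for sub_dir in sorted(cohort_dir.glob("sub-*")):
        sub = sub_dir.name.removeprefix("sub-")
        for ses_path in sorted(sub_dir.glob("ses-*.tsv")):
            ses = ses_path.stem.removeprefix("ses-")
            matrix, file_labels = read_matrix(ses_path)
            if labels is None:
                labels = file_labels
            scans[(sub, ses)] = ConnectomeScan(sub, ses, matrix)
    if not scans:
        raise ValueError(f"no sub-*/ses-*.tsv scans found under {cohort_dir}")
    return Cohort(scans=scans, node_labels=labels or [])
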