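"""End-to-end analysis pipeline and its configuration.

Stages, in order: load or simulate a cohort of test-retest connectivity
matrices; build retained-edge masks for every threshold of the sweep under
each requested strategy; tabulate sparsity; compute the four weighted
network metrics for every scan x threshold, with and without cost
normalization; quantify per-edge reproducibility (CV_ws, CV_bs, ICC,
similarity, connectivity-binned summaries); and integrate the metric
curves over sparsity to obtain summary metrics and their reliability.

Everything is deterministic given the seed; all outputs are delimited text
or JSON, written with 12 significant digits, plus a manifest recording the
configuration, package versions and a checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .construction import (
    EdgeMask,
    apply_mask,
    group_threshold_mask,
    sparsity,
    threshold_sweep,
    total_cost,
)
from .integration import summarize_cohort
from .metrics import compute_metrics
from .reproducibility import bin_edges_by_connectivity, edge_reliability, similarity
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_full_analysis", "metric_table", "sparsity_table"]

logger = logging.getLogger("connrep")

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``cohort_dir`` points at an on-disk cohort; when it is None a synthetic
    cohort is generated from ``synthetic`` (seeded by ``seed``).  The
    defaults reproduce the emulated study design: thresholds 0.01 to 0.10
    in 0.0025 steps (37 networks per scan), both thresholding strategies,
    both normalization conditions, and 31 connectivity bins.
    """

    cohort_dir: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    tmin: float = 0.01
    tmax: float = 0.10
    tstep: float = 0.0025
    strategies: tuple[str, ...] = ("common", "separate")
    normalizations: tuple[str, ...] = ("raw", "cost")
    bin_start: float = 0.0
    bin_stop: float = 0.3
    bin_step: float = 0.01
    out_dir: str = "connrep_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for s in self.strategies:
            if s not in ("common", "separate"):
                raise ValueError(f"unknown strategy {s!r}")
        for n in self.normalizations:
            if n not in ("raw", "cost"):
                raise ValueError(f"unknown normalization {n!r}")
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        if not self.normalizations:
            raise ValueError("at least one normalization is required")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in _RUN_FIELDS})
        unknown = set(raw) - _RUN_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if syn:
            cfg.synthetic = SyntheticConfig(**syn)
        cfg.strategies = tuple(cfg.strategies)
        cfg.normalizations = tuple(cfg.normalizations)
        if "seed" in raw and "seed" not in syn:
            cfg.synthetic = cfg.synthetic.with_seed(cfg.seed)
        return cfg


_RUN_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def _load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_dir is not None:
        logger.info("loading cohort from %s", config.cohort_dir)
        return read_cohort(config.cohort_dir)
    syn = config.synthetic
    logger.info(
        "simulating cohort: %d subjects x %d sessions, %d nodes, seed %d",
        syn.n_subjects, syn.n_sessions, syn.n_nodes, syn.seed,
    )
    return generate_cohort(syn)


def build_masks(
    cohort: Cohort, thresholds: Sequence[float], strategies: Sequence[str]
) -> dict[tuple[str, str], list[EdgeMask]]:
    """Masks per (strategy, session_scope), one per threshold.

    For the common strategy the scope is ``"pooled"`` and the single mask
    applies to every scan; for separate there is one scope per session.
    """
    masks: dict[tuple[str, str], list[EdgeMask]] = {}
    scans = cohort.all_scans()
    for strategy in strategies:
        for t in thresholds:
            result = group_threshold_mask(scans, float(t), strategy)  # type: ignore[arg-type]
            if isinstance(result, EdgeMask):
                masks.setdefault((strategy, "pooled"), []).append(result)
            else:
                for ses, m in result.items():
                    masks.setdefault((strategy, ses), []).append(m)
    return masks


def sparsity_table(masks: dict[tuple[str, str], list[EdgeMask]]) -> pd.DataFrame:
    rows = [
        {
            "strategy": strategy,
            "session_scope": scope,
            "threshold": m.threshold,
            "sparsity": sparsity(m),
        }
        for (strategy, scope), series in sorted(masks.items())
        for m in series
    ]
    return pd.DataFrame.from_records(rows)


def metric_table(
    cohort: Cohort,
    masks: dict[tuple[str, str], list[EdgeMask]],
    normalizations: Sequence[str] = ("raw", "cost"),
) -> pd.DataFrame:
    """Long-format metric table over scans x thresholds x strategies.

    Metrics are computed on the raw masked weights; the cost-normalized
    condition is obtained by rescaling with the scan's total cost, which is
    exact because every metric is linear (L_w inverse-linear) in a global
    weight rescaling.
    """
    strategies = sorted({s for s, _ in masks})
    rows = []
    for strategy in strategies:
        for scan in cohort.all_scans():
            scope = "pooled" if (strategy, "pooled") in masks else scan.session_id
            for mask in masks[(strategy, scope)]:
                W = apply_mask(scan.matrix, mask)
                cost = total_cost(W)
                rec = compute_metrics(
                    W,
                    subject_id=scan.subject_id,
                    session_id=scan.session_id,
                    threshold=mask.threshold,
                )
                base = {
                    "subject": scan.subject_id,
                    "session": scan.session_id,
                    "strategy": strategy,
                    "threshold": mask.threshold,
                    "sparsity": sparsity(mask),
                    "n_connected_pairs": rec.n_connected_pairs,
                    "cost": cost,
                }
                if "raw" in normalizations:
                    rows.append(
                        base
                        | {
                            "cost_normalized": False,
                            "E_glob": rec.E_glob,
                            "E_loc": rec.E_loc,
                            "C_w": rec.C_w,
                            "L_w": rec.L_w,
                        }
                    )
                if "cost" in normalizations:
                    if cost <= 0:
                        scaled = dict.fromkeys(("E_glob", "E_loc", "C_w", "L_w"), np.nan)
                    else:
                        scaled = {
                            "E_glob": rec.E_glob / cost,
                            "E_loc": rec.E_loc / cost,
                            "C_w": rec.C_w / cost,
                            "L_w": rec.L_w * cost,
                        }
                    rows.append(base | {"cost_normalized": True} | scaled)
    return pd.DataFrame.from_records(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _write_matrix_tsv(matrix: np.ndarray, labels: list[str], path: Path) -> None:
    pd.DataFrame(matrix, columns=labels).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute all pipeline stages and write outputs plus a manifest.

    Returns the manifest (also written to ``manifest.json``).  Any stage
    failure aborts with the stage name; outputs written so far are retained
    next to a ``FAILED`` marker file.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "package": "connrep",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "versions": _versions(),
        "stages": [],
        "outputs": {},
    }

    stage = "load_cohort"
    try:
        cohort = _load_cohort(config)
        manifest["stages"].append(stage)

        stage = "threshold_masks"
        thresholds = threshold_sweep(config.tmin, config.tmax, config.tstep)
        masks = build_masks(cohort, thresholds, config.strategies)
        sp = sparsity_table(masks)
        _write_tsv(sp, out / "sparsity.tsv")
        manifest["n_thresholds"] = int(len(thresholds))
        manifest["stages"].append(stage)

        stage = "network_metrics"
        logger.info(
            "computing metrics: %d scans x %d thresholds x %d strategies",
            len(cohort.scans), len(thresholds), len(config.strategies),
        )
        records = metric_table(cohort, masks, config.normalizations)
        _write_tsv(records, out / "metrics.tsv")
        manifest["stages"].append(stage)

        stage = "edge_reliability"
        rel = edge_reliability(cohort)
        for name, m in (
            ("mean_connectivity", rel.mean),
            ("edge_cv_ws", rel.cv_ws),
            ("edge_cv_bs", rel.cv_bs),
            ("edge_icc", rel.icc),
        ):
            _write_matrix_tsv(m, cohort.node_labels, out / f"{name}.tsv")
        bins = bin_edges_by_connectivity(
            rel.mean,
            {"cv_ws": rel.cv_ws, "cv_bs": rel.cv_bs, "icc": rel.icc},
            bin_start=config.bin_start,
            bin_stop=config.bin_stop,
            bin_step=config.bin_step,
        )
        _write_tsv(bins, out / "edge_bins.tsv")
        within_sim, between_sim = similarity(cohort)
        scalars = {
            "within_subject_similarity": within_sim,
            "between_subject_similarity": between_sim,
            "n_undefined_edges": rel.n_undefined_edges,
        }
        (out / "similarity.json").write_text(json.dumps(scalars, indent=2))
        manifest["stages"].append(stage)

        stage = "integrated_summary"
        summary, integrated = summarize_cohort(records)
        _write_tsv(integrated, out / "integrated_metrics.tsv")
        _write_tsv(summary, out / "integrated_summary.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.glob("*.tsv")) + [out / "similarity.json"]:
        manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["strategies"] = list(config.strategies)
    d["normalizations"] = list(config.normalizations)
    return d


def _versions() -> dict[str, str]:
    import scipy

    return {
        "connrep": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
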