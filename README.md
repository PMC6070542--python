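# connrep

Test-retest reproducibility analysis of weighted structural brain networks.

Structural connectomes from probabilistic diffusion tractography are
symmetric node × node matrices of connection probabilities P_ij ∈ [0, 1].
Before graph analysis, faint edges — dominated by tracking noise — are
removed by a group-level connectivity threshold: edge (i, j) is dropped when

    mean(P_ij) + 2·sd(P_ij) < threshold,

evaluated either on all scans pooled (**common** strategy: every subject and
session gets the same edge set and sparsity) or per session (**separate**
strategy: sparsity may differ between repeated scans).  `connrep` implements
this construction together with:

* the four weighted network metrics — global efficiency E_glob, local
  efficiency E_loc, clustering coefficient C_w (Onnela form), characteristic
  path length L_w — with edge length 1/w and optional cost normalization
  (weights divided by their total sum);
* integration of each metric over the sparsity range covered by a threshold
  sweep (default 0.01–0.10 in 0.0025 steps, 37 networks per scan), giving
  one threshold-free summary value per scan;
* test-retest reproducibility statistics: within/between-subject
  coefficients of variation

      CV_ws = mean_subjects( sd_sessions ) / grand mean · 100%
      CV_bs = mean_sessions( sd_subjects ) / grand mean · 100%,

  the two-way single-measures absolute-agreement intraclass correlation
  ICC(A,1), Pearson matrix similarity, and per-edge variants with
  connectivity-binned summaries (31 bins, 0–0.3 in 0.01 steps plus
  overflow);
* a synthetic test-retest cohort generator (30 subjects × 2 sessions, 78
  nodes by default) with distance-dependent connectivity and known
  within/between-subject variance components, so the full pipeline runs and
  is validated without imaging data.

It is aimed at researchers studying the reliability of connectome-derived
measures and at method developers who need a controlled, fully synthetic
test bed for thresholding and reliability analyses.  See
[docs/methods.md](docs/methods.md) for the model details and design choices.

## Worked example

```python
import numpy as np
from connrep import (SyntheticConfig, generate_cohort, edge_reliability,
                     similarity, summarize_cohort, threshold_sweep)
from connrep.pipeline import build_masks, metric_table

cohort = generate_cohort(SyntheticConfig(seed=1))

rel = edge_reliability(cohort)                      # per-edge CV_ws/CV_bs/ICC
iu = np.triu_indices(cohort.n_nodes, k=1)
print(f"edges below 0.01: {100*(rel.mean[iu] < 0.01).mean():.1f}%")
print(f"median edge CV_ws {np.nanmedian(rel.cv_ws[iu]):.1f}%, "
      f"CV_bs {np.nanmedian(rel.cv_bs[iu]):.1f}%, ICC {np.nanmedian(rel.icc[iu]):.2f}")
w, b = similarity(cohort)
print(f"similarity: within {w:.3f}, between {b:.3f}")

masks = build_masks(cohort, threshold_sweep(0.01, 0.10, 0.0025),
                    ("common", "separate"))
summary, _ = summarize_cohort(metric_table(cohort, masks))
cn = summary[summary.cost_normalized].set_index(["strategy", "metric"])
for m in ("E_loc", "C_w"):
    print(f"integrated {m} (cost-normalized): ICC common "
          f"{cn.loc[('common', m), 'icc']:.2f}, separate {cn.loc[('separate', m), 'icc']:.2f}")
```

prints

```
edges below 0.01: 80.3%
median edge CV_ws 7.8%, CV_bs 30.9%, ICC 0.89
similarity: within 0.993, between 0.926
integrated E_loc (cost-normalized): ICC common 0.79, separate 0.66
integrated C_w (cost-normalized): ICC common 0.84, separate 0.79
```

About 80% of edges are faint (mean connectivity < 0.01), the noisiest part
of the connectome.  Within-subject variation (7.8%) is well below
between-subject variation (30.9%), so per-edge ICC is high, and repeated
scans of one subject correlate more strongly (0.993) than scans of
different subjects (0.926).  The last two lines show the sparsity-mismatch
effect: when the two sessions are thresholded separately their sparsity
differs slightly, which penalizes the reliability of the local,
cost-normalized metrics (ICC drops from 0.79 to 0.66 for E_loc) — the
common strategy, or integration over thresholds, avoids most of that
penalty.

## Command line

```sh
connrep simulate --seed 1 --out cohort/           # write TSV matrices
connrep threshold --cohort cohort/ --strategy separate --out masks/
connrep reliability --cohort cohort/ --out report/
connrep run --config run.yaml                     # full pipeline + manifest
connrep summarize --metrics out/metrics.tsv --out summary/
```

`connrep run` executes every stage (simulate/load → masks → sparsity →
metrics → per-edge reliability and bins → integrated summaries) and writes
TSV/JSON tables plus a manifest with per-file checksums; the same seed
reproduces byte-identical outputs.

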