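# Methods

## Problem and scope

`connrep` quantifies the short-term test-retest reproducibility of weighted
structural brain networks built from connection-probability matrices, and of
the graph metrics computed on them.  The pipeline boundary is the symmetric
node × node connectivity matrix: everything upstream (diffusion MRI
acquisition, tractography, parcellation, registration) is out of scope, and a
synthetic cohort generator stands in for tractography output so that every
stage is testable without imaging data.

## Network construction

Connection probabilities from probabilistic tractography are direction
dependent; the two estimates for a region pair (seeding at either end) are
averaged into one symmetric matrix with zero diagonal (`symmetrize`).

Faint edges are dominated by tracking noise and are removed by a group-level
rule: edge (i, j) is dropped when `mean(P_ij) + 2·sd(P_ij) < threshold`, with
the sample (n−1) standard deviation taken over the scans in scope.  Two
scopes are implemented:

* **common** — both sessions pooled; one mask shared by every scan, so all
  subjects and both sessions have identical edge positions and identical
  sparsity;
* **separate** — the rule evaluated per session; masks and sparsity may
  differ slightly between the two sessions of a test-retest pair.

The denominator choice (n−1) follows common statistical-software defaults;
ties (statistic exactly equal to the threshold) retain the edge.  The edge
universe is the strict upper triangle of a simple undirected graph: a
78-node network has 78·77/2 = 3003 possible edges, and sparsity is the
retained fraction of that universe.  The default sweep runs thresholds 0.01
to 0.10 in 0.0025 steps (37 networks per scan); the endpoint is included
when the range is an integer multiple of the step within 1e−9.

Cost normalization divides every weight by the sum of weights over the
strict upper triangle, giving every network unit total cost.  The sum-to-1
convention is arbitrary because all four metrics are scale-covariant (below).

## Network metrics

Edge weights are connection probabilities (w = P); the connection length of
an edge is 1/w, and shortest path distances are minimal total lengths
(Dijkstra on the sparse length graph).  With d the distance matrix and n the
node count:

* **global efficiency** `E_glob = (1/(n(n−1))) Σ_{i≠j} 1/d_ij`, with
  1/∞ = 0 for disconnected pairs;
* **characteristic path length** `L_w` = mean of the finite d_ij over
  ordered pairs; disconnected pairs are excluded rather than imputed, and
  the number of connected pairs is reported alongside (a fully disconnected
  network yields an undefined flag, not an exception);
* **clustering coefficient** `C_w` (Onnela form): per node,
  `C_i = 2/(k_i(k_i−1)) Σ_{j<h} (w_ij w_ih w_jh)^{1/3}` over neighbor pairs,
  averaged over all nodes.  Weights are deliberately **not** rescaled by the
  maximum weight: max-rescaling would destroy the exact linear behaviour of
  the metric under a global weight rescaling, which the cost-normalization
  analysis relies on;
* **local efficiency** `E_loc`: per node i with neighbor set N_i (k_i ≥ 2),
  `E_loc(i) = 1/(k_i(k_i−1)) Σ_{j≠h∈N_i} (w_ij w_ih / d_jh(N_i))^{1/3}`
  where d_jh(N_i) is the shortest path length inside the subgraph induced by
  N_i (original weights); nodes with fewer than two neighbors contribute 0.

Scale covariance: for c > 0, E_glob, C_w and E_loc scale by c and L_w by
1/c, exactly.  The pipeline therefore computes metrics once on the raw
masked weights and obtains the cost-normalized condition by rescaling with
the scan's total cost; a test verifies this equals direct computation on
cost-normalized matrices to 1e−9 relative.  On weights in [0, 1] (no
rescaling) E_glob ≤ 1 and C_w ≤ 1.

Numerical notes: the public all-pairs operation uses Dijkstra
(`scipy.sparse.csgraph`); inside `local_efficiency` the per-neighborhood
distances use a vectorized dense min-plus (Floyd–Warshall) recursion, which
is faster than per-node sparse Dijkstra calls at the neighborhood sizes
arising here (tens of nodes).  A naive triple-loop Floyd–Warshall and an
exhaustive triangle enumeration serve as independent oracles in the test
suite only.

## Reproducibility indices

For a subject × session table of any quantity:

* `CV_ws` = 100 · mean over subjects of the across-session sample sd,
  divided by the grand mean;
* `CV_bs` = 100 · mean over sessions of the across-subject sample sd,
  divided by the grand mean;
* `ICC(A,1)` — two-way, single-measures, absolute-agreement intraclass
  correlation (McGraw–Wong), `(MS_R − MS_E) / (MS_R + (k−1)MS_E +
  (k/n)(MS_C − MS_E))` from the two-way ANOVA mean squares.  Negative
  estimates are reported as-is; classification bands are poor (<0.5),
  moderate [0.5, 0.75), good [0.75, 0.9), excellent (≥0.9), with the lower
  bound owning each boundary (the conventional ranges do not state boundary
  ownership; this assignment is ours).

CVs are scale-invariant but not shift-invariant — they are relative
measures, so location shifts change them by construction.

Per-edge reliability applies the three estimators independently to each
upper-triangle edge; edges that are zero in every scan are flagged undefined
and excluded from bin summaries (a count is reported).  Edges are binned by
cohort-mean connectivity into half-open bins [b, b+0.01) from 0 to 0.3 plus
an overflow group — 31 groups at the defaults; setting `bin_start=0.01`
gives the 30-group variant that drops the faint group.

Similarity: within-subject similarity is the mean over subjects of the
Pearson correlation between the two sessions' vectorized upper triangles;
between-subject similarity is the mean correlation over unordered subject
pairs, computed per session and averaged across the two sessions (a single
session can be selected to probe sensitivity to that choice).

## Integration over sparsity

Metrics across the threshold sweep form a metric-versus-sparsity curve per
scan.  The summary is the trapezoidal integral over sparsity divided by the
sparsity range — a sparsity-weighted mean that keeps the metric's units and
remains comparable between subjects whose sparsity ranges differ (as under
the separate strategy, where per-session sparsity grids are used and flagged
in the output).  Curves are sorted by sparsity; duplicate sparsity points
(two thresholds producing the same mask) are collapsed by averaging.  The
raw (un-normalized) integral is also available.  The subject × session
integrated values then feed the CV/ICC machinery, producing the summary
table (per-session mean ± sd, CV_bs, CV_ws, ICC) for every strategy ×
normalization × metric.

## Synthetic cohort generator

The generator emulates the study design: 30 subjects × 2 sessions, 78
nodes.  Nodes receive fixed pseudo-random positions in the unit cube; the
population template is `T_ij = base_scale · exp(−decay_rate · dist(i, j))`,
capturing the empirical pattern that short-range connections are strong and
most edges are faint.  Each edge then follows a two-level lognormal model:
subject effect `exp(a_ij · b)`, b ~ N(0, σ_b²), and session effect
`exp(a_ij · e)`, e ~ N(0, σ_w²), clipped at `clip_max`.

The attenuation factor `a_ij = 1/√(1 + T_ij/attenuation_scale)` encodes a
robust feature of tractography connectomes: strong, short-range connections
are measured with smaller relative error than faint ones, so CVs decrease
with connectivity.  For faint edges (T well below the attenuation scale)
a_ij ≈ 1 and the plain two-level lognormal model holds.

Defaults and rationale (all frozen after one-time tuning, not revisited):

| parameter | default | meaning / rationale |
|---|---|---|
| n_nodes | 78 | cortical parcellation size of the emulated design |
| n_subjects / n_sessions | 30 / 2 | emulated test-retest design |
| base_scale | 0.4 | connectivity at zero distance; keeps clipping negligible |
| decay_rate | 8.8 | tuned once so ~80% of edges fall below connectivity 0.01 (observed 78–83% over seeds) |
| sigma_between | 0.3 | between-subject log-sd; yields between-subject CV ≈ 32% |
| sigma_within | 0.1 | session log-sd; within-subject CV ≈ 10%, below the between-subject level as in real test-retest data |
| attenuation_scale | 0.2 | mildest value that makes per-bin CV decrease with connectivity robustly; `None` disables, restoring the exactly homogeneous model |
| clip_max | 1.0 | probabilities; heavy clipping would invalidate the closed forms |

Closed-form expectations (`theoretical_reliability`): the CV of a lognormal
with log-sd σ is √(exp(σ²)−1); the observed between-subject spread combines
both components, so the between CV uses √(σ_b²+σ_w²); the expected ICC on
the log scale is σ_b²/(σ_b²+σ_w²).  These are population quantities, valid
for σ ≤ 0.5 with negligible clipping and attenuation.  A known caveat: the
plug-in CV_ws estimator averages sample sds over k = 2 sessions, and a
sample sd of two normal draws has expectation c4(2) = √(2/π) ≈ 0.798 of the
population sd, so the estimator's expectation is ≈ 0.8 × the population CV.
`theoretical_reliability(..., bias_corrected=True)` returns the
c4-corrected expectations for comparing against empirical estimates;
recovered medians match the corrected value within a few percent.

What the generator does **not** emulate: spatial correlation of subject
effects across edges (effects are i.i.d. per edge), head motion or
registration artifacts, distance-dependent ICC structure beyond what the
attenuation induces, and the exact distributional shape of real
probabilistic-tractography connectivity (lognormal is a convenient
positive, right-skewed stand-in that makes the variance-components oracle
closed-form).  Passing tests therefore demonstrate internal correctness and
faithful reproduction of the analysis design's qualitative behaviour, not
claims about any particular imaging dataset.

## Design choices where the design was open

* Thresholding uses strict inequality for removal, per the stated rule;
  ties retain.
* Symmetrization precedes thresholding (the construction narrative order).
* Disconnected pairs are excluded from L_w rather than imputed — the
  least-assumption option; the connected-pair count is logged per network.
* The integrated summary defaults to the range-normalized integral so that
  integrated values are on the same scale as per-threshold values; the raw
  integral is available via `normalize=False`.
* Between-subject similarity averages the two sessions by default, with a
  per-session option.
* The pipeline writes all floating output with 12 significant digits so
  that repeated runs with the same seed produce byte-identical tables.

## Problem sizes

Unit tests run on small cohorts (≤ 16 nodes) against brute-force oracles;
the end-to-end property checks run the full 78-node, 30-subject design —
per-edge reliability over all 3003 edges, and the complete 37-threshold ×
2-strategy × 2-normalization sweep (8 880 metric evaluations per cohort,
about half a minute) with the 10-seed qualitative replications reusing the
same machinery.

## Known limitations

* Absolute metric values depend on weighting conventions (no max-weight
  rescaling, length = 1/w); comparisons with other software must align those
  conventions first.  Only internal scale-consistency is asserted.
* ICC estimates at n = 30 subjects are noisy; qualitative statements
  (separate ≤ common under sparsity mismatch) are made over seed ensembles.
* No modeling of long-term or inter-site reliability; the generator's
  session noise represents short-interval repetition only.
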