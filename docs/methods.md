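# Methods

## Model

The core of `mirnca` is network component analysis (NCA): a
support-constrained matrix decomposition of a target-gene expression
time course. Let `E` be the `N x M` matrix of (log2) expression values
of `N` target genes at `M` time points, `C` the `N x L` matrix of
control strengths of `L` regulators (miRNAs and/or transcription
factors) on their targets, and `T` the `L x M` matrix of hidden
regulator activities. The model is

    E = C T,    C restricted to a fixed 0/1 support Z0,

with `Z0` taken from curated regulator→target databases. `C` and `T`
are estimated by minimizing the Frobenius residual `||E - C T||`
subject to `C` vanishing off the support. The solution is unique up to
a diagonal rescaling of the regulators when three structural criteria
hold:

1. the support admits a full-column-rank `C`;
2. removing any regulator together with all of its targets leaves a
   support that still admits full column rank;
3. `M >= L`, so `T` can have full row rank.

The model is linear in log-space and assumes the connectivity is
correct and complete for the modeled genes; both are idealizations of
curated databases.

## Estimation

`nca_decompose` uses two-step alternating least squares. With `T`
fixed, each target row of `C` is solved by ordinary least squares
restricted to that row's support (rows sharing a support pattern are
batched through the normal equations of the shared submatrix of `T`).
With `C` fixed, `T` is the full least-squares solution. Both half-steps
are exact minimizers, so the recorded per-iteration residual is
non-increasing; iteration stops when the relative residual change
drops below `tol` (default 1e-6) or at `max_iter` (default 500). `T` is
initialized with standard-normal entries; the best of `n_restarts`
(default 5) seeded restarts is kept. Singular values below 1e-8 of the
largest are treated as zero throughout (rank checks and the step-B
least squares).

Degenerate case: when a regulator carries no true signal, alternating
least squares can converge to a gauge in which that regulator's `C`
column is collinear with live columns and its activity row absorbs a
mixture of live activities while the residual stays at its optimum. A
post-convergence cleanup therefore zeroes any activity row whose
removal (with `C` re-fit once) leaves the residual unchanged within
1e-8 of the data norm, and flags the regulator in
`NCADecomposition.zero_activity`.

The scaling gauge is fixed by `normalize_decomposition`: each activity
row is scaled to max |value| = 1 and its sign chosen so that the
corresponding control-strength column has a non-negative sum (positive
on a tie); the inverse scale is absorbed into `C`, so the product `C T`
is preserved exactly. Exactly-zero activity rows are left at scale 1
and flagged.

`reduce_to_compatible` prunes an incompatible support greedily: at each
step the offending regulator with the smallest target set is removed
(ties lexicographic by ID) and orphaned targets are pruned, cascading
to regulators emptied by the pruning. When the violation carries no
per-regulator attribution (criteria 1 or 3), every remaining regulator
is a candidate and the same smallest-target-set rule picks the victim.
A fully duplicated regulator family collapses to a single surviving
regulator — a rank-1, identifiable network — rather than failing;
"no compatible sub-network" is raised only when pruning empties the
pattern. Greedy smallest-degree-first removal minimizes the number of
interactions lost per step; it is not guaranteed to find the maximum
compatible sub-network (finding that is combinatorial).

## Preprocessing

Raw two-channel replicate intensities pass through, in order:

1. **Loess within time point.** For each time point and replicate, the
   log ratio `M = log2(treatment/control)` is regressed on the mean
   intensity `A` with locally weighted regression (tricube weights,
   span 0.3, 2 robustifying iterations; `statsmodels` lowess) and the
   fitted trend is subtracted. The two channels are reconstructed
   symmetrically about `A`. At least 10 points are required. The span
   default is conventional for MA-trend removal; it is exposed as
   `loess_span`.
2. **Quantile normalization across all columns.** Every column (both
   conditions, all time points and replicates) is mapped by rank onto
   the reference distribution (row-means of the column-sorted matrix);
   tied values receive the mean of the reference values at their tied
   ranks. On tie-free columns the map is idempotent; tie-averaging
   makes repeated application contract tied groups, the same behaviour
   as limma's `normalizeQuantiles(ties = "mean")`. Being rank-based,
   the map compresses effects at the extreme ranks of a small gene
   universe: an up-shifted gene already at the top rank cannot exceed
   the reference maximum (observed as ~15% fold-change attenuation for
   a top-rank gene in a 120-gene universe).
3. **Differential expression.** Per time point, a two-sided two-sample
   t-test with pooled variance compares treatment and control
   replicates (with two replicates per condition a Welch correction
   would make the degrees of freedom unstable), and the linear fold
   change is `2**(mean_t - mean_c)` on the normalized log2 values. A
   gene is selected as differentially expressed when `|FC| > 1.5`
   (two-sided: `> 1.5` or `< 1/1.5`; repression matters as much as
   activation for miRNA analysis) and `p < 0.05` at two or more time
   points. Both groups constant and equal gives `p = 1` by convention.
   No multiple-testing correction is applied at this stage.
4. **Fourier smoothing.** Each differential time course is fit by least
   squares with a truncated Fourier series (period = grid span,
   `n_harmonics` = 4 by default, required `< (M-1)/2`), which suppresses
   measurement noise while preserving the smooth, possibly periodic
   responses expected after a growth-factor stimulus. Replicates are
   averaged after normalization.

## Networks and statistics

**Synergy network.** Two regulators are joined when the Pearson
correlation of their reconstructed (signed, normalized) activity
profiles is strictly greater than `pcc_threshold` (default 0.7) and
they share at least `min_shared` targets (default 3, counted on the
reduced connectivity actually used in the decomposition). Constant
activity rows have undefined correlation; they are recorded as 0 and
flagged. Edges carry `pcc` and `shared`; isolated regulators are
dropped.

**Integrated network.** The typed layers miRNA→TG, TF→TG, TF→miRNA and
the undirected synergy edges are unioned over a heterogeneous node set;
an entity may hold several roles (a TF can be another regulator's
target gene). Duplicate edges of one type between one pair collapse.
A node filter (typically the DEG list) restricts the target-gene side.
Hubs are ranked by total degree — in plus out, with each undirected
synergy incidence counting once — ties broken lexicographically.

**Topology statistics.** The clustering coefficient is the mean local
coefficient with degree<2 nodes contributing 0 (a flag switches to
excluding them); mean connectivity is `2|E|/|V|`; the power-law slope
is ordinary least squares of log10(count) on log10(degree) over
non-empty bins with degree >= `k_min` (a maximum-likelihood exponent
was considered and set aside: the log-log OLS slope is the quantity
directly comparable with the conventional reporting style).

**Null model.** Degree-preserving randomization applies double-edge
swaps with rejection of self-loops and multi-edges for a fixed budget
of attempts (default 10 per edge), preserving the exact degree
sequence; degree sequences with a single realization (a triangle) come
back unchanged. The randomization test reports the null mean, an
empirical p-value `(#null >= observed + 1)/(n_random + 1)`, and a
two-sided one-sample t-test of the null sample against the observed
value — the parametric figure is reported because the empirical
p-value cannot drop below `1/(n_random+1)` (~0.0099 at 100 nulls),
while clustering excesses in real synergy networks are far more
extreme than that floor.

**Timing and enrichment.** An entity is active at the time point where
its profile peaks — maximum absolute value by default, so repression
troughs count as activity (signed maximum behind a flag); target genes
are peaked on the smoothed log2 differential. Enrichment of a gene list
against GMT collections is the upper-tail hypergeometric probability
`P(X >= k)` over a user-supplied background (default: all genes on the
expression matrix); a set is called significant at `k >= 10` members
and `p < 0.001`. The EASE-style `k-1` penalization is available behind
a flag, default off.

## Synthetic data

The generator emulates the shape of a two-channel, two-replicate,
17-time-point (0–72 h) stimulation time course:

- a random bipartite connectivity with 3–8 targets per regulator,
  every target assigned at least one regulator, regenerated until the
  NCA criteria hold (or, on request, made incompatible by duplicating
  a target set);
- activities as random truncated Fourier series scaled to max |value|
  = 1 (the smooth peaked/periodic shapes reconstruction produces);
  full row rank requires `2*n_harmonics + 1 >= L`, which is enforced
  and auto-raised by the bundle generator;
- control strengths uniform on ±[0.2, 2] — bounded away from zero so
  every planted interaction is structurally meaningful — with balanced
  random signs (miRNAs repress; TFs go both ways; balance also keeps
  the normalization steps unbiased, as in real balanced designs);
- expression `E = C T` plus i.i.d. Gaussian log2 noise (sd 0.1 by
  default); the Gaussian choice is an assumption of the generator, not
  a claim about any particular platform;
- raw replicate intensities around per-gene baselines uniform on
  log2 [6, 12], with a smooth intensity-dependent log-ratio bias of
  amplitude 0.5 on the treatment channel (exercising loess) and a
  per-column affine gain/offset distortion (exercising quantile
  normalization).

Default scale is L=10 regulators, N=120 genes, M=17 time points — the
smallest at which criteria checks and recovery are non-trivial while
the suite runs in seconds. Everything is deterministic under a fixed
seed; the pipeline splits one root seed into per-stage seeds.

What the generator does *not* emulate: probe-level microarray physics,
probe-to-gene mapping, missing values, correlated (gene-block) noise,
database errors in the connectivity, and the true (unknown) noise law
of real arrays. Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated statistical structure,
not performance guarantees on any real dataset.

## Measured behaviour (recomputed by tests and `scripts/acceptance.py`)

Problem sizes were chosen so each check runs in seconds: recovery at
L=10/N=120/M=17 over 10 seeds; convergence over 100 seeded runs at
L=3/N=15; criteria-oracle agreement on random patterns with L<=6,
N<=15; graph-statistic oracles on all 4-node graphs plus random graphs
up to 8 nodes; enrichment exactness for backgrounds up to 50; null
calibration over 50 Erdős–Rényi repetitions. Under those conditions
the suite measures: mean |activity correlation| ≈ 1.00 at 5% noise
(noiseless residual at machine precision), zero monotonicity
violations, 100% oracle agreement, zero graph-statistic error, exact
−2.0 slope on exact power-law input, planted-triangle empirical
p ≈ 0.0099 at 100 nulls, hypergeometric error at machine precision,
and DEG recovery at ≥90% sensitivity with ≤10% FDR.

## Known limitations

- Greedy reduction is not guaranteed minimal; an adversarial support
  could lose more regulators than necessary.
- The decomposition is identifiable only up to the diagonal gauge; all
  comparisons of activities across runs must use the canonical
  normalization (or correlation, which is scale-free).
- No confidence intervals on activities; no sparse/Bayesian variants;
  no sign constraints on miRNA control strengths (canonically
  repressive) — a deliberate default, available to revisit since real
  miRNA action is predominantly but not exclusively repressive.
- The synergy rule's strict `> 0.7` correlation and `>= 3` shared
  targets are conventions, exposed as configuration.
- Quantile normalization's tail compression (above) biases fold
  changes of genes at the extreme ranks of small universes.
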