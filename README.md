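# mirnca

Temporal miRNA and transcription-factor activity reconstruction from
target-gene expression time series, with synergy- and integrated-network
analysis.

miRNA activity is rarely measured directly in time-course experiments,
but its footprint is visible in the expression of target genes. Given a
log2 expression matrix `E` (N target genes × M time points) and a curated
regulator→target connectivity `Z0` (e.g. miRTarBase for miRNA→TG, TFacts
or ChIP compendia for TF→TG), network component analysis (NCA) recovers
both the control strengths `C` and the hidden temporal activities `T`:

    E = C T      s.t.  C ∈ Z0          (support-constrained least squares)
    min ‖E − C T‖_F

The decomposition is identifiable up to per-regulator scaling whenever
(1) the support admits full column rank, (2) it keeps full column rank
after removing any one regulator with all of its targets, and (3) M ≥ L.
The package checks these criteria, prunes incompatible networks to a
compatible sub-network, solves the decomposition by alternating least
squares, and canonically normalizes the result (each activity scaled to
max |value| = 1).

Downstream of the decomposition it builds the miRNA–miRNA *synergistic
network* (edges between regulators with activity correlation > 0.7 and
≥ 3 shared targets), assembles the integrated miRNA/TF/target network,
ranks hub regulators by total degree, tests topology statistics against
degree-preserving random networks, assigns peak-activity time points,
and runs hypergeometric gene-set enrichment on GMT collections.

A synthetic-data module generates connectivity patterns, ground-truth
activities and raw two-channel replicate arrays with realistic
normalization artifacts, so the whole pipeline is testable without any
downloads.

Intended users: computational biologists analyzing stimulation
time-course expression data who want regulator dynamics rather than a
static network.

## Worked example

Simulate a study (8 regulators, 80 genes, 17 time points over 72 h,
two replicates per condition) and run the full seven-stage pipeline:

```
$ mirnca simulate bundle --regulators 8 --targets 80 --seed 3
bundle written to bundle
$ mirnca run --control bundle/control.tsv --treatment bundle/treatment.tsv \
      --mirna-tg bundle/mirna_tg.tsv --tf-tg bundle/tf_tg.tsv \
      --tf-mirna bundle/tf_mirna.tsv --out out --seed 3
7/7 stages completed -> out
```

`out/manifest.json` records what each stage did:

```
{'name': 'preprocess', 'status': 'completed', 'n_genes': 80, 'n_degs': 31}
{'name': 'reduce',     'status': 'completed', 'n_regulators': 8, 'n_targets': 31, 'n_removed': 0}
{'name': 'nca',        'status': 'completed', 'converged': True, 'n_iter': 9}
{'name': 'synergy',    'status': 'completed', 'n_nodes': 0, 'n_edges': 0}
{'name': 'integrate',  'status': 'completed', 'n_nodes': 43, 'n_edges': 54}
{'name': 'netstats',   'status': 'completed', 'clustering_coefficient': 0.0}
{'name': 'downstream', 'status': 'completed', 'tg_mirna_count_correlation': 0.9339093122544945}
```

Reading the numbers: 31 of 80 genes pass the DEG rule (|fold change| >
1.5 and p < 0.05 at ≥ 2 time points — the planted effect genes); the
connectivity restricted to those DEGs already satisfies the NCA
criteria, so nothing is pruned; alternating least squares converges in
9 iterations; the 8 independent random activities produce no synergy
edges (a real study's hundreds of co-regulating miRNAs do — see the
thresholds above); and the per-time-point counts of peaking target
genes track the counts of peaking miRNA activities with Pearson
r = 0.93, the cascade signature of a stimulus propagating through the
regulatory layers.

`out/activities.tsv` holds the reconstructed activity profiles, e.g.

```
gene    0             10            15            30           ...
mir-003 0.9723646703  0.9449840783  0.9309231203  0.8874177453 ...
mir-002 0.3205470549  0.37888176    0.4072747649  0.4891781851 ...
```

each row normalized to max |value| = 1, sign fixed so the regulator's
control-strength column sums non-negative.

Individual stages are also exposed (`mirnca nca`, `synergy`, `stats`,
`enrich`) and the whole library is importable:

```python
import mirnca as m
truth = m.generate_ground_truth(n_regulators=10, n_targets=120, seed=7)
E = m.generate_expression(truth)
dec = m.nca_decompose(E, truth.Z0, seed=1)
dec.activities(truth.grid.times)   # DataFrame, regulators x time points
```

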