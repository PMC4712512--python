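"""End-to-end pipeline orchestration.

Seven stages run in order: preprocessing, reduction of the connectivity
pattern to an NCA-compatible sub-network, the decomposition itself,
synergy-network construction, integrated-network assembly, topology
statistics with the degree-preserving null, and the downstream timing /
enrichment analyses. Every stage writes its outputs as plain text under
the output directory, and a JSON manifest records the config, stage
seeds and completion status, so that re-running with the same seed and
config reproduces every file byte for byte. A stage failure halts the
run, leaves earlier outputs in place, and drops a FAILED marker naming
the stage and cause.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as mio
from . import __version__
from .config import PipelineConfig
from .downstream import (
    active_counts,
    assign_peaks,
    count_correlation,
    hypergeometric_enrichment,
)
from .nca import ConnectivityPattern, nca_decompose, reduce_to_compatible
from .networks import build_integrated_network, build_synergy_network, hub_ranking
from .netstats import (
    clustering_coefficient,
    degree_distribution,
    mean_connectivity,
    powerlaw_slope,
    randomization_test,
)
from .preprocess import preprocess_experiment
from .synthetic import (
    RawMicroarray,
    TimeGrid,
    default_grid,
    generate_connectivity,
    generate_expression,
    generate_ground_truth,
    generate_raw_microarray,
)

STAGES = (
    "preprocess",
    "reduce",
    "nca",
    "synergy",
    "integrate",
    "netstats",
    "downstream",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministically split one root seed into per-stage seeds."""
    children = np.random.SeedSequence(root_seed).spawn(len(STAGES))
    return {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)
    }


def simulate_bundle(
    outdir,
    n_regulators: int = 10,
    n_targets: int = 120,
    noise_sd: float = 0.1,
    effect_fraction: float = 0.5,
    bias_amplitude: float = 0.5,
    n_replicates: int = 2,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic input bundle for the pipeline.

    The bundle holds raw control/treatment replicate TSVs, the miRNA->TG
    adjacency list, a small TF layer (TF->TG and TF->miRNA adjacency),
    and the planted truth (C, T, noiseless expression) for recovery
    checks. ``effect_fraction`` of the genes carry the planted
    differential signal.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_ground_truth(
        n_regulators=n_regulators, n_targets=n_targets, noise_sd=noise_sd, seed=seed
    )
    E = generate_expression(truth)
    genes = truth.Z0.targets
    rng = np.random.default_rng((seed, 0xF))
    n_effect = max(1, int(round(effect_fraction * len(genes))))
    effect = sorted(rng.choice(genes, size=n_effect, replace=False).tolist())
    truth.effect_genes = effect
    raw = generate_raw_microarray(
        E,
        genes,
        truth.grid,
        n_replicates=n_replicates,
        bias_amplitude=bias_amplitude,
        effect_genes=effect,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    mio.write_replicates_tsv(out / "control.tsv", raw.control, genes, truth.grid)
    mio.write_replicates_tsv(out / "treatment.tsv", raw.treatment, genes, truth.grid)
    mio.write_adjacency(out / "mirna_tg.tsv", truth.Z0.to_edges())

    # small TF layer on the same targets: TF->TG plus TF->miRNA edges
    tf_rng = np.random.default_rng((seed, 0xAF))
    n_tfs = max(3, n_regulators // 2)
    tf_ids = [f"TF-{j + 1:02d}" for j in range(n_tfs)]
    tf_tg = []
    for tf in tf_ids:
        for tg in tf_rng.choice(genes, size=min(6, len(genes)), replace=False):
            tf_tg.append((tf, tg))
    tf_mirna = [
        (tf, mir)
        for tf in tf_ids
        for mir in tf_rng.choice(truth.Z0.regulators, size=2, replace=False)
    ]
    mio.write_adjacency(out / "tf_tg.tsv", sorted(set(tf_tg)))
    mio.write_adjacency(out / "tf_mirna.tsv", sorted(set(tf_mirna)))

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    import pandas as pd

    times = list(truth.grid.times)
    mio.write_expression_tsv(
        truth_dir / "expression.tsv", pd.DataFrame(E, index=genes, columns=times)
    )
    mio.write_expression_tsv(
        truth_dir / "activities.tsv",
        pd.DataFrame(truth.T_true, index=truth.Z0.regulators, columns=times),
    )
    mio.write_expression_tsv(
        truth_dir / "control_strengths.tsv",
        pd.DataFrame(
            truth.C_true, index=genes, columns=[float(i) for i in range(n_regulators)]
        ),
    )
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "kind": "synthetic-bundle",
                "seed": seed,
                "n_regulators": n_regulators,
                "n_targets": len(genes),
                "noise_sd": noise_sd,
                "effect_genes": effect,
                "n_replicates": n_replicates,
                "times": times,
            },
            indent=1,
        )
    )
    return out


def run_pipeline(config: PipelineConfig, inputs: dict, outdir) -> dict:
    """Run all seven stages on a bundle of input paths.

    ``inputs`` maps names to paths: ``control``, ``treatment`` (raw
    replicate TSVs), ``mirna_tg`` (adjacency; required), and optionally
    ``tf_tg``, ``tf_mirna`` and ``gmt``. Returns the manifest dict
    (also written to ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "tool": "mirnca",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "stages": [],
    }
    state: dict = {}
    runners = {
        "preprocess": _run_preprocess,
        "reduce": _run_reduce,
        "nca": _run_nca,
        "synergy": _run_synergy,
        "integrate": _run_integrate,
        "netstats": _run_netstats,
        "downstream": _run_downstream,
    }
    for stage in STAGES:
        try:
            info = runners[stage](config, inputs, out, state, seeds[stage])
        except Exception as exc:  # halt, keep partial outputs, mark failure
            manifest["stages"].append({"name": stage, "status": "FAILED",
                                       "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise StageError(stage, exc) from exc
        manifest["stages"].append({"name": stage, "status": "completed", **info})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_preprocess(config, inputs, out, state, seed):
    import pandas as pd

    for key in ("control", "treatment", "mirna_tg"):
        if key not in inputs or not Path(inputs[key]).exists():
            raise FileNotFoundError(f"missing input {key!r}: {inputs.get(key)}")
    ctrl, genes, grid = mio.read_replicates_tsv(inputs["control"])
    trt, genes2, _ = mio.read_replicates_tsv(inputs["treatment"])
    if genes != genes2:
        raise ValueError("control and treatment gene lists differ")
    raw = RawMicroarray(
        genes=genes, grid=grid, control=ctrl, treatment=trt,
        effect_genes=[], planted_lfc=np.zeros(ctrl.shape[:2]),
    )
    res = preprocess_experiment(
        raw,
        span=config.loess_span,
        n_harmonics=config.n_harmonics,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
        min_timepoints=config.min_timepoints,
    )
    state["preprocess"] = res
    mio.write_expression_tsv(out / "differential.tsv", res.differential)
    mio.write_expression_tsv(out / "smoothed.tsv", res.smoothed)
    res.degs.table.to_csv(out / "deg_table.tsv", sep="\t", index=False,
                          float_format=mio.FLOAT_FMT)
    (out / "deg_selected.txt").write_text(
        "".join(g + "\n" for g in res.degs.selected_genes)
    )
    return {"n_genes": len(genes), "n_degs": len(res.degs.selected_genes)}


def _run_reduce(config, inputs, out, state, seed):
    edges = mio.read_adjacency(inputs["mirna_tg"])
    degs = set(state["preprocess"].degs.selected_genes)
    kept = [(r, t) for r, t in edges if t in degs] or edges
    Z0 = ConnectivityPattern.from_edges(kept)
    reduced, log = reduce_to_compatible(
        Z0, n_timepoints=len(state["preprocess"].grid), seed=seed
    )
    state["Z0"] = reduced
    mio.write_adjacency(out / "connectivity_reduced.tsv", reduced.to_edges())
    (out / "reduction_log.json").write_text(json.dumps(log, indent=1))
    return {"n_regulators": reduced.n_regulators, "n_targets": reduced.n_targets,
            "n_removed": len(log)}


def _run_nca(config, inputs, out, state, seed):
    import pandas as pd

    res = state["preprocess"]
    dec = nca_decompose(
        res.smoothed,
        state["Z0"],
        tol=config.nca_tol,
        max_iter=config.nca_max_iter,
        n_restarts=config.nca_restarts,
        seed=seed,
    )
    state["nca"] = dec
    times = list(res.grid.times)
    mio.write_expression_tsv(out / "activities.tsv", dec.activities(times))
    mio.write_expression_tsv(
        out / "control_strengths.tsv",
        pd.DataFrame(dec.C, index=dec.targets,
                     columns=[float(i) for i in range(len(dec.regulators))]),
    )
    (out / "nca_log.json").write_text(json.dumps({
        "converged": dec.converged,
        "n_iter": dec.n_iter,
        "residual_trace": dec.residual_trace,
        "zero_activity": dec.zero_activity,
    }, indent=1))
    return {"converged": dec.converged, "n_iter": dec.n_iter}


def _run_synergy(config, inputs, out, state, seed):
    dec = state["nca"]
    g = build_synergy_network(
        dec.activities(),
        state["Z0"],
        pcc_threshold=config.pcc_threshold,
        min_shared=config.min_shared,
    )
    state["synergy"] = g
    mio.write_synergy_tsv(out / "synergy.tsv", g)
    return {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}


def _run_integrate(config, inputs, out, state, seed):
    mirna_tg = state["Z0"].to_edges()
    tf_tg = mio.read_adjacency(inputs["tf_tg"]) if inputs.get("tf_tg") else []
    tf_mirna = mio.read_adjacency(inputs["tf_mirna"]) if inputs.get("tf_mirna") else []
    degs = set(state["preprocess"].degs.selected_genes) | set(state["Z0"].targets)
    net = build_integrated_network(
        mirna_tg, tf_tg, tf_mirna, synergy=state["synergy"], node_filter=degs
    )
    state["integrated"] = net
    mio.write_integrated_sif(out / "integrated.sif", net)
    hubs = {
        role: hub_ranking(net, role, top_k=20) for role in ("miRNA", "TF", "TG")
    }
    (out / "hubs.json").write_text(json.dumps(hubs, indent=1))
    return {"n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.number_of_edges()}


def _run_netstats(config, inputs, out, state, seed):
    g = state["synergy"]
    report = {
        "clustering_coefficient": clustering_coefficient(g),
        "mean_connectivity": mean_connectivity(g),
        "degree_distribution": degree_distribution(g),
    }
    try:
        report["powerlaw_slope"] = powerlaw_slope(report["degree_distribution"])
    except ValueError as exc:
        report["powerlaw_slope"] = None
        report["powerlaw_note"] = str(exc)
    if g.number_of_edges() >= 2:
        rand = randomization_test(
            g, "clustering_coefficient", n_random=config.n_random, seed=seed
        )
        report["randomization"] = {
            "observed": rand.observed_stat,
            "mean_null": rand.mean_null,
            "p_value": rand.p_value,
            "empirical_p": rand.empirical_p,
        }
        with open(out / "null_clustering.tsv", "w") as fh:
            fh.write("clustering_coefficient\n")
            fh.writelines(mio.FLOAT_FMT % x + "\n" for x in rand.null_stats)
    report["degree_distribution"] = {
        str(k): v for k, v in report["degree_distribution"].items()
    }
    (out / "netstats.json").write_text(json.dumps(report, indent=1))
    return {"clustering_coefficient": report["clustering_coefficient"]}


def _run_downstream(config, inputs, out, state, seed):
    res = state["preprocess"]
    dec = state["nca"]
    grid = res.grid
    deg_genes = res.degs.selected_genes or res.genes
    tg_profiles = res.smoothed.loc[deg_genes]
    assignments = assign_peaks(tg_profiles, "TG", grid)
    assignments += assign_peaks(dec.activities(grid.times), "miRNA", grid)
    counts = active_counts(assignments, grid)
    counts.to_csv(out / "active_counts.tsv", sep="\t")
    corr = None
    if counts["TG"].std() > 0 and counts["miRNA"].std() > 0:
        corr = count_correlation(counts["TG"], counts["miRNA"])
    info: dict = {"tg_mirna_count_correlation": corr}
    if inputs.get("gmt"):
        sets = mio.read_gmt(inputs["gmt"])
        enr = hypergeometric_enrichment(
            set(deg_genes) & set(res.genes),
            sets,
            background=res.genes,
            min_overlap=config.min_overlap,
            alpha=config.alpha,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format=mio.FLOAT_FMT)
        info["n_significant_sets"] = int(enr["significant"].sum())
    (out / "timing.json").write_text(json.dumps(info, indent=1))
    return info
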