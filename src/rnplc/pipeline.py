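"""End-to-end orchestration of the interactome pipeline from one config.

Stages: simulate (optional) -> normalize -> call-hcip -> classify ->
coelute -> assemble -> annotate -> stoichiometry -> resample -> bridge ->
prey-profiles -> jaccard. Every stage writes TSV outputs under the
configured output directory, and a JSON run report records seeds,
parameters and per-stage counts. Runs are deterministic per seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import bridge as bridge_mod
from . import cooccurrence, io, prey, resampling, sec, simulate, tmt
from . import hcip as hcip_mod
from . import network as network_mod

log = logging.getLogger("rnplc")


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults for every knob."""

    outdir: str = "rnplc_out"
    seed: int = 0
    simulate: bool = True
    # HCIP thresholds
    z_threshold: float = 1.645
    ratio_threshold: float = 1.0
    alpha: float = 0.05
    sparsity_frac: float = 0.5
    # co-elution
    apex_delta: int = 2
    coelution_window: int = 5
    q_threshold: float = 0.1
    n_decoys: int = 500
    # resampling
    n_resamples: int = 1000
    # prey clustering
    n_prey_clusters: int = 0  # 0 -> one per observed step
    # co-occurrence
    n_random_pairs: int = 1000
    # generator overrides (names of SimConfig fields)
    sim: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        sim_known = {f.name for f in fields(simulate.SimConfig)}
        bad = set(cfg.sim) - sim_known
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")
        return cfg

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(**{**self.sim, "seed": self.seed})


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "parameters": asdict(config)}

    if not config.simulate:
        raise NotImplementedError(
            "file-driven runs use the individual CLI subcommands; run-all operates "
            "on the synthetic study"
        )

    sim_cfg = config.sim_config()
    truth = simulate.make_truth(sim_cfg)
    truth.edges_frame().to_csv(outdir / "truth_edges.tsv", sep="\t", index=False)
    io.write_step_table(truth.bait_steps, outdir / "bait_steps.tsv")
    raw = simulate.simulate_ip(truth, sim_cfg)
    io.write_intensity_table(raw, outdir)
    report["stages"]["simulate"] = {
        "n_proteins": int(raw.values.shape[0]),
        "n_samples": int(raw.values.shape[1]),
        "n_true_edges": len(truth.true_edges),
    }
    log.info("simulated %d proteins x %d samples", *raw.values.shape)

    norm = tmt.normalize(raw)
    io.write_matrix(norm.values, outdir / "normalized.tsv")
    failed = tmt.flag_failed_ips(
        norm, z_threshold=config.z_threshold, sparsity_frac=config.sparsity_frac
    )
    failed.frame().to_csv(outdir / "failed_ips.tsv", sep="\t", index=False)
    report["stages"]["normalize"] = {
        "n_failed_ip_sets": int((~failed.frame()["passed"]).sum())
    }

    params = hcip_mod.HCIPParams(
        z_threshold=config.z_threshold,
        ratio_threshold=config.ratio_threshold,
        alpha=config.alpha,
    )
    typed_edges, calls = hcip_mod.call_all_baits(norm, failed, params)
    calls.to_csv(outdir / "hcip_calls.tsv", sep="\t", index=False)
    typed_edges.to_csv(outdir / "typed_edges.tsv", sep="\t", index=False)
    report["stages"]["hcip"] = {
        "n_edges": len(typed_edges),
        "by_type": typed_edges["ip_type"].value_counts().to_dict(),
    }
    log.info("called %d typed edges", len(typed_edges))

    ip_net = network_mod.build_ip_network(typed_edges)
    sec_reps, calib = simulate.simulate_sec(truth, sim_cfg)
    calib.to_csv(outdir / "sec_calibration.tsv", sep="\t", index=False)
    candidates = [
        (a, b) for a, b in ip_net.pair_set()
    ] + [
        (m[i], m[j])
        for m, _ in truth.complexes
        for i in range(len(m))
        for j in range(i + 1, len(m))
    ]
    candidates = sorted({network_mod.canonical_pair(a, b) for a, b in candidates})
    coel = sec.call_coelution(
        sec_reps,
        candidates,
        n_decoys=config.n_decoys,
        seed=config.seed,
        params=sec.CoelutionParams(
            apex_delta=config.apex_delta,
            window=config.coelution_window,
            q_threshold=config.q_threshold,
        ),
    )
    coel.to_csv(outdir / "coelution.tsv", sep="\t", index=False)
    sec_pairs = [
        (r["protein_a"], r["protein_b"]) for _, r in coel.iterrows() if r["called"]
    ]
    report["stages"]["coelution"] = {
        "n_candidates": len(candidates),
        "n_called": len(sec_pairs),
    }

    net = network_mod.merge_ip_sec(ip_net, sec_pairs)
    reference = {network_mod.canonical_pair(b, p) for b, p, _ in truth.true_edges}
    net = network_mod.annotate_reference_support(net, {"truth": reference})
    network_mod.export_network(net, str(outdir / "network.tsv"), "tsv")
    network_mod.export_network(net, str(outdir / "network.graphml"), "graphml")
    report["stages"]["assemble"] = {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_dual_support": int((net.edges["ip_support"] & net.edges["sec_support"]).sum()),
    }

    total = simulate.simulate_total_proteome(truth, sim_cfg)
    stoich = network_mod.interaction_stoichiometry(typed_edges, raw, total)
    stoich.to_csv(outdir / "stoichiometry.tsv", sep="\t", index=False)
    report["stages"]["stoichiometry"] = {"n_records": len(stoich)}

    edges_bp = list(zip(typed_edges["bait"], typed_edges["prey"]))
    if edges_bp:
        res = resampling.resampling_test(
            edges_bp,
            reference,
            universe=list(truth.preys),
            n=config.n_resamples,
            seed=config.seed,
        )
        resampling.resampling_summary({"all_edges": res}).to_csv(
            outdir / "resampling.tsv", sep="\t", index=False
        )
        report["stages"]["resampling"] = {
            "f_exp": res.f_exp, "p_value": res.p_value, "fold": res.fold,
        }

    graph = net.to_networkx()
    steps = {
        b: s for b, s in truth.bait_steps.items()
        if b != truth.control_bait and b in graph
    }
    try:
        scores = bridge_mod.bridge_score_all_steps(graph, steps)
        score_frame = pd.DataFrame(
            {
                "all_steps": pd.Series(scores.all_steps),
                "balanced": pd.Series(scores.balanced),
            }
        ).sort_values("balanced", ascending=False)
        io.write_matrix(score_frame, outdir / "bridge_scores.tsv", index_name="protein")
        report["stages"]["bridge"] = {
            "top_balanced": score_frame.index[0] if len(score_frame) else None,
        }
    except ValueError as exc:
        report["stages"]["bridge"] = {"skipped": str(exc)}

    profiles = prey.prey_step_profiles(typed_edges, truth.bait_steps)
    assigned = prey.assign_prey_steps(
        profiles, k=config.n_prey_clusters or None
    )
    assigned.to_csv(outdir / "prey_profiles.tsv", sep="\t")
    incidence = prey.prey_incidence(typed_edges)
    corr, _, order = prey.prey_correlation_matrix(incidence)
    io.write_matrix(corr.loc[order, order], outdir / "prey_correlation.tsv")
    report["stages"]["prey"] = {
        "n_preys": len(profiles),
        "multi_step_fraction": float(assigned["multi_step"].mean()),
    }

    sites = simulate.simulate_binding_sites(truth, sim_cfg)
    io.write_bed(simulate.binding_sites_to_bed(sites), outdir / "binding_sites")
    summary, _, _ = cooccurrence.typewise_jaccard_comparison(
        typed_edges, sites, n_random=config.n_random_pairs, seed=config.seed
    )
    summary.to_csv(outdir / "jaccard_by_type.tsv", sep="\t", index=False)
    report["stages"]["jaccard"] = {
        "medians": dict(zip(summary["ip_type"], summary["median_jaccard"]))
    }

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
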