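"""End-to-end orchestration: normalize -> DE -> modules -> context GRNs
-> differential topology -> master regulators.

Every stage writes its table(s) into the output directory and records
counts in a RunReport.  Runs are fully deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .coexpression import (CoexpressionConfig, detect_modules, module_activity,
                           ora_modules, select_soft_threshold)
from .expression import differential_expression, normalize
from .grn import (build_context_grn, compare_grns, merge_reference_networks,
                  module_subnetwork, select_varying_genes)
from .master_regulators import MRConfig, identify_master_regulators

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str = ""
    design: str = ""
    reference_networks: list[str] = field(default_factory=list)
    ppi: str = ""
    gmt: str | None = None
    condition_a: str | None = None  # baseline (healthy)
    condition_b: str | None = None  # contrast (disease)
    tau_expr: float = 10.0
    lfc_min: float = 1.0
    alpha: float = 0.05
    f1_max: float = 0.99
    beta: int | None = None  # None -> automatic scale-free selection
    coexpression: CoexpressionConfig = field(default_factory=CoexpressionConfig)
    mr: MRConfig = field(default_factory=MRConfig)
    rng_seed: int = 0
    outdir: str = "perionet_out"
    include_timestamp: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        coex = CoexpressionConfig(**raw.pop("coexpression", {}))
        mr = MRConfig(**raw.pop("mr", {}))
        return cls(coexpression=coex, mr=mr, **raw)

    def validate(self) -> None:
        for name in ("counts", "design", "ppi"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} missing: {p}")
        for p in self.reference_networks:
            if not Path(p).exists():
                raise FileNotFoundError(f"reference network missing: {p}")
        if self.gmt and not Path(self.gmt).exists():
            raise FileNotFoundError(f"GMT file missing: {self.gmt}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the RunReport dict (also written as
    run_report.json)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "stages": {},
    }
    if config.include_timestamp:
        report["timestamp"] = datetime.datetime.now().isoformat()

    counts = io.read_counts(config.counts, config.design)
    conds = counts.conditions
    cond_a = config.condition_a or conds[0]
    cond_b = config.condition_b or next(c for c in conds if c != cond_a)
    report["stages"]["input"] = {
        "n_genes": len(counts.genes), "n_samples": len(counts.samples),
        "conditions": [cond_a, cond_b],
    }

    norm = normalize(counts)
    io.write_table(norm.size_factors.to_frame(), out / "size_factors.tsv")
    io.write_table(norm.values, out / "normalized.tsv")

    de = differential_expression(norm, cond_a, cond_b,
                                 lfc_min=config.lfc_min, alpha=config.alpha)
    io.write_table(de, out / "de.tsv")
    report["stages"]["de"] = {
        "n_up": int((de["status"] == "up").sum()),
        "n_down": int((de["status"] == "down").sum()),
        "n_ns": int((de["status"] == "ns").sum()),
    }

    if config.beta is None:
        beta_res = select_soft_threshold(norm, config.coexpression)
        beta = beta_res.effective_beta
        report["stages"]["soft_threshold"] = {
            "beta": beta, "flagged": beta_res.flagged}
    else:
        beta = config.beta
        report["stages"]["soft_threshold"] = {"beta": beta, "flagged": False}
    modules = detect_modules(norm, beta, config.coexpression)
    io.write_table(modules.to_frame("module"), out / "modules.tsv")
    sizes = modules[modules != "unassigned"].value_counts()
    report["stages"]["modules"] = {
        "n_modules": int(len(sizes)),
        "n_assigned": int(sizes.sum()),
        "n_unassigned": int((modules == "unassigned").sum()),
    }
    activity = module_activity(norm, modules, counts.design)
    io.write_table(activity, out / "module_activity.tsv")

    if config.gmt:
        gene_sets = io.read_gmt(config.gmt)
        enrich = ora_modules(modules, gene_sets, universe=counts.genes)
        io.write_table(enrich, out / "ora.tsv", index=False)
        report["stages"]["ora"] = {"n_tests": int(len(enrich))}

    tables = [io.read_edges(p) for p in config.reference_networks]
    names = [Path(p).stem for p in config.reference_networks]
    reference = merge_reference_networks(tables, names)
    report["stages"]["reference"] = {
        "n_tfs": len(reference.tfs),
        "n_edges": reference.graph.number_of_edges(),
    }

    grns = {}
    for label, cond in (("A", cond_a), ("B", cond_b)):
        samples = counts.samples_of(cond)
        grn = build_context_grn(reference, norm, samples,
                                tau_expr=config.tau_expr, context=cond)
        grns[label] = grn
        io.write_sif(grn.graph, out / f"grn_{cond}.sif")
        report["stages"][f"grn_{cond}"] = {
            "n_edges_retained": grn.graph.number_of_edges(),
            "n_edges_removed": (reference.graph.number_of_edges()
                                - grn.graph.number_of_edges()),
        }

    combined = compare_grns(grns["A"], grns["B"], tfs=reference.tfs)
    io.write_table(combined.node_table(), out / "combined_nodes.tsv",
                   index=False)
    io.write_table(combined.edge_table(), out / "combined_edges.tsv",
                   index=False)
    io.write_graphml(combined.graph, out / "combined.graphml")
    varying = select_varying_genes(combined, config.f1_max)
    (out / "varying_genes.tsv").write_text(
        "gene\n" + "".join(f"{g}\n" for g in varying))
    sub = module_subnetwork(combined, modules, de)
    io.write_sif(sub, out / "module_subnetwork.sif")
    report["stages"]["combined"] = {
        "n_nodes": combined.graph.number_of_nodes(),
        "n_edges": combined.graph.number_of_edges(),
        "n_varying": len(varying),
        "module_subnetwork_nodes": sub.number_of_nodes(),
        "module_subnetwork_isolates_removed":
            sub.graph.get("n_isolates_removed", 0),
    }

    ppi = io.read_ppi(config.ppi)
    mr_report = identify_master_regulators(
        combined, modules, norm, ppi, de, config.mr, tfs=reference.tfs)
    io.write_table(mr_report.table, out / "mr_table.tsv", index=False)
    io.write_sif(mr_report.mr_subnetwork, out / "mr_subnetwork.sif")
    io.write_graphml(_with_mr_attrs(mr_report), out / "mr_subnetwork.graphml")
    rows = [{"tf": tf, "rank": i + 1, "target": t}
            for tf in sorted(mr_report.top_targets)
            for i, t in enumerate(mr_report.top_targets[tf])]
    io.write_table(__import__("pandas").DataFrame(
        rows, columns=["tf", "rank", "target"]), out / "mr_top_targets.tsv",
        index=False)
    report["stages"]["master_regulators"] = {
        "n_mrs": len(mr_report.mr_set),
        "n_edges": mr_report.mr_subnetwork.number_of_edges(),
    }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _with_mr_attrs(mr_report):
    g = mr_report.mr_subnetwork.copy()
    by_tf = mr_report.table.set_index("tf")
    for n in g:
        if n in by_tf.index:
            g.nodes[n]["u"] = float(by_tf.loc[n, "u"])
            g.nodes[n]["condition_call"] = str(
                by_tf.loc[n, "condition_call"])
    return g
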