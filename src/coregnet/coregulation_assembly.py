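"""Assembly of the TF-miRNA coregulation network, the miRNA-target
anticorrelation check, and the end-to-end pipeline driver.

The coregulation network keeps exactly the modules that retain both a TF
regulator and a miRNA regulator. It is a typed graph: module genes
(``gene``; assigned TFs are typed ``tf``), regulator miRNAs (``mirna``),
gene-gene coexpression edges inside modules, and miRNA->gene edges for
consensus targets within the regulated module.

The anticorrelation check computes, for every regulator miRNA, the Pearson
correlation between its expression profile and each of its in-module target
genes across matched samples, and labels the miRNA ``negative`` when the
median target correlation is below zero — the expected signature of a
repressive miRNA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from coregnet import data_io
from coregnet.coexpression_network import build_network
from coregnet.data_io import ExpressionMatrix, SampleLabels
from coregnet.differential_expression import call_differential, significant_features
from coregnet.enrichment import filter_modules_by_deg
from coregnet.module_detection import DetectionParams, Module, detect_modules, merge_by_one_third_rule
from coregnet.regulator_inference import (
    RegulatorAssignment,
    assign_regulators,
    build_consensus_targets,
)

logger = logging.getLogger(__name__)


@dataclass
class CoregulationNetwork:
    """The tripartite TF/miRNA/gene network over coregulated modules."""

    graph: nx.Graph
    modules: dict[int, frozenset[str]]
    mirna_regulators: dict[int, tuple[tuple[str, float], ...]]
    tf_regulators: dict[int, tuple[str, ...]]
    module_targets: dict[tuple[int, str], frozenset[str]]  # (module_id, mirna) -> in-module targets
    summary: pd.DataFrame

    @property
    def n_modules(self) -> int:
        return len(self.modules)


@dataclass
class AnticorrelationReport:
    """Per-pair and per-miRNA correlation summary of regulator miRNAs."""

    pairs: pd.DataFrame  # module_id, mirna_id, gene_id, r
    summary: pd.DataFrame  # module_id, mirna_id, n_targets, median_r, mean_r, direction


def build_coregulation_network(
    retained_modules: list[Module],
    assignments: Mapping[int, RegulatorAssignment],
    targets: dict[str, frozenset[str]],
    network: nx.Graph,
) -> CoregulationNetwork:
    """Assemble the coregulation network from modules with both regulator kinds.

    Modules lacking a TF or a miRNA regulator are dropped. Every
    miRNA->gene edge is checked against the consensus target map; node
    types are mutually exclusive except that an assigned TF is a module
    gene typed ``tf``.
    """
    keep = [m for m in retained_modules if assignments[m.module_id].coregulated]
    if not keep:
        logger.warning("no module is coregulated by both a TF and a miRNA")

    g = nx.Graph()
    modules: dict[int, frozenset[str]] = {}
    mirna_regs: dict[int, tuple[tuple[str, float], ...]] = {}
    tf_regs: dict[int, tuple[str, ...]] = {}
    module_targets: dict[tuple[int, str], frozenset[str]] = {}
    membership: dict[str, list[int]] = {}
    rows = []

    for mod in sorted(keep, key=lambda m: m.module_id):
        a = assignments[mod.module_id]
        modules[mod.module_id] = mod.genes
        mirna_regs[mod.module_id] = a.mirna_regulators
        tf_regs[mod.module_id] = a.tf_regulators
        tf_set = set(a.tf_regulators)
        for gene in sorted(mod.genes):
            membership.setdefault(gene, []).append(mod.module_id)
            g.add_node(gene, node_type="tf" if gene in tf_set else "gene")
        for u in sorted(mod.genes):
            for v in sorted(network[u]):
                if v in mod.genes and u < v:
                    g.add_edge(u, v, edge_type="coexpression",
                               weight=float(network[u][v]["weight"]))
        for mirna, _p in a.mirna_regulators:
            in_module = frozenset(set(targets.get(mirna, frozenset())) & mod.genes)
            module_targets[(mod.module_id, mirna)] = in_module
            g.add_node(mirna, node_type="mirna")
            for gene in sorted(in_module):
                assert gene in targets[mirna], "miRNA edge outside the consensus target map"
                g.add_edge(mirna, gene, edge_type="targets")
        rows.append(
            {
                "module_id": mod.module_id,
                "n_nodes": mod.size,
                "n_edges": mod.n_internal_edges,
                "mirnas": ",".join(m for m, _ in a.mirna_regulators),
                "tfs": ",".join(a.tf_regulators),
            }
        )

    for gene, mids in membership.items():
        g.nodes[gene]["module_id"] = ",".join(str(m) for m in sorted(set(mids)))
    for (mid, mirna), _tg in module_targets.items():
        node = g.nodes[mirna]
        prev = node.get("module_id", "")
        mids = sorted(set((prev.split(",") if prev else []) + [str(mid)]), key=lambda s: int(s))
        node["module_id"] = ",".join(mids)

    # typed-node exclusivity: a node never carries two types
    types = nx.get_node_attributes(g, "node_type")
    assert all(t in ("tf", "gene", "mirna") for t in types.values())

    summary = pd.DataFrame(rows, columns=["module_id", "n_nodes", "n_edges", "mirnas", "tfs"])
    return CoregulationNetwork(g, modules, mirna_regs, tf_regs, module_targets, summary)


def mirna_target_anticorrelation(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    coreg: CoregulationNetwork,
    labels: SampleLabels | None = None,
    sample_set: str = "all",
) -> AnticorrelationReport:
    """Correlate regulator-miRNA expression with their in-module targets.

    Pearson correlation is computed per (miRNA, target) pair across the
    samples shared by the two matrices (``sample_set="all"``, default) or
    across shared case samples only (``"case"``). A miRNA is labelled
    ``negative`` for a module when the median correlation over its
    in-module targets is below zero.
    """
    mirna_samples = set(mirna_expr.sample_ids)
    shared = [s for s in gene_expr.sample_ids if s in mirna_samples]
    if sample_set == "case":
        if labels is None:
            raise ValueError('sample_set="case" requires labels')
        shared = [s for s in shared if s in labels and labels[s] == "case"]
    elif sample_set != "all":
        raise ValueError(f"unknown sample_set {sample_set!r}")
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared samples, got {len(shared)}")

    gene_df = gene_expr.data[shared]
    mirna_df = mirna_expr.data[shared]
    pair_rows = []
    summary_rows = []
    for (mid, mirna), tg in sorted(coreg.module_targets.items()):
        if mirna not in mirna_df.index:
            logger.warning("regulator %s not in the miRNA expression matrix; skipped", mirna)
            continue
        x = mirna_df.loc[mirna].to_numpy(dtype=float)
        rs = []
        for gene in sorted(tg):
            if gene not in gene_df.index:
                continue
            y = gene_df.loc[gene].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(-1.0, min(1.0, r))
            rs.append(r)
            pair_rows.append({"module_id": mid, "mirna_id": mirna, "gene_id": gene, "r": r})
        if rs:
            med = float(np.median(rs))
            summary_rows.append(
                {
                    "module_id": mid,
                    "mirna_id": mirna,
                    "n_targets": len(rs),
                    "median_r": med,
                    "mean_r": float(np.mean(rs)),
                    "direction": "negative" if med < 0 else "non-negative",
                }
            )
    pairs = pd.DataFrame(pair_rows, columns=["module_id", "mirna_id", "gene_id", "r"])
    summary = pd.DataFrame(
        summary_rows,
        columns=["module_id", "mirna_id", "n_targets", "median_r", "mean_r", "direction"],
    )
    return AnticorrelationReport(pairs, summary)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "alpha_de": 0.05,
    "alpha_network": 0.05,
    "alpha_module_enrichment": 0.01,
    "alpha_regulator": 0.01,
    "welch": False,
    "min_sources": 2,
    "min_module_edges": 1,
    "network_case_only": True,
    "network_positive_only": True,
    "anticorrelation_samples": "all",
    "detection": {},
    "seed": 0,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _float_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_pipeline(config: Mapping[str, Any] | str | Path) -> Path:
    """Run the full inference pipeline from a config mapping or YAML path.

    Stages: differential calling (genes and miRNAs) -> case-sample
    coexpression network -> cohesiveness module detection -> one-third
    overlap merge -> DEG-enrichment filter -> consensus targets and
    regulator assignment -> coregulation-network assembly -> miRNA-target
    anticorrelation. Every intermediate table, both GraphML networks, a
    JSON run report with stage counts, and a log are written to
    ``out_dir``. All stages are deterministic, so reruns with the same
    config produce byte-identical outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    for key in ("gene_expression", "mirna_expression", "labels", "targets", "tf_list", "out_dir"):
        if key not in cfg:
            raise ValueError(f"config is missing required key {key!r}")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("coregnet.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)

    report: dict[str, Any] = {
        "thresholds": {
            "alpha_de": cfg["alpha_de"],
            "alpha_network": cfg["alpha_network"],
            "alpha_module_enrichment": cfg["alpha_module_enrichment"],
            "alpha_regulator": cfg["alpha_regulator"],
        },
        "seed": cfg["seed"],
    }
    stage = "load_inputs"
    try:
        gene_expr = data_io.read_expression(cfg["gene_expression"], "gene")
        mirna_expr = data_io.read_expression(cfg["mirna_expression"], "mirna")
        labels = data_io.read_labels(cfg["labels"])
        evidence = data_io.read_target_table(cfg["targets"])
        tfs = data_io.read_tf_list(cfg["tf_list"])
        unmeasured_tfs = tfs - set(gene_expr.feature_ids)
        if unmeasured_tfs:
            log.warning("%d TF(s) not in the expression matrix are ignored", len(unmeasured_tfs))
        log.info("inputs: %d genes, %d miRNAs, %d samples, %d evidence pairs, %d TFs",
                 gene_expr.n_features, mirna_expr.n_features, gene_expr.n_samples,
                 len(evidence), len(tfs))

        stage = "differential_expression"
        deg_table = call_differential(gene_expr, labels, cfg["alpha_de"], welch=cfg["welch"])
        demir_table = call_differential(mirna_expr, labels, cfg["alpha_de"], welch=cfg["welch"])
        _float_tsv(deg_table, out_dir / "degs.tsv")
        _float_tsv(demir_table, out_dir / "demirs.tsv")
        degs = significant_features(deg_table)
        demirs = significant_features(demir_table)
        report["n_degs"] = len(degs)
        report["n_demirs"] = len(demirs)
        log.info("differential: %d DEGs, %d DemiRs (alpha=%g)", len(degs), len(demirs),
                 cfg["alpha_de"])

        stage = "coexpression_network"
        network = build_network(
            gene_expr, labels, cfg["alpha_network"],
            case_only=cfg["network_case_only"], positive_only=cfg["network_positive_only"],
        )
        data_io.write_network(network, out_dir / "net.graphml")
        report["n_network_nodes"] = network.number_of_nodes()
        report["n_network_edges"] = network.number_of_edges()
        log.info("network: %d nodes, %d edges", network.number_of_nodes(),
                 network.number_of_edges())

        stage = "module_detection"
        params = DetectionParams(**cfg["detection"])
        detected = detect_modules(network, params)
        _write_modules(detected, out_dir / "modules.tsv", out_dir / "modules_summary.tsv")
        report["n_modules_detected"] = len(detected)

        stage = "module_merge"
        merged = merge_by_one_third_rule(detected, network, params.penalty)
        _write_modules(merged, out_dir / "modules_merged.tsv",
                       out_dir / "modules_merged_summary.tsv")
        report["n_modules_after_merge"] = len(merged)
        log.info("modules: %d detected, %d after one-third merge", len(detected), len(merged))

        stage = "deg_enrichment_filter"
        universe = set(network.nodes)
        retained, enrich_table = filter_modules_by_deg(
            merged, degs, universe, cfg["alpha_module_enrichment"]
        )
        _float_tsv(enrich_table, out_dir / "enrich.tsv")
        report["n_deg_enriched"] = len(retained)
        log.info("%d module(s) enriched with DEGs at alpha=%g", len(retained),
                 cfg["alpha_module_enrichment"])

        stage = "regulator_assignment"
        targets = build_consensus_targets(evidence, cfg["min_sources"])
        assignments = assign_regulators(
            retained, demirs, targets, tfs, network, universe,
            cfg["alpha_regulator"], cfg["min_module_edges"],
        )
        _write_regulators(assignments, out_dir / "regulators.tsv")

        stage = "coregulation_assembly"
        coreg = build_coregulation_network(retained, assignments, targets, network)
        data_io.write_network(coreg.graph, out_dir / "coregulation.graphml")
        _float_tsv(coreg.summary, out_dir / "coregulation_summary.tsv")
        report["n_coregulated"] = coreg.n_modules
        report["coregulated_modules"] = [
            {
                "module_id": int(mid),
                "n_genes": len(coreg.modules[mid]),
                "mirnas": [m for m, _ in coreg.mirna_regulators[mid]],
                "tfs": list(coreg.tf_regulators[mid]),
            }
            for mid in sorted(coreg.modules)
        ]
        log.info("%d coregulated module(s)", coreg.n_modules)

        stage = "anticorrelation"
        anti = mirna_target_anticorrelation(
            mirna_expr, gene_expr, coreg, labels, cfg["anticorrelation_samples"]
        )
        _float_tsv(anti.pairs, out_dir / "anticorrelation_pairs.tsv")
        _float_tsv(anti.summary, out_dir / "anticorrelation.tsv")
        report["n_negative_mirnas"] = int((anti.summary["direction"] == "negative").sum())
        report["anticorrelation"] = [
            {
                "module_id": int(r.module_id),
                "mirna_id": r.mirna_id,
                "median_r": round(float(r.median_r), 12),
                "direction": r.direction,
            }
            for r in anti.summary.itertuples(index=False)
        ]
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    # stage-count sanity: each filter can only shrink the module list
    assert report["n_modules_after_merge"] <= report["n_modules_detected"]
    assert report["n_coregulated"] <= report["n_deg_enriched"] <= report["n_modules_after_merge"]

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def _write_modules(modules: list[Module], long_path: Path, summary_path: Path) -> None:
    long_rows = [
        {"module_id": m.module_id, "gene_id": g} for m in modules for g in sorted(m.genes)
    ]
    _float_tsv(pd.DataFrame(long_rows, columns=["module_id", "gene_id"]), long_path)
    summary_rows = [
        {
            "module_id": m.module_id,
            "size": m.size,
            "n_internal_edges": m.n_internal_edges,
            "density": m.density,
            "cohesiveness": m.cohesiveness,
        }
        for m in modules
    ]
    _float_tsv(
        pd.DataFrame(
            summary_rows,
            columns=["module_id", "size", "n_internal_edges", "density", "cohesiveness"],
        ),
        summary_path,
    )


def _write_regulators(assignments: Mapping[int, RegulatorAssignment], path: Path) -> None:
    rows = []
    for mid in sorted(assignments):
        a = assignments[mid]
        for mirna, p in a.mirna_regulators:
            rows.append({"module_id": mid, "regulator_type": "mirna", "regulator_id": mirna,
                         "enrichment_p": p})
        for tf in a.tf_regulators:
            rows.append({"module_id": mid, "regulator_type": "tf", "regulator_id": tf,
                         "enrichment_p": float("nan")})
    _float_tsv(
        pd.DataFrame(rows, columns=["module_id", "regulator_type", "regulator_id", "enrichment_p"]),
        path,
    )
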