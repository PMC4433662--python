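"""Consensus miRNA-target mapping and per-module regulator assignment.

A miRNA-gene interaction enters the consensus target map when it is
predicted by at least two tools or is experimentally validated. A
differentially expressed miRNA (DemiR) regulates a module when its
consensus targets are enriched in the module (one-sided Fisher's exact,
default p < 0.01); non-differential miRNAs are never tested. A
transcription factor regulates a module when it belongs to the module and
has at least ``min_module_edges`` coexpression edges to other module
members. A module is coregulated when both regulator kinds are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from coregnet.data_io import TargetEvidence
from coregnet.enrichment import fisher_enrichment
from coregnet.module_detection import Module

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatorAssignment:
    module_id: int
    mirna_regulators: tuple[tuple[str, float], ...]  # (mirna_id, enrichment p), ascending p
    tf_regulators: tuple[str, ...]  # descending within-module degree

    @property
    def coregulated(self) -> bool:
        return bool(self.mirna_regulators) and bool(self.tf_regulators)


def build_consensus_targets(
    evidence: list[TargetEvidence], min_sources: int = 2
) -> dict[str, frozenset[str]]:
    """Build the consensus miRNA -> target-gene map.

    A pair is retained iff it is supported by at least ``min_sources``
    prediction tools or is experimentally validated. miRNAs with no
    retained target are absent from the map.
    """
    targets: dict[str, set[str]] = {}
    for ev in evidence:
        if len(ev.sources) >= min_sources or ev.experimental:
            targets.setdefault(ev.mirna_id, set()).add(ev.gene_id)
    return {m: frozenset(g) for m, g in targets.items()}


def assign_mirna_regulators(
    module: Module,
    demirs: set[str] | frozenset[str],
    targets: dict[str, frozenset[str]],
    universe: set[str] | frozenset[str],
    alpha: float = 0.01,
) -> list[tuple[str, float]]:
    """miRNA regulators of a module: DemiRs with target enrichment p < alpha.

    Only differentially expressed miRNAs are tested. A DemiR with no
    consensus target inside the universe is skipped with a log entry.
    Returns (mirna_id, p) pairs sorted by ascending p, ties by id.
    """
    universe = set(universe)
    out: list[tuple[str, float]] = []
    for mirna in sorted(demirs):
        tg = set(targets.get(mirna, frozenset())) & universe
        if not tg:
            logger.debug("DemiR %s has no consensus target in the universe; skipped", mirna)
            continue
        res = fisher_enrichment(module.genes, tg, universe, alpha, module_id=module.module_id,
                                set_name=mirna)
        if res.significant:
            out.append((mirna, res.p_value))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def assign_tf_regulators(
    module: Module,
    tfs: set[str] | frozenset[str],
    network: nx.Graph,
    min_module_edges: int = 1,
) -> list[str]:
    """TF regulators of a module: member TFs coexpressing within the module.

    A TF qualifies when it belongs to the module and has at least
    ``min_module_edges`` coexpression edges to other module members.
    Sorted by descending within-module degree, ties by id.
    """
    scored = []
    for gene in module.genes & set(tfs):
        if gene not in network:
            continue
        deg = sum(1 for nb in network[gene] if nb in module.genes)
        if deg >= min_module_edges:
            scored.append((-deg, gene))
    return [g for _, g in sorted(scored)]


def assign_regulators(
    modules: list[Module],
    demirs: set[str] | frozenset[str],
    targets: dict[str, frozenset[str]],
    tfs: set[str] | frozenset[str],
    network: nx.Graph,
    universe: set[str] | frozenset[str] | None = None,
    alpha: float = 0.01,
    min_module_edges: int = 1,
) -> dict[int, RegulatorAssignment]:
    """Assign miRNA and TF regulators to every module.

    ``universe`` defaults to the coexpression-network node set. The
    returned mapping carries one :class:`RegulatorAssignment` per module;
    its gate invariants (miRNA regulators are DemiRs, TF regulators are
    module members) are asserted on every call.
    """
    if universe is None:
        universe = set(network.nodes)
    assignments: dict[int, RegulatorAssignment] = {}
    for mod in modules:
        mirnas = assign_mirna_regulators(mod, demirs, targets, universe, alpha)
        tf_list = assign_tf_regulators(mod, tfs, network, min_module_edges)
        assert all(m in demirs for m, _ in mirnas), "assigned miRNA outside the DemiR set"
        assert all(t in mod.genes for t in tf_list), "assigned TF outside the module"
        assignments[mod.module_id] = RegulatorAssignment(
            mod.module_id, tuple(mirnas), tuple(tf_list)
        )
    return assignments
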