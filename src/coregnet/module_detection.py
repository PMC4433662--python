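"""Cohesiveness-based greedy module detection on weighted coexpression networks.

A candidate module V is scored by its cohesiveness

    f(V) = w_in / (w_in + w_bound + penalty * |V|),

where ``w_in`` is the total weight of edges inside V, ``w_bound`` the total
weight of edges crossing the boundary of V, and ``penalty`` a per-node term
modelling unobserved connections. Clusters are grown greedily from seeds in
degree-descending order: from each seed the single best move (adding a
boundary node or removing a member) that strictly increases f is applied
until a local optimum is reached. Grown clusters are filtered by size and
internal edge density, highly overlapping clusters are unioned by the match
coefficient omega(A, B) = |A n B|^2 / (|A| * |B|), and a separate post-hoc
pass merges any two modules where more than one-third of the smaller
module's genes occur in the larger one.

All tie-breaks are deterministic (smallest gene id), so identical inputs
and parameters yield identical module lists.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import networkx as nx

logger = logging.getLogger(__name__)

#: minimum strict improvement in cohesiveness for a greedy move (guards
#: against floating-point oscillation)
_EPS = 1e-12


@dataclass(frozen=True)
class DetectionParams:
    """Free parameters of the greedy detection algorithm.

    penalty:
        Per-node penalty in the cohesiveness denominator (default 2).
    min_size:
        Smallest module size kept (default 3).
    min_density:
        Minimum internal edge density of a kept module (default 0.3).
    merge_overlap_omega:
        Match-coefficient threshold above which grown clusters are unioned
        (default 0.8).
    """

    penalty: float = 2.0
    min_size: int = 3
    min_density: float = 0.3
    merge_overlap_omega: float = 0.8

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if not 0.0 <= self.min_density <= 1.0:
            raise ValueError("min_density must be in [0, 1]")
        if not 0.0 < self.merge_overlap_omega <= 1.0:
            raise ValueError("merge_overlap_omega must be in (0, 1]")


@dataclass(frozen=True)
class Module:
    """A detected gene module with its cohesiveness bookkeeping."""

    module_id: int
    genes: frozenset[str]
    cohesiveness: float
    n_internal_edges: int
    internal_weight: float
    boundary_weight: float

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def density(self) -> float:
        """Internal edge density |E_in| / C(|V|, 2)."""
        k = self.size
        return 0.0 if k < 2 else self.n_internal_edges / (k * (k - 1) / 2)


def _subgraph_weights(network: nx.Graph, genes: frozenset[str] | set[str]) -> tuple[float, float, int]:
    w_in = w_bound = 0.0
    n_edges = 0
    for g in genes:
        if g not in network:
            raise KeyError(f"gene {g!r} not in network")
        for nb, d in network[g].items():
            w = float(d["weight"])
            if nb in genes:
                if g < nb:
                    w_in += w
                    n_edges += 1
            else:
                w_bound += w
    return w_in, w_bound, n_edges


def cohesiveness(network: nx.Graph, genes: set[str] | frozenset[str], penalty: float) -> float:
    """Cohesiveness f(V) = w_in / (w_in + w_bound + penalty * |V|)."""
    if not genes:
        raise ValueError("gene set is empty")
    w_in, w_bound, _ = _subgraph_weights(network, genes)
    denom = w_in + w_bound + penalty * len(genes)
    return 0.0 if denom == 0 else w_in / denom


def module_from_genes(
    network: nx.Graph, genes: set[str] | frozenset[str], penalty: float, module_id: int = -1
) -> Module:
    """Build a :class:`Module` record for an explicit gene set."""
    genes = frozenset(genes)
    w_in, w_bound, n_edges = _subgraph_weights(network, genes)
    denom = w_in + w_bound + penalty * len(genes)
    f = 0.0 if denom == 0 else w_in / denom
    return Module(module_id, genes, f, n_edges, w_in, w_bound)


def _plain_adjacency(network: nx.Graph) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Weight adjacency and weighted degrees as plain dicts (hot-loop food)."""
    adj = {
        v: {nb: float(d["weight"]) for nb, d in nbrs.items()}
        for v, nbrs in network.adj.items()
    }
    deg_w = {v: sum(ws.values()) for v, ws in adj.items()}
    return adj, deg_w


def _connected(adj: dict[str, dict[str, float]], genes: set[str]) -> bool:
    start = next(iter(genes))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for nb in adj[v]:
            if nb in genes and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(genes)


def grow_cluster(
    network: nx.Graph,
    seed_gene: str,
    params: DetectionParams,
    _adj: dict[str, dict[str, float]] | None = None,
    _deg_w: dict[str, float] | None = None,
) -> Module:
    """Grow a cohesiveness-locally-optimal cluster from a seed gene.

    Starting from the singleton {seed}, the single move (add an external
    boundary node or remove a member) with the highest resulting
    cohesiveness is applied while it strictly improves f; ties are broken
    by smallest gene id, and removals that would disconnect the cluster
    are skipped. The returned set is a connected local optimum of f.

    ``_adj``/``_deg_w`` are precomputed plain-dict views of the network,
    shared across grows by :func:`detect_modules`.
    """
    if seed_gene not in network:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    if _adj is None or _deg_w is None:
        _adj, _deg_w = _plain_adjacency(network)
    adj, deg_w = _adj, _deg_w
    penalty = params.penalty

    members: set[str] = {seed_gene}
    # conn[v] = total edge weight between v and current members, for any v
    conn: dict[str, float] = dict(adj[seed_gene])
    w_in = 0.0
    w_bound = deg_w[seed_gene]
    f = w_in / (w_in + w_bound + penalty) if (w_in + w_bound + penalty) > 0 else 0.0

    while True:
        k = len(members)
        banned: set[str] = set()  # removals rejected for disconnecting the cluster
        while True:
            # single best strictly improving move; ties go to the smallest id
            best_f, best_v, best_kind = f + _EPS, None, ""
            denom_add = penalty * (k + 1)
            for v, c in conn.items():
                if c <= 0.0 or v in members:
                    continue
                wi = w_in + c
                denom = wi + w_bound - 2.0 * c + deg_w[v] + denom_add
                new_f = wi / denom if denom > 0 else 0.0
                if new_f > best_f or (new_f == best_f and best_v is not None and v < best_v):
                    best_f, best_v, best_kind = new_f, v, "add"
            if k > 1:
                denom_rm = penalty * (k - 1)
                for v in members:
                    c = conn.get(v, 0.0)
                    if v in banned:
                        continue
                    wi = w_in - c
                    denom = wi + w_bound + 2.0 * c - deg_w[v] + denom_rm
                    new_f = wi / denom if denom > 0 else 0.0
                    if new_f > best_f or (new_f == best_f and best_v is not None and v < best_v):
                        best_f, best_v, best_kind = new_f, v, "remove"
            if best_kind == "remove" and not _connected(adj, members - {best_v}):
                banned.add(best_v)
                continue
            break
        if best_v is None:
            break
        f, v = best_f, best_v
        c = conn.get(v, 0.0)
        if best_kind == "add":
            w_in += c
            w_bound += deg_w[v] - 2.0 * c
            members.add(v)
            for nb, w in adj[v].items():
                conn[nb] = conn.get(nb, 0.0) + w
        else:
            w_in -= c
            w_bound -= deg_w[v] - 2.0 * c
            members.remove(v)
            for nb, w in adj[v].items():
                conn[nb] -= w
    return module_from_genes(network, members, penalty)


def match_coefficient(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """Match coefficient omega(A, B) = |A n B|^2 / (|A| * |B|)."""
    if not a or not b:
        return 0.0
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def _merge_by_omega(gene_sets: list[frozenset[str]], threshold: float) -> list[frozenset[str]]:
    """Transitively union sets whose pairwise match coefficient >= threshold."""
    parent = list(range(len(gene_sets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(gene_sets)), 2):
        if match_coefficient(gene_sets[i], gene_sets[j]) >= threshold:
            parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, gs in enumerate(gene_sets):
        groups.setdefault(find(i), set()).update(gs)
    return [frozenset(g) for g in groups.values()]


def _finalize(network: nx.Graph, gene_sets: list[frozenset[str]], penalty: float) -> list[Module]:
    """Deterministic ids: sort by descending size, then smallest gene id."""
    ordered = sorted(gene_sets, key=lambda s: (-len(s), min(s)))
    return [module_from_genes(network, s, penalty, module_id=i + 1) for i, s in enumerate(ordered)]


def detect_modules(network: nx.Graph, params: DetectionParams | None = None) -> list[Module]:
    """Detect cohesive modules in a weighted coexpression network.

    Seeds are the network nodes in degree-descending order (ties by id);
    a node already covered by a previously kept cluster is not used as a
    seed. Grown clusters are kept when they reach ``min_size`` and
    ``min_density``, and highly overlapping kept clusters
    (omega >= merge_overlap_omega) are transitively unioned.
    """
    params = params or DetectionParams()
    adj, deg_w = _plain_adjacency(network)
    order = sorted(network.nodes, key=lambda v: (-network.degree(v), v))
    covered: set[str] = set()
    grown = 0
    kept: list[frozenset[str]] = []
    for v in order:
        if v in covered:
            continue
        mod = grow_cluster(network, v, params, _adj=adj, _deg_w=deg_w)
        grown += 1
        # only clusters that pass the filters cover their genes; genes of a
        # discarded cluster stay eligible as seeds
        if mod.size >= params.min_size and mod.density >= params.min_density:
            kept.append(mod.genes)
            covered |= mod.genes
    merged = _merge_by_omega(kept, params.merge_overlap_omega)
    modules = _finalize(network, merged, params.penalty)
    logger.info("detected %d module(s) from %d grown cluster(s)", len(modules), grown)
    return modules


def merge_by_one_third_rule(
    modules: list[Module], network: nx.Graph, penalty: float = 2.0
) -> list[Module]:
    """Merge module pairs where the smaller one overlaps the larger by more
    than one-third of its genes.

    Iterates to a fixed point: at each step, among all pairs with
    ``|smaller n larger| > |smaller| / 3`` (strict), the pair with the
    largest overlap fraction is unioned (ties: larger combined size first,
    then smallest member gene id). Cohesiveness is recomputed for merged
    modules; the sets are not re-grown. In the output every pairwise
    overlap is at most one-third of the smaller module.
    """
    sets = [m.genes for m in modules]
    while True:
        best = None  # (frac, combined, -minid sentinel) -> track explicitly
        for i, j in itertools.combinations(range(len(sets)), 2):
            a, b = sets[i], sets[j]
            small = a if len(a) <= len(b) else b
            overlap = len(a & b)
            if overlap * 3 <= len(small):  # strict: merge only if overlap > |small|/3
                continue
            frac = overlap / len(small)
            combined = len(a) + len(b)
            key = (frac, combined)
            if best is None or key > best[0] or (key == best[0] and min(a | b) < best[1]):
                best = (key, min(a | b), i, j)
        if best is None:
            break
        _, _, i, j = best
        union = frozenset(sets[i] | sets[j])
        sets = [s for idx, s in enumerate(sets) if idx not in (i, j)] + [union]
    return _finalize(network, sets, penalty)
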