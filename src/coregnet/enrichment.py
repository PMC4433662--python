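"""One-sided Fisher's-exact (hypergeometric) gene-set enrichment.

Used twice in the pipeline: to retain only modules enriched with
differentially expressed genes (default p < 0.01), and to test whether a
miRNA's consensus targets are over-represented in a module. The p-value is
the exact hypergeometric upper tail P(X >= k) for drawing k query genes in
a module of size n from a universe of N genes containing K query genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd
from scipy.stats import hypergeom

from coregnet.module_detection import Module


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: int
    set_name: str
    k: int  # overlap count
    K: int  # query-set size in universe
    n: int  # module size
    N: int  # universe size
    odds_ratio: float
    p_value: float
    significant: bool


def fisher_enrichment(
    module_genes: set[str] | frozenset[str],
    query_set: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    alpha: float = 0.01,
    module_id: int = -1,
    set_name: str = "",
) -> EnrichmentResult:
    """One-sided enrichment test of ``query_set`` within ``module_genes``.

    The query set is intersected with the universe before testing; the
    module must be a subset of the universe. p = P(X >= k) with X
    hypergeometric(N, K, n). Significance uses strict inequality p < alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module_genes = set(module_genes)
    if not module_genes <= universe:
        missing = sorted(module_genes - universe)[:5]
        raise ValueError(f"module genes not in universe: {missing}")
    query = set(query_set) & universe
    N = len(universe)
    K = len(query)
    n = len(module_genes)
    k = len(module_genes & query)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(0.0, p))
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    # strict inequality, except alpha >= 1 disables the filter entirely
    significant = p < alpha or alpha >= 1.0
    return EnrichmentResult(module_id, set_name, k, K, n, N, odds, p, significant)


def filter_modules_by_deg(
    modules: list[Module],
    degs: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    alpha: float = 0.01,
) -> tuple[list[Module], pd.DataFrame]:
    """Retain the modules enriched with differentially expressed genes.

    ``universe`` is normally the coexpression-network node set. Returns the
    retained modules (input order) and the full enrichment table for all
    modules.
    """
    results = [
        fisher_enrichment(m.genes, degs, universe, alpha, module_id=m.module_id, set_name="DEG")
        for m in modules
    ]
    table = pd.DataFrame([r.__dict__ for r in results])
    retained = [m for m, r in zip(modules, results) if r.significant]
    return retained, table
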