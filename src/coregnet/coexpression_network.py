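"""Weighted gene coexpression network over case samples.

Two genes are linked when the Pearson correlation of their case-sample
expression profiles is positive and significant (two-sided test of r = 0 at
p < alpha, default 0.05); the edge weight is the correlation coefficient
itself. Restricting to positive correlations keeps all edge weights
nonnegative, which the downstream cohesiveness objective requires; an
absolute-correlation variant is available via ``positive_only=False``.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
from scipy import stats

from coregnet.data_io import ExpressionMatrix, SampleLabels

logger = logging.getLogger(__name__)

#: warn above this many candidate nodes (dense all-pairs correlation)
LARGE_NETWORK_WARNING = 20_000


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length profiles.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 observations, or a constant vector
        (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need >=3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for the null of zero Pearson correlation.

    Uses the exact t transform t = r * sqrt(n-2) / sqrt(1-r^2) with n-2
    degrees of freedom; |r| = 1 maps to p = 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` (two-sided) for sample size n."""
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / math.sqrt(n - 2 + t * t))


def build_network(
    matrix: ExpressionMatrix,
    labels: SampleLabels | None,
    alpha: float = 0.05,
    case_only: bool = True,
    positive_only: bool = True,
) -> nx.Graph:
    """Build the coexpression network from an expression matrix.

    Parameters
    ----------
    matrix:
        Gene expression matrix; all measured genes are candidate nodes.
    labels:
        Case/control labels. With ``case_only=True`` (default) only case
        samples enter the correlation; pass ``case_only=False`` (labels may
        then be None) to use every sample.
    alpha:
        Edge significance threshold (strict p < alpha).
    positive_only:
        Keep only positively correlated pairs (default). With ``False``,
        significant negative correlations are admitted with ``|r|`` as the
        edge weight (the signed r is kept in the ``r`` attribute).

    Returns
    -------
    networkx.Graph with edge attributes ``weight`` (nonnegative), ``r``
    (signed correlation) and ``p_value``, and graph attributes
    ``n_samples`` and ``alpha``. Genes without any significant edge are
    not nodes of the graph. Constant-profile genes are skipped with a log
    entry.
    """
    if case_only:
        if labels is None:
            raise ValueError("case_only=True requires sample labels")
        use = [s for s in matrix.sample_ids if s in labels and labels[s] == "case"]
    else:
        use = matrix.sample_ids
    n = len(use)
    if n < 3:
        raise ValueError(f"need >=3 samples for correlation, got {n}")

    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    values = matrix.values[:, [col_index[s] for s in use]]
    genes = np.array(matrix.feature_ids)

    nonconstant = values.std(axis=1) > 0
    n_const = int((~nonconstant).sum())
    if n_const:
        logger.info("skipped %d constant-profile gene(s)", n_const)
    values = values[nonconstant]
    genes = genes[nonconstant]
    if len(genes) > LARGE_NETWORK_WARNING:
        logger.warning("dense all-pairs correlation over %d genes", len(genes))

    g = nx.Graph(n_samples=n, alpha=float(alpha))
    if len(genes) < 2:
        return g

    r_mat = np.corrcoef(values)
    np.clip(r_mat, -1.0, 1.0, out=r_mat)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = r_mat * np.sqrt(df / (1.0 - r_mat**2))
    p_mat = 2.0 * stats.t.sf(np.abs(t_mat), df)
    p_mat[np.abs(r_mat) >= 1.0] = 0.0

    iu = np.triu_indices(len(genes), k=1)
    sig = p_mat[iu] < alpha
    if positive_only:
        sig &= r_mat[iu] > 0
    rows, cols = iu[0][sig], iu[1][sig]

    # sorted insertion keeps GraphML output stable under input-row permutation
    edges = sorted(
        (min(genes[i], genes[j]), max(genes[i], genes[j]), float(r_mat[i, j]), float(p_mat[i, j]))
        for i, j in zip(rows, cols)
    )
    for u, v, r, p in edges:
        g.add_edge(u, v, weight=abs(r) if not positive_only else r, r=r, p_value=p)
    logger.info("coexpression network: %d nodes, %d edges (n=%d, alpha=%g)",
                g.number_of_nodes(), g.number_of_edges(), n, alpha)
    return g
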