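"""Shared fixtures: tiny hand-built graphs and expression matrices."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coregnet.data_io import ExpressionMatrix, SampleLabels


def weighted_graph(edges: list[tuple[str, str, float]]) -> nx.Graph:
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w), p_value=0.001)
    return g


def clique_edges(nodes: list[str], weight: float = 1.0) -> list[tuple[str, str, float]]:
    return [(u, v, weight) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]


@pytest.fixture
def triangle() -> nx.Graph:
    return weighted_graph(clique_edges(["a", "b", "c"], 1.0))


@pytest.fixture
def two_cliques_bridge() -> nx.Graph:
    """Two unit-weight 4-cliques joined by a single bridge edge."""
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    edges = clique_edges(a) + clique_edges(b) + [("a0", "b0", 1.0)]
    return weighted_graph(edges)


def expression_matrix(values: np.ndarray, features: list[str] | None = None,
                      samples: list[str] | None = None, kind: str = "gene") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), kind)


@pytest.fixture
def seven_vs_seven_labels() -> SampleLabels:
    labels = {f"s{i}": ("case" if i < 7 else "control") for i in range(14)}
    return SampleLabels(labels)


def exact_correlation_pair(n: int, c: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two n-vectors whose sample Pearson correlation is exactly ``c``.

    Built from an orthonormal, zero-mean basis so the sample statistic hits
    the target up to float rounding.
    """
    x = rng.standard_normal(n)
    x = x - x.mean()
    x /= np.linalg.norm(x)
    y0 = rng.standard_normal(n)
    y0 = y0 - y0.mean()
    y0 -= (y0 @ x) * x
    y0 /= np.linalg.norm(y0)
    y = c * x + np.sqrt(1.0 - c * c) * y0
    return x, y
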