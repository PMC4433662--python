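"""Differential expression calling with a two-sample Student's t-test.

Genes (or miRNAs) are called differentially expressed between cases and
controls with a two-sided, pooled-variance two-sample t-test at a raw
p-value threshold (default 0.05, strict inequality, no multiple-testing
correction). Welch's unequal-variance variant and Benjamini-Hochberg
adjustment are available behind flags.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from coregnet.data_io import ExpressionMatrix, SampleLabels

logger = logging.getLogger(__name__)


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float
    degenerate: bool


def t_test_two_sample(
    case_values: np.ndarray, control_values: np.ndarray, welch: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test of case vs control values.

    Pooled-variance (Student's) by default; Welch with ``welch=True``.
    A comparison where the pooled variance is zero is degenerate: it is
    reported as (t=0, p=1) when the group means are equal and (t=+/-inf,
    p=0) otherwise, with ``degenerate=True``, so batch runs proceed.

    Raises
    ------
    ValueError
        If either group has fewer than two observations.
    """
    t, p, deg = _t_test_matrix(
        np.asarray(case_values, dtype=float)[None, :],
        np.asarray(control_values, dtype=float)[None, :],
        welch=welch,
    )
    return TTestResult(float(t[0]), float(p[0]), bool(deg[0]))


def _t_test_matrix(
    x: np.ndarray, y: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test on (features x n1) vs (features x n2)."""
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {n1} and {n2}")
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = np.sqrt(se2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, float(n1 + n2 - 2))
    degenerate = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.ones_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # zero variance in both groups: equal means -> no evidence; unequal -> infinite evidence
    t[degenerate & (diff == 0)] = 0.0
    p[degenerate & (diff == 0)] = 1.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    p[degenerate & (diff != 0)] = 0.0
    return t, p, degenerate


def call_differential(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    alpha: float = 0.05,
    welch: bool = False,
    correction: str | None = None,
) -> pd.DataFrame:
    """Call differential features between case and control samples.

    Parameters
    ----------
    matrix:
        Expression matrix; every sample must be labelled.
    labels:
        Case/control assignment of the samples.
    alpha:
        Significance threshold; a feature is significant iff p < alpha
        (strict).
    welch:
        Use Welch's unequal-variance test instead of the pooled-variance
        default.
    correction:
        ``None`` (raw p-values, the default) or ``"bh"`` for
        Benjamini-Hochberg; with ``"bh"`` significance is called on the
        adjusted q-value.

    Returns
    -------
    DataFrame with one row per feature (input order) and columns
    feature_id, t_stat, p_value, mean_case, mean_control, significant,
    degenerate (+ q_value under BH).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    case_ids, control_ids = labels.split(matrix.sample_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_ids)} case / {len(control_ids)} control"
        )
    values = matrix.values
    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    x = values[:, [col_index[s] for s in case_ids]]
    y = values[:, [col_index[s] for s in control_ids]]
    t, p, degenerate = _t_test_matrix(x, y, welch=welch)
    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "t_stat": t,
            "p_value": p,
            "mean_case": x.mean(axis=1),
            "mean_control": y.mean(axis=1),
            "degenerate": degenerate,
        }
    )
    if correction is None or correction == "none":
        out["significant"] = out["p_value"] < alpha
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        _, qvals, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["q_value"] = qvals
        out["significant"] = out["q_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("flagged %d degenerate (zero-variance) feature(s)", n_deg)
    return out


def significant_features(results: pd.DataFrame) -> set[str]:
    """Return the ids of features called significant."""
    return set(results.loc[results["significant"], "feature_id"])
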