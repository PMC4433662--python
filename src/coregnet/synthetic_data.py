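"""Synthetic matched mRNA/miRNA case-control data with planted structure.

The generator emulates the small-cohort two-platform design the pipeline
targets: a gene and a miRNA expression matrix over the same 7 case + 7
control samples, a multi-source miRNA-target evidence table, and a TF
list — together with complete ground truth (module membership, planted
differential features, planted TFs, planted repressive regulators and the
true target pairs).

Each planted module follows a single-latent-factor model: for module m
with loading lambda, member gene profiles are

    x = noise_sd * (lambda * F_m + sqrt(1 - lambda^2) * eps) + baseline,

with F_m a per-sample standard-normal factor and eps i.i.d. noise, so the
population correlation between two member genes is lambda^2 and the
implied covariance is positive definite by construction. Each module's
planted repressor miRNA loads negatively on the same factor
(``repressor_loading``), giving a population miRNA-target correlation of
lambda * repressor_loading. Module genes are shifted down and repressor
miRNAs up in cases (the repression signature), and a configurable fraction
of background features receives a differential shift of random sign.
Target evidence is drawn per prediction source with stated sensitivity on
true pairs and false-positive rate on non-pairs; experimentally validated
rows are emitted under the ``Tarbase`` source name. All randomness flows
from the single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coregnet import data_io
from coregnet.data_io import ExpressionMatrix, SampleLabels, TargetEvidence
from coregnet.module_detection import Module
from coregnet.regulator_inference import RegulatorAssignment

DEFAULT_SOURCES = ("PicTar", "miRanda", "MicroT", "TargetScan")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated dataset.

    Defaults mirror the matched-cohort design the pipeline addresses:
    7 cases vs 7 controls, two planted 25-gene modules with factor loading
    0.98 (population member correlation 0.96, comfortably above the n=7
    critical correlation of ~0.754), unit noise, a 3-sigma differential
    shift on planted features, two planted TF members per module, a
    planted repressor covering 60% of its module against a 5% background
    target rate (population miRNA-target correlation 0.98 * -0.82 = -0.80),
    and four prediction sources at 0.8 sensitivity / 0.01 false-positive
    rate.
    """

    n_case: int = 7
    n_control: int = 7
    n_genes: int = 1000
    n_mirnas: int = 60
    modules: tuple[tuple[int, float], ...] = ((25, 0.98), (25, 0.98))
    noise_sd: float = 1.0
    de_effect: float = 3.0
    de_fraction_background: float = 0.05
    n_tf_per_module: int = 2
    n_background_tfs: int = 10
    regulator_coverage: float = 0.6
    background_target_rate: float = 0.05
    source_names: tuple[str, ...] = DEFAULT_SOURCES
    source_sensitivity: float | Mapping[str, float] = 0.8
    source_fpr: float | Mapping[str, float] = 0.01
    experimental_rate: float = 0.1
    repressor_loading: float = -0.82
    gene_baseline: float = 8.0
    mirna_baseline: float = 6.0
    seed: int = 0

    def sensitivity(self, source: str) -> float:
        s = self.source_sensitivity
        return float(s[source] if isinstance(s, Mapping) else s)

    def fpr(self, source: str) -> float:
        s = self.source_fpr
        return float(s[source] if isinstance(s, Mapping) else s)

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >=2 samples per group")
        if sum(size for size, _ in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if len(self.modules) > self.n_mirnas:
            raise ValueError("need one miRNA per planted module")
        for size, lam in self.modules:
            if size < 2 or not 0.0 < lam <= 1.0:
                raise ValueError(f"bad module definition ({size}, {lam})")
        for frac in (self.de_fraction_background, self.regulator_coverage,
                     self.background_target_rate, self.experimental_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not -1.0 <= self.repressor_loading < 0.0:
            raise ValueError("repressor_loading must be in [-1, 0)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for src in self.source_names:
            for v in (self.sensitivity(src), self.fpr(src)):
                if not 0.0 <= v <= 1.0:
                    raise ValueError("source rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure serialized alongside each generated dataset."""

    module_genes: dict[str, tuple[str, ...]]
    module_tfs: dict[str, tuple[str, ...]]
    module_repressor: dict[str, str]
    de_genes: tuple[str, ...]
    de_mirnas: tuple[str, ...]
    tf_genes: tuple[str, ...]
    true_targets: tuple[tuple[str, str], ...]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_targets"] = tuple(tuple(p) for p in d["true_targets"])
        for key in ("module_genes", "module_tfs"):
            d[key] = {k: tuple(v) for k, v in d[key].items()}
        for key in ("de_genes", "de_mirnas", "tf_genes"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimData:
    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    labels: SampleLabels
    evidence: list[TargetEvidence]
    evidence_table: pd.DataFrame  # raw long rows: mirna_id, gene_id, source, experimental
    tfs: set[str]
    truth: GroundTruth


def generate_dataset(config: SimConfig) -> SimData:
    """Generate one matched case/control dataset with full ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_s = config.n_case + config.n_control
    samples = [f"case_{i + 1}" for i in range(config.n_case)] + [
        f"ctrl_{i + 1}" for i in range(config.n_control)
    ]
    case_cols = np.arange(config.n_case)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i:03d}" for i in range(config.n_mirnas)]
    module_names = [f"M{i + 1}" for i in range(len(config.modules))]

    # --- gene matrix -------------------------------------------------------
    factors = rng.standard_normal((len(config.modules), n_s))
    eps = rng.standard_normal((config.n_genes, n_s))
    X = eps.copy()
    module_rows: dict[str, np.ndarray] = {}
    offset = 0
    for name, (size, lam) in zip(module_names, config.modules):
        rows = np.arange(offset, offset + size)
        module_rows[name] = rows
        X[rows] = lam * factors[module_names.index(name)] + math.sqrt(1 - lam * lam) * eps[rows]
        offset += size
    X *= config.noise_sd
    X += config.gene_baseline

    n_module_genes = offset
    shift = config.de_effect * config.noise_sd
    # module genes are downregulated in cases (repression signature)
    X[np.ix_(np.arange(n_module_genes), case_cols)] -= shift

    background = np.arange(n_module_genes, config.n_genes)
    n_bg_de = int(round(config.de_fraction_background * len(background)))
    bg_de = rng.choice(background, size=n_bg_de, replace=False) if n_bg_de else np.array([], int)
    bg_signs = rng.choice([-1.0, 1.0], size=n_bg_de)
    for row, sign in zip(bg_de, bg_signs):
        X[row, case_cols] += sign * shift

    gene_expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples), feature_kind="gene"
    )

    # --- miRNA matrix ------------------------------------------------------
    eps_m = rng.standard_normal((config.n_mirnas, n_s))
    M = eps_m.copy()
    rho = config.repressor_loading
    repressors = {name: mirnas[i] for i, name in enumerate(module_names)}
    for i, name in enumerate(module_names):
        M[i] = rho * factors[i] + math.sqrt(1 - rho * rho) * eps_m[i]
    M *= config.noise_sd
    M += config.mirna_baseline
    # repressors are upregulated in cases and therefore planted DemiRs
    M[np.ix_(np.arange(len(module_names)), case_cols)] += shift

    bg_mirnas = np.arange(len(module_names), config.n_mirnas)
    n_bg_de_m = int(round(config.de_fraction_background * len(bg_mirnas)))
    bg_de_m = rng.choice(bg_mirnas, size=n_bg_de_m, replace=False) if n_bg_de_m else np.array([], int)
    signs_m = rng.choice([-1.0, 1.0], size=n_bg_de_m)
    for row, sign in zip(bg_de_m, signs_m):
        M[row, case_cols] += sign * shift

    mirna_expr = ExpressionMatrix(
        pd.DataFrame(M, index=mirnas, columns=samples), feature_kind="mirna"
    )

    labels = SampleLabels(
        {s: ("case" if i < config.n_case else "control") for i, s in enumerate(samples)}
    )

    # --- TFs ---------------------------------------------------------------
    module_tfs = {
        name: tuple(genes[r] for r in rows[: config.n_tf_per_module])
        for name, rows in module_rows.items()
    }
    n_bg_tf = min(config.n_background_tfs, len(background))
    bg_tfs = rng.choice(background, size=n_bg_tf, replace=False) if n_bg_tf else np.array([], int)
    tf_genes = sorted(
        {g for tfs in module_tfs.values() for g in tfs} | {genes[r] for r in bg_tfs}
    )

    # --- true target pairs -------------------------------------------------
    true_mask = np.zeros((config.n_mirnas, config.n_genes), dtype=bool)
    for i, name in enumerate(module_names):
        rows = module_rows[name]
        n_cov = int(round(config.regulator_coverage * len(rows)))
        chosen = rng.choice(rows, size=n_cov, replace=False)
        true_mask[i, chosen] = True
    background_mask = rng.random((config.n_mirnas, config.n_genes)) < config.background_target_rate
    true_mask |= background_mask
    true_pairs = [
        (mirnas[i], genes[j]) for i, j in zip(*np.nonzero(true_mask))
    ]

    # --- evidence table ----------------------------------------------------
    rows_out: list[tuple[str, str, str, int]] = []
    for src in config.source_names:
        draw = rng.random((config.n_mirnas, config.n_genes))
        detected = np.where(true_mask, draw < config.sensitivity(src), draw < config.fpr(src))
        for i, j in zip(*np.nonzero(detected)):
            rows_out.append((mirnas[i], genes[j], src, 0))
    exp_draw = rng.random((config.n_mirnas, config.n_genes))
    exp_mask = true_mask & (exp_draw < config.experimental_rate)
    for i, j in zip(*np.nonzero(exp_mask)):
        rows_out.append((mirnas[i], genes[j], "Tarbase", 1))
    evidence_table = pd.DataFrame(
        sorted(rows_out), columns=["mirna_id", "gene_id", "source", "experimental"]
    )
    evidence = data_io.merge_evidence_rows(evidence_table) if len(evidence_table) else []

    truth = GroundTruth(
        module_genes={n: tuple(genes[r] for r in rows) for n, rows in module_rows.items()},
        module_tfs=module_tfs,
        module_repressor=repressors,
        de_genes=tuple(sorted(
            [genes[r] for r in range(n_module_genes)] + [genes[r] for r in bg_de]
        )),
        de_mirnas=tuple(sorted(
            [repressors[n] for n in module_names] + [mirnas[r] for r in bg_de_m]
        )),
        tf_genes=tuple(tf_genes),
        true_targets=tuple(sorted(true_pairs)),
    )
    return SimData(gene_expr, mirna_expr, labels, evidence, evidence_table, set(tf_genes), truth)


def write_dataset(sim: SimData, out_dir: str | Path) -> Path:
    """Write a simulated dataset in the pipeline's input formats (+ truth.json)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_io.write_expression(sim.gene_expr, out_dir / "gene_expr.tsv")
    data_io.write_expression(sim.mirna_expr, out_dir / "mirna_expr.tsv")
    data_io.write_labels(sim.labels, out_dir / "labels.tsv")
    sim.evidence_table.to_csv(out_dir / "targets.tsv", sep="\t", index=False)
    data_io.write_tf_list(sim.tfs, out_dir / "tfs.txt")
    sim.truth.to_json(out_dir / "truth.json")
    return out_dir


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b) if (a | b) else 0.0


def score_recovery(
    truth: GroundTruth,
    modules: Sequence[Module] | None = None,
    assignments: Mapping[int, RegulatorAssignment] | None = None,
    de_genes: set[str] | None = None,
    de_mirnas: set[str] | None = None,
    gene_universe: set[str] | None = None,
    mirna_universe: set[str] | None = None,
    match_threshold: float = 0.5,
) -> dict[str, float]:
    """Score inferred objects against the planted ground truth.

    Returns a flat metric dict: per-planted-module best-match Jaccard and
    their mean; pooled miRNA-regulator precision/recall (an inferred module
    is matched to the planted module it covers best, counted only when it
    contains at least ``match_threshold`` of that module's genes — coverage
    rather than Jaccard, because modules grown from few samples legitimately
    absorb background genes); and differential-calling sensitivity/
    specificity when DE calls are supplied.
    """
    metrics: dict[str, float] = {}

    if modules is not None:
        jac = {}
        for name, planted in truth.module_genes.items():
            planted_set = set(planted)
            jac[name] = max((jaccard(planted_set, m.genes) for m in modules), default=0.0)
            metrics[f"jaccard_{name}"] = jac[name]
        metrics["jaccard_mean"] = float(np.mean(list(jac.values()))) if jac else 0.0

    if assignments is not None and modules is not None:
        truth_pairs = {(n, mir) for n, mir in truth.module_repressor.items()}
        predicted: set[tuple[str, str]] = set()
        n_predicted = 0
        for m in modules:
            a = assignments.get(m.module_id)
            if a is None:
                continue
            n_predicted += len(a.mirna_regulators)
            best_name, best_cov = None, 0.0
            for name, planted in truth.module_genes.items():
                cov = len(set(planted) & m.genes) / len(planted)
                if cov > best_cov:
                    best_name, best_cov = name, cov
            if best_name is not None and best_cov >= match_threshold:
                for mir, _p in a.mirna_regulators:
                    predicted.add((best_name, mir))
        tp = len(predicted & truth_pairs)
        metrics["regulator_precision"] = tp / n_predicted if n_predicted else 0.0
        metrics["regulator_recall"] = tp / len(truth_pairs) if truth_pairs else 1.0

    for kind, called, planted_ids, universe in (
        ("gene", de_genes, truth.de_genes, gene_universe),
        ("mirna", de_mirnas, truth.de_mirnas, mirna_universe),
    ):
        if called is None:
            continue
        planted = set(planted_ids)
        tp = len(called & planted)
        metrics[f"de_{kind}_sensitivity"] = tp / len(planted) if planted else 1.0
        if universe is not None:
            nulls = set(universe) - planted
            metrics[f"de_{kind}_specificity"] = (
                len(nulls - called) / len(nulls) if nulls else 1.0
            )
    return metrics
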