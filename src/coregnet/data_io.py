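"""Plain-text I/O for expression matrices, sample labels, miRNA-target tables, TF lists and networks.

All formats are tab-separated text or GraphML:

* expression: TSV, first column = feature ids, header row = sample ids;
* labels: two-column TSV ``sample_id<TAB>group`` with group in {case, control};
* targets: four-column TSV ``mirna_id, gene_id, source, experimental``;
* TF list: one gene id per line;
* networks: GraphML or an edge-list TSV.

Identifier matching throughout the package is exact string match after
whitespace stripping; probe-to-gene mapping and normalisation are
deliberately external.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens treated as missing values in expression matrices
NA_TOKENS = ("", "NA", "N/A", "NaN", "nan", "null", "NULL")

CASE = "case"
CONTROL = "control"


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A normalised features x samples expression matrix.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index and sample ids as columns.
        Values are assumed pre-normalised (typically log scale) and must be
        numeric with no missing entries.
    feature_kind:
        ``"gene"`` or ``"mirna"``.
    """

    data: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "mirna"):
            raise ValueError(f"feature_kind must be 'gene' or 'mirna', got {self.feature_kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if self.data.isna().any().any():
            raise FormatError("expression matrix contains missing values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``sample_ids`` (kept in the given order)."""
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.feature_kind)


@dataclass
class SampleLabels:
    """Mapping of sample id to group, with group in {case, control}."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.labels.items() if g not in (CASE, CONTROL)}
        if bad:
            raise FormatError(f"labels must be 'case' or 'control', got {bad}")

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.labels

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == CONTROL]

    def split(self, sample_ids: Iterable[str]) -> tuple[list[str], list[str]]:
        """Split ``sample_ids`` into (case, control) lists, preserving order.

        Raises
        ------
        KeyError
            If a sample id is unlabelled.
        """
        case, control = [], []
        for s in sample_ids:
            if s not in self.labels:
                raise KeyError(f"sample {s!r} has no case/control label")
            (case if self.labels[s] == CASE else control).append(s)
        return case, control


@dataclass(frozen=True)
class TargetEvidence:
    """One miRNA-gene interaction with its evidence.

    ``sources`` holds the names of prediction tools supporting the pair;
    ``experimental`` flags experimentally validated interactions (e.g. from
    a curated database). At least one of the two must be present.
    """

    mirna_id: str
    gene_id: str
    sources: frozenset[str] = field(default_factory=frozenset)
    experimental: bool = False

    def __post_init__(self) -> None:
        if not self.sources and not self.experimental:
            raise ValueError(f"evidence for ({self.mirna_id}, {self.gene_id}) is empty")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _strip_index(idx: pd.Index) -> pd.Index:
    return pd.Index([str(x).strip() for x in idx])


def read_expression(path: str | Path, feature_kind: str = "gene") -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    Rows containing missing values (``NA`` tokens or blank cells) are
    dropped with a logged count; rows duplicated by feature id are collapsed
    to their mean with a logged warning. A non-numeric cell that is not a
    recognised NA token raises :class:`FormatError` naming the offending
    row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            keep_default_na=False, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")

    # pandas silently renames duplicated header fields, so check the raw line
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")[1:]]
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicate sample ids in header")

    df.index = _strip_index(df.index)
    df.columns = _strip_index(df.columns)

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        cells = df[col].str.strip()
        vals = pd.to_numeric(cells.where(~cells.isin(NA_TOKENS)), errors="coerce")
        bad = vals.isna() & ~cells.isin(NA_TOKENS)
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        numeric[col] = vals

    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%s: dropped %d feature row(s) with missing values", path, n_missing)
        numeric = numeric.dropna(axis=0)

    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("%s: collapsed %d duplicate feature row(s) by mean", path, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()

    if numeric.shape[0] == 0:
        raise FormatError(f"{path}: no usable feature rows")
    return ExpressionMatrix(numeric, feature_kind)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (inverse of :func:`read_expression`)."""
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_labels(path: str | Path) -> SampleLabels:
    """Read a two-column sample_id/group TSV (header row optional)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty labels file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: labels file needs two columns (sample_id, group)")
    df = df.iloc[:, :2].apply(lambda c: c.str.strip())
    first_id, first_group = df.iloc[0, 0].lower(), df.iloc[0, 1].lower()
    if first_id in ("sample_id", "sample") or first_group in ("group", "label", "condition"):
        df = df.iloc[1:]  # header row
    if df.empty:
        raise FormatError(f"{path}: no samples in labels file")
    labels = {row[0]: row[1].lower() for row in df.itertuples(index=False)}
    if len(labels) != len(df):
        raise FormatError(f"{path}: duplicate sample ids in labels")
    return SampleLabels(labels)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in labels.labels.items():
            fh.write(f"{s}\t{g}\n")


REQUIRED_TARGET_COLUMNS = ("mirna_id", "gene_id", "source", "experimental")


def merge_evidence_rows(rows: pd.DataFrame) -> list[TargetEvidence]:
    """Collapse raw evidence rows to one :class:`TargetEvidence` per pair.

    Sources are unioned and the experimental flag OR-ed across duplicate
    (mirna_id, gene_id) rows. Output order is sorted by (mirna_id, gene_id)
    for determinism.
    """
    out: dict[tuple[str, str], tuple[set[str], bool]] = {}
    for mirna, gene, source, exp in zip(
        rows["mirna_id"], rows["gene_id"], rows["source"], rows["experimental"]
    ):
        key = (str(mirna).strip(), str(gene).strip())
        sources, experimental = out.setdefault(key, (set(), False))
        src = str(source).strip()
        if src:
            sources.add(src)
        out[key] = (sources, experimental or bool(int(exp)))
    return [
        TargetEvidence(m, g, frozenset(srcs), exp)
        for (m, g), (srcs, exp) in sorted(out.items())
    ]


def read_target_table(path: str | Path) -> list[TargetEvidence]:
    """Read a miRNA-target evidence table.

    Expected columns: ``mirna_id``, ``gene_id``, ``source`` (tool name, may
    be empty for purely experimental rows), ``experimental`` (0/1). Rows
    sharing (mirna_id, gene_id) are merged per :func:`merge_evidence_rows`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty target table") from exc
    missing = [c for c in REQUIRED_TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: target table missing column(s) {missing}")
    if df.empty:
        return []
    return merge_evidence_rows(df)


def write_target_table(evidence: Iterable[TargetEvidence], path: str | Path) -> None:
    """Write evidence in the long (one row per source) input format."""
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tsource\texperimental\n")
        for ev in evidence:
            if ev.sources:
                for src in sorted(ev.sources):
                    fh.write(f"{ev.mirna_id}\t{ev.gene_id}\t{src}\t{int(ev.experimental)}\n")
            else:
                fh.write(f"{ev.mirna_id}\t{ev.gene_id}\t\t{int(ev.experimental)}\n")


def read_tf_list(path: str | Path) -> set[str]:
    """Read a transcription-factor gene list, one id per line."""
    with open(path) as fh:
        tfs = {line.strip() for line in fh if line.strip()}
    if not tfs:
        raise FormatError(f"{path}: empty TF list")
    return tfs


def write_tf_list(tfs: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(tfs):
            fh.write(f"{tf}\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a weighted graph as GraphML or an edge-list TSV.

    GraphML round-trips all node/edge/graph attributes; the TSV edge list
    keeps only gene pair, weight and p_value columns. Floats are written at
    full repr precision so a write/read cycle is lossless.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tweight\tp_value\n")
            for u, v, d in sorted(network.edges(data=True)):
                w = repr(float(d.get("weight", 1.0)))
                p = repr(float(d.get("p_value", float("nan"))))
                fh.write(f"{u}\t{v}\t{w}\t{p}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path, node_type=str)
    if format == "tsv":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype={"node1": str, "node2": str})
        for row in df.itertuples(index=False):
            g.add_edge(row.node1, row.node2, weight=float(row.weight), p_value=float(row.p_value))
        return g
    raise ValueError(f"unknown network format {format!r}")
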