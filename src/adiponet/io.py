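"""Reading, writing and normalizing expression matrices and PPI networks.

The processing chain mirrors the standard single-cell pipeline used for
UMI-based differentiation time courses: remove cells with too few detected
genes, transform counts to log2(UMI + 1), and z-score each gene across cells.
Interaction networks are read from SIF files (plain 2/3-column or the
Pathway Commons extended binary SIF dialect) and treated as an undirected,
unweighted union over all interaction types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, StateError, ValidationError

logger = logging.getLogger("adiponet.io")

Stage = Literal["raw", "log", "zscore"]


@dataclass
class ExpressionMatrix:
    """A gene x cell expression matrix with an explicit processing stage.

    ``values`` is dense float64, genes on rows and cells on columns. The
    algorithms that model cells as network snapshots view each cell as a row
    vector over genes; that orientation is obtained internally by transposing,
    so callers never need to care.

    Invariants enforced at construction:

    * no NaN or infinity at any stage;
    * ``raw`` entries are non-negative integers (UMI counts);
    * ``zscore`` rows have mean within 1e-8 of 0 and sample SD within 1e-6
      of 1 for every retained gene;
    * gene and cell identifiers are unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    stage: Stage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite values in {self.stage}-stage matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = _duplicates(self.cell_ids)
            raise ValidationError(f"duplicate cell ids: {sorted(dupes)[:5]}")
        if self.stage == "raw":
            if np.any(self.values < 0):
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("raw counts must be integers")
        elif self.stage == "zscore" and self.values.shape[1] >= 2:
            mean = self.values.mean(axis=1)
            sd = self.values.std(axis=1, ddof=1)
            if np.any(np.abs(mean) > 1e-8) or np.any(np.abs(sd - 1) > 1e-6):
                raise ValidationError(
                    "z-score stage requires per-gene mean ~0 and sample SD ~1"
                )
        elif self.stage not in ("raw", "log", "zscore"):
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in current row order)."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.cell_ids),
            self.stage,
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


@dataclass
class PPIGraph:
    """Undirected, unweighted protein-protein interaction graph.

    No self-loops, no parallel edges; the edge set is the union over all
    interaction types of the source network.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "PPIGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                g.add_node(a)
            else:
                g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def subgraph(self, nodes: Iterable[str]) -> "PPIGraph":
        return PPIGraph(nx.Graph(self.graph.subgraph(nodes)))


# ---------------------------------------------------------------------------
# Count matrix IO


def read_counts(
    path: str | Path,
    format: Literal["tsv", "mtx"] | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a raw UMI count matrix from TSV or MatrixMarket MTX.

    TSV layout: header row of cell ids, first column of gene ids. MTX files
    are gene x cell and accompanied by sidecar name files (one id per line),
    by default ``<stem>.genes.txt`` and ``<stem>.cells.txt``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "tsv"

    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: empty file (line 1)") from exc
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"{path}: malformed TSV: {exc}") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: header line 1 has no cell columns")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"{path}: duplicate gene names {dup[:5]}")
        values = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    elif format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_suffix(".cells.txt")
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"MTX sidecar name file missing: {p}")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed MatrixMarket header: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        if values.shape != (len(genes), len(cells)):
            raise ParseError(
                f"{path}: matrix is {values.shape} but sidecars name "
                f"{len(genes)} genes x {len(cells)} cells"
            )
    else:
        raise ValidationError(f"unknown format {format!r}")

    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        bad = np.argwhere((values < 0) | (values != np.round(values)))[0]
        raise ValidationError(
            f"{path}: entry at gene {genes[bad[0]]}, cell {cells[bad[1]]} "
            "is negative or non-integer"
        )
    logger.info("read %d genes x %d cells from %s", len(genes), len(cells), path)
    return ExpressionMatrix(values, genes, cells, stage="raw")


def read_expression(path: str | Path, stage: Stage = "log") -> ExpressionMatrix:
    """Read a real-valued expression TSV (genes x samples), e.g. clonal
    log-scale profiles. Layout as in :func:`read_counts` TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (line 1)") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene names {dup[:5]}")
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(g) for g in df.index],
        [str(c) for c in df.columns], stage=stage,
    )


def write_counts(
    m: ExpressionMatrix,
    path: str | Path,
    format: Literal["tsv", "mtx"] = "tsv",
) -> None:
    """Write a matrix; inverse of :func:`read_counts` for raw counts."""
    path = Path(path)
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t")
    else:
        sparse = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(str(path), sparse, field="integer" if m.stage == "raw" else "real")
        path.with_suffix(".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        path.with_suffix(".cells.txt").write_text("\n".join(m.cell_ids) + "\n")


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter_cells(m: ExpressionMatrix, min_detected: int = 1000) -> ExpressionMatrix:
    """Remove cells with fewer than ``min_detected`` detected genes.

    A gene is detected in a cell when its raw count is strictly positive; a
    cell with exactly ``min_detected`` detected genes is kept. Gene set and
    relative cell order are unchanged. Idempotent.
    """
    if m.stage != "raw":
        raise StateError(f"QC filter requires raw counts, got stage {m.stage!r}")
    if min_detected < 0:
        raise ValidationError("min_detected must be >= 0")
    detected = (m.values > 0).sum(axis=0)
    keep = np.flatnonzero(detected >= min_detected)
    logger.info(
        "QC filter (min_detected=%d): kept %d of %d cells",
        min_detected, keep.size, m.n_cells,
    )
    return ExpressionMatrix(
        m.values[:, keep],
        list(m.gene_ids),
        [m.cell_ids[i] for i in keep],
        stage="raw",
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(UMI + 1) transform of raw counts."""
    if m.stage != "raw":
        raise StateError(f"log transform requires raw counts, got stage {m.stage!r}")
    return ExpressionMatrix(
        np.log2(m.values + 1.0), list(m.gene_ids), list(m.cell_ids), stage="log"
    )


def zscore_genes(
    m: ExpressionMatrix,
    constant_gene_policy: Literal["drop", "zero"] = "drop",
) -> ExpressionMatrix:
    """Standardize each gene across cells to mean 0, sample SD 1 (ddof=1).

    Genes constant across cells have undefined z-scores; they are dropped by
    default (``constant_gene_policy="drop"``) or set to all-zero rows
    (``"zero"``). Zero rows violate the unit-SD invariant, so the ``zero``
    policy returns a matrix whose constant genes are flagged in the log and
    exempted from that invariant by being exactly zero.
    """
    if m.stage != "log":
        raise StateError(f"z-scoring requires log-stage matrix, got {m.stage!r}")
    if m.n_cells < 2:
        raise ValidationError("z-scoring requires at least 2 cells")
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant_gene_policy == "drop":
        keep = np.flatnonzero(~constant)
        if constant.any():
            logger.info("dropping %d constant genes before z-scoring", int(constant.sum()))
        z = (m.values[keep] - mean[keep]) / sd[keep]
        genes = [m.gene_ids[i] for i in keep]
        return ExpressionMatrix(z, genes, list(m.cell_ids), stage="zscore")
    if constant_gene_policy == "zero":
        sd_safe = np.where(sd == 0, 1.0, sd)
        z = (m.values - mean) / sd_safe
        z[constant, :] = 0.0
        if constant.any():
            logger.warning(
                "%d constant genes set to zero rows; unit-SD invariant relaxed for them",
                int(constant.sum()),
            )
            out = ExpressionMatrix.__new__(ExpressionMatrix)
            out.values = z
            out.gene_ids = list(m.gene_ids)
            out.cell_ids = list(m.cell_ids)
            out.stage = "zscore"
            return out
        return ExpressionMatrix(z, list(m.gene_ids), list(m.cell_ids), stage="zscore")
    raise ValidationError(f"unknown constant_gene_policy {constant_gene_policy!r}")


# ---------------------------------------------------------------------------
# SIF networks


def read_sif(path: str | Path) -> PPIGraph:
    """Read a SIF interaction file into an undirected, unweighted graph.

    Accepts plain 2-column (``A<TAB>B``) and 3+-column
    (``A<TAB>type<TAB>B[<TAB>...]``) tab-separated lines; the interaction
    type and any extended trailing columns are ignored, so the result is the
    union over all interaction types. Edges are symmetrized and deduplicated;
    self-loops are dropped (the node is kept).
    """
    path = Path(path)
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                raise ParseError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
            a, b = (fields[0], fields[1]) if len(fields) == 2 else (fields[0], fields[2])
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ParseError(f"{path}: line {lineno}: empty endpoint")
            if a == b:
                g.add_node(a)
                n_loops += 1
            else:
                g.add_edge(a, b)
    logger.info(
        "read SIF %s: %d nodes, %d edges (%d self-loops dropped)",
        path, g.number_of_nodes(), g.number_of_edges(), n_loops,
    )
    return PPIGraph(g)


def write_sif(g: PPIGraph, path: str | Path) -> None:
    """Write edges as 3-column SIF with a generic interaction type.

    Isolated nodes are written as self-referential lines so they survive a
    round trip through :func:`read_sif` (which keeps the node, drops the loop).
    """
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.graph.edges):
            fh.write(f"{a}\tinteracts-with\t{b}\n")
        for node in sorted(nx.isolates(g.graph)):
            fh.write(f"{node}\tisolated\t{node}\n")


def align_to_graph(
    m: ExpressionMatrix, g: PPIGraph
) -> tuple[ExpressionMatrix, PPIGraph]:
    """Restrict matrix and network to their common gene set.

    Returns the matrix limited to genes present as network nodes (row order
    preserved) and the induced subgraph on measured genes. If either input is
    already limited to the intersection it is returned unchanged.
    """
    measured = set(m.gene_ids)
    shared = measured & g.nodes
    if not shared:
        raise ValidationError("no overlap between matrix genes and network nodes")
    logger.info(
        "gene/network alignment: %d shared; dropping %d matrix genes, %d network nodes",
        len(shared), m.n_genes - len(shared), g.n_nodes - len(shared),
    )
    m_out = m if len(shared) == m.n_genes else m.subset_genes(shared)
    g_out = g if len(shared) == g.n_nodes else g.subgraph(shared)
    return m_out, g_out


# ---------------------------------------------------------------------------
# Tables


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a cell label table (TSV: cell_id, day, cluster)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = {"cell_id", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
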