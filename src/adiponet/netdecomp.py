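"""Connectivity-constrained rank-1 decomposition of single-cell expression.

Model
-----
Each cell's z-scored expression profile is viewed as a snapshot of an
underlying protein-interaction network. The matrix Y (cells x genes) is
approximated as a sum of rank-1 terms

    Y  ~=  sum_k  a_k  b_k^T

subject to two biological constraints:

1. the genes with nonzero loading in b_k (the module's *support*) induce a
   connected subgraph of the PPI network;
2. a gene may appear in several modules, so its expression is a linear
   combination of the activities of the connected networks it belongs to.

For a fixed support S, the optimal rank-1 term in the least-squares sense is
the leading singular triplet of the column-restricted matrix Y[:, S]; the
module's *residual error* is the Frobenius norm of Y minus that term,

    residual_error = sqrt(||Y||_F^2 - sigma_1(Y[:, S])^2),

which is the quantity modules are ranked by. Finding the support minimizing
it over all connected subgraphs is NP-hard, so the search is a greedy
seed-and-expand over graph neighbors with multi-seed restarts, validated in
tests against exhaustive enumeration on small graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .errors import ResourceError, ValidationError
from .io import ExpressionMatrix, PPIGraph

logger = logging.getLogger("adiponet.netdecomp")


@dataclass
class NetworkModule:
    """One connected rank-1 module.

    ``support`` is the ordered gene set S; ``loading`` holds one coefficient
    per support gene (zero implicitly elsewhere); ``activity`` is per-cell and
    carries the scale, so the module's term is activity x loading^T with
    ``loading`` unit-norm. Sign convention: sum(loading) >= 0.
    ``residual_error`` is computed against the matrix the module is reported
    for (the original, un-deflated matrix in :func:`detect_modules`).
    """

    support: list[str]
    activity: np.ndarray
    loading: np.ndarray
    residual_error: float
    cell_ids: list[str]

    def loading_series(self) -> pd.Series:
        return pd.Series(self.loading, index=self.support)

    @property
    def size(self) -> int:
        return len(self.support)


@dataclass
class Decomposition:
    """Ordered list of modules in extraction order, with deflation history."""

    modules: list[NetworkModule]
    deflated: list[bool]
    global_residual: float
    total_norm: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# internal matrix plumbing


def _as_cells_by_genes(Y, genes: Sequence[str] | None):
    """Accept an ExpressionMatrix (stored gene x cell) or ndarray (cell x gene)."""
    if isinstance(Y, ExpressionMatrix):
        return np.ascontiguousarray(Y.values.T), list(Y.gene_ids), list(Y.cell_ids)
    arr = np.asarray(Y, dtype=float)
    if genes is None:
        raise ValidationError("gene ids required when Y is a bare array")
    if arr.shape[1] != len(genes):
        raise ValidationError("Y columns must match gene ids")
    cells = [f"cell{i}" for i in range(arr.shape[0])]
    return arr, list(genes), cells


def _support_indices(genes: list[str], support: Iterable[str]) -> list[int]:
    index = {g: i for i, g in enumerate(genes)}
    idx = []
    for g in support:
        if g not in index:
            raise KeyError(f"gene {g!r} not in matrix")
        idx.append(index[g])
    if not idx:
        raise ValidationError("module support must be non-empty")
    return idx


def _leading_eig(gram_sub: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenpair of a small symmetric PSD matrix."""
    k = gram_sub.shape[0]
    if k == 1:
        return float(gram_sub[0, 0]), np.array([1.0])
    w, v = scipy.linalg.eigh(gram_sub, subset_by_index=[k - 1, k - 1])
    return float(max(w[0], 0.0)), v[:, 0]


def _sigma1_sq(gram: np.ndarray, idx: Sequence[int]) -> float:
    sub = gram[np.ix_(idx, idx)]
    return _leading_eig(sub)[0]


def _fit_on_indices(
    Yc: np.ndarray, gram: np.ndarray, idx: Sequence[int], total_sq: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading singular triplet of Yc[:, idx] via the support Gram matrix.

    Returns (activity, unit-norm loading, residual_error) with the
    sum(loading) >= 0 sign convention.
    """
    s2, b = _leading_eig(gram[np.ix_(idx, idx)])
    ssum = b.sum()
    if ssum < 0 or (ssum == 0 and b[np.flatnonzero(b)[0] if np.any(b) else 0] < 0):
        b = -b
    a = Yc[:, idx] @ b
    residual = float(np.sqrt(max(total_sq - s2, 0.0)))
    return a, b, residual


def rank1_fit(
    Y, support: Iterable[str], genes: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best rank-1 approximation of Y with loading restricted to ``support``.

    ``Y`` may be an :class:`ExpressionMatrix` (z-score stage expected) or a
    cells x genes array with explicit ``genes``. Returns
    ``(activity, loading, residual_error)`` where ``loading`` is unit-norm
    over the support genes in the order given, ``activity = Y[:, S] @ loading``
    and ``residual_error = sqrt(||Y||_F^2 - sigma_1(Y[:, S])^2)``.
    Deterministic up to the sign convention sum(loading) >= 0.
    """
    Yc, gene_list, _ = _as_cells_by_genes(Y, genes)
    idx = _support_indices(gene_list, support)
    sub = Yc[:, idx]
    gram = sub.T @ sub
    total_sq = float(np.sum(Yc * Yc))
    full_idx = list(range(len(idx)))
    a, b, residual = _fit_on_indices(sub, gram, full_idx, total_sq)
    return a, b, residual


# ---------------------------------------------------------------------------
# connectivity


def is_connected(support: Iterable[str], g: PPIGraph) -> bool:
    """True iff the induced subgraph on ``support`` has one component."""
    nodes = list(dict.fromkeys(support))
    if not nodes:
        raise ValidationError("connectivity undefined for the empty gene set")
    missing = [n for n in nodes if n not in g.graph]
    if missing:
        raise KeyError(f"genes not in network: {missing[:5]}")
    if len(nodes) == 1:
        return True
    import networkx as nx

    return nx.is_connected(g.graph.subgraph(nodes))


# ---------------------------------------------------------------------------
# greedy search


def greedy_module_search(
    Y,
    g: PPIGraph,
    seed_gene: str,
    max_size: int = 80,
    min_gain: float = 1e-4,
    genes: Sequence[str] | None = None,
    _gram: np.ndarray | None = None,
    _total_sq: float | None = None,
) -> NetworkModule:
    """Grow a connected module from ``seed_gene`` by steepest residual descent.

    Starting from S = {seed}, repeatedly add the PPI neighbor of S whose
    inclusion most decreases the residual error; stop when the best relative
    gain drops below ``min_gain`` or |S| reaches ``max_size``. Ties are broken
    by lexicographic gene id, making the search fully deterministic.
    """
    Yc, gene_list, cell_ids = _as_cells_by_genes(Y, genes)
    if seed_gene not in g.graph:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    if seed_gene not in gene_list:
        raise KeyError(f"seed gene {seed_gene!r} not in matrix")
    if max_size < 1:
        raise ValidationError("max_size must be >= 1")
    index = {gname: i for i, gname in enumerate(gene_list)}
    measured = set(gene_list)

    gram = _gram if _gram is not None else Yc.T @ Yc
    total_sq = _total_sq if _total_sq is not None else float(np.sum(Yc * Yc))

    support = [seed_gene]
    idx = [index[seed_gene]]
    s2 = _sigma1_sq(gram, idx)
    residual = float(np.sqrt(max(total_sq - s2, 0.0)))

    while len(support) < max_size and residual > 0:
        frontier = set()
        for node in support:
            frontier |= g.neighbors(node)
        frontier = sorted((frontier - set(support)) & measured)
        if not frontier:
            break
        best_gene, best_res = None, residual
        for cand in frontier:
            s2_new = _sigma1_sq(gram, idx + [index[cand]])
            res_new = float(np.sqrt(max(total_sq - s2_new, 0.0)))
            if res_new < best_res:  # strict: lexicographic first wins ties
                best_gene, best_res = cand, res_new
        if best_gene is None:
            break
        gain = (residual - best_res) / residual
        if gain < min_gain:
            break
        support.append(best_gene)
        idx.append(index[best_gene])
        residual = best_res

    order = np.argsort(support)  # canonical lexicographic support order
    support = [support[i] for i in order]
    idx = [idx[i] for i in order]
    a, b, residual = _fit_on_indices(Yc, gram, idx, total_sq)
    return NetworkModule(support, a, b, residual, cell_ids)


# ---------------------------------------------------------------------------
# exhaustive oracle


def _connected_subsets(g: PPIGraph, nodes: Sequence[str], max_size: int, budget: int):
    """Yield every connected subset of size <= max_size exactly once (ESU-style)."""
    order = {n: i for i, n in enumerate(sorted(nodes))}
    adj = {n: sorted(g.neighbors(n) & set(nodes)) for n in nodes}
    count = 0

    def extend(sub: list[str], ext: list[str], root_rank: int):
        nonlocal count
        count += 1
        if count > budget:
            raise ResourceError(
                f"connected-subgraph enumeration exceeded budget of {budget}"
            )
        yield tuple(sub)
        if len(sub) == max_size:
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            excl = set(sub) | {u for s in sub for u in adj[s]}
            new_ext = ext + [
                u for u in adj[w] if order[u] > root_rank and u not in excl
            ]
            yield from extend(sub + [w], new_ext, root_rank)

    for v in sorted(nodes):
        ext0 = [u for u in adj[v] if order[u] > order[v]]
        yield from extend([v], ext0, order[v])


def brute_force_best_module(
    Y,
    g: PPIGraph,
    max_size: int,
    genes: Sequence[str] | None = None,
    budget: int = 200_000,
) -> NetworkModule:
    """Exhaustive search over all connected subsets of size <= ``max_size``.

    Test oracle for the greedy search; aborts with :class:`ResourceError` once
    the enumeration exceeds ``budget`` subsets. Ties are broken by smaller
    support, then lexicographic gene order.
    """
    Yc, gene_list, cell_ids = _as_cells_by_genes(Y, genes)
    measured = set(gene_list)
    nodes = [n for n in g.nodes if n in measured]
    if not nodes:
        raise ValidationError("no network node is measured in the matrix")
    index = {gname: i for i, gname in enumerate(gene_list)}
    gram = Yc.T @ Yc
    total_sq = float(np.sum(Yc * Yc))

    best_key, best_subset = None, None
    for subset in _connected_subsets(g, nodes, max_size, budget):
        idx = [index[n] for n in subset]
        s2 = _sigma1_sq(gram, idx)
        residual = float(np.sqrt(max(total_sq - s2, 0.0)))
        key = (residual, len(subset), tuple(sorted(subset)))
        if best_key is None or key < best_key:
            best_key, best_subset = key, subset
    support = sorted(best_subset)
    idx = [index[n] for n in support]
    a, b, residual = _fit_on_indices(Yc, gram, idx, total_sq)
    return NetworkModule(support, a, b, residual, cell_ids)


# ---------------------------------------------------------------------------
# full decomposition


def _seed_scores(gram: np.ndarray, gene_list: list[str], g: PPIGraph) -> np.ndarray:
    """Seed ranking: per-gene sum over PPI neighbors of squared correlation.

    On z-scored data every gene has unit variance, so variance itself cannot
    rank seeds; genes inside a co-activated connected module instead stand out
    by correlating with their network neighbors. The score stays meaningful on
    deflated matrices, where residual variances differ.
    """
    diag = np.maximum(np.diag(gram), 1e-300)
    index = {gname: i for i, gname in enumerate(gene_list)}
    scores = np.zeros(len(gene_list))
    for i, gname in enumerate(gene_list):
        if gname not in g.graph:
            scores[i] = -np.inf
            continue
        nbr = [index[n] for n in g.neighbors(gname) if n in index]
        if nbr:
            r2 = gram[i, nbr] ** 2 / (diag[i] * diag[nbr])
            scores[i] = float(np.sum(r2))
    return scores


def detect_modules(
    Y,
    g: PPIGraph,
    K: int = 3,
    n_seeds: int = 10,
    max_size: int = 80,
    min_gain: float = 1e-4,
    deflate: bool = True,
    rng_seed: int = 0,
    genes: Sequence[str] | None = None,
) -> Decomposition:
    """Extract up to K connected modules by multi-seed greedy search.

    Each round ranks unclaimed genes by neighbor co-expression, runs
    :func:`greedy_module_search` from the ``n_seeds`` best seeds on the
    current (possibly deflated) matrix, and keeps the module with the lowest
    residual. Reported residual errors are always computed against the
    ORIGINAL matrix so that modules from different rounds are comparable.
    With ``deflate=True`` the fitted term is subtracted before the next round,
    which lets genes participate in several overlapping modules.

    The procedure is deterministic: the greedy search breaks ties
    lexicographically and seeding is score-ranked. ``rng_seed`` is accepted
    for interface stability and recorded in logs.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    Y0, gene_list, cell_ids = _as_cells_by_genes(Y, genes)
    Ycur = Y0.copy()
    total_sq0 = float(np.sum(Y0 * Y0))
    gram0 = Y0.T @ Y0

    modules: list[NetworkModule] = []
    deflated_flags: list[bool] = []
    deflation_sum = np.zeros_like(Y0)
    claimed: set[str] = set()
    logger.info("detect_modules: K=%d n_seeds=%d max_size=%d rng_seed=%d",
                K, n_seeds, max_size, rng_seed)

    for round_no in range(K):
        gram_cur = Ycur.T @ Ycur
        total_sq_cur = float(np.sum(Ycur * Ycur))
        scores = _seed_scores(gram_cur, gene_list, g)
        candidates = [
            (-scores[i], gname)
            for i, gname in enumerate(gene_list)
            if np.isfinite(scores[i]) and gname not in claimed
        ]
        if not candidates:
            logger.warning("round %d: no unclaimed network genes left; stopping at %d modules",
                           round_no + 1, len(modules))
            break
        candidates.sort()
        seeds = [gname for _, gname in candidates[:n_seeds]]

        best: NetworkModule | None = None
        for seed in seeds:
            mod = greedy_module_search(
                Ycur, g, seed, max_size=max_size, min_gain=min_gain,
                genes=gene_list, _gram=gram_cur, _total_sq=total_sq_cur,
            )
            key = (mod.residual_error, mod.size, tuple(mod.support))
            if best is None or key < (best.residual_error, best.size, tuple(best.support)):
                best = mod
        assert best is not None

        # deflation term is fitted on the CURRENT matrix; the reported module
        # is refit on the original matrix so residuals stay comparable
        idx = _support_indices(gene_list, best.support)
        a_cur, b_cur, _ = _fit_on_indices(Ycur, gram_cur, idx, total_sq_cur)
        a0, b0, res0 = _fit_on_indices(Y0, gram0, idx, total_sq0)
        modules.append(NetworkModule(list(best.support), a0, b0, res0, cell_ids))
        claimed |= set(best.support)
        deflated_flags.append(bool(deflate))
        if deflate:
            term = np.zeros_like(Y0)
            term[:, idx] = np.outer(a_cur, b_cur)
            Ycur = Ycur - term
            deflation_sum += term
        logger.info("round %d: module of %d genes, residual %.4f (original matrix)",
                    round_no + 1, len(best.support), res0)

    if not modules:
        raise ValidationError("no module could be extracted (empty graph/matrix overlap)")

    if deflate:
        global_residual = float(np.linalg.norm(Y0 - deflation_sum))
    else:
        # joint least-squares refit of activities with loadings fixed
        B = np.zeros((len(gene_list), len(modules)))
        for k, mod in enumerate(modules):
            B[_support_indices(gene_list, mod.support), k] = mod.loading
        A, *_ = np.linalg.lstsq(B, Y0.T, rcond=None)
        global_residual = float(np.linalg.norm(Y0 - (B @ A).T))
    return Decomposition(modules, deflated_flags, global_residual,
                         total_norm=float(np.sqrt(total_sq0)))


# ---------------------------------------------------------------------------
# downstream summaries


def top_cells(mod: NetworkModule, n: int = 100) -> list[str]:
    """The ``n`` cells with highest module activity (signed), descending.

    Ties are resolved by cell order, so the result is deterministic.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if n > len(mod.cell_ids):
        raise ValidationError(f"n={n} exceeds {len(mod.cell_ids)} cells")
    order = np.argsort(-mod.activity, kind="stable")
    return [mod.cell_ids[i] for i in order[:n]]


@dataclass
class MarkerTrend:
    """Binned trend of max-over-gene-set expression against a marker gene."""

    table: pd.DataFrame  # columns: bin_center, mean_of_max, ci_low, ci_high, n
    trend_rho: float
    trend_p: float


def marker_trend(
    m: ExpressionMatrix,
    cells: Sequence[str],
    gene_set: Sequence[str],
    marker: str,
    n_bins: int = 10,
) -> MarkerTrend:
    """Trend of the per-cell max over ``gene_set`` against marker expression.

    For each cell the maximum log expression over the gene set is taken
    (e.g. the strongest-expressed zinc-finger of a detected module); cells are
    then split into ``n_bins`` equal-count bins along the marker (e.g. the
    adipogenic marker FABP4) and the per-bin mean with a normal-approximation
    95% CI is reported. ``trend_rho`` is the Spearman correlation between the
    per-cell max and the marker across all selected cells.
    """
    if m.stage not in ("log", "zscore"):
        raise ValidationError("marker_trend expects a log- or zscore-stage matrix")
    if marker not in m.gene_ids:
        raise ValidationError(f"marker {marker!r} not in matrix")
    genes = [g for g in gene_set if g in set(m.gene_ids)]
    if not genes:
        raise ValidationError("gene_set empty after intersecting with matrix genes")
    cell_index = {c: i for i, c in enumerate(m.cell_ids)}
    missing = [c for c in cells if c not in cell_index]
    if missing:
        raise ValidationError(f"unknown cells: {missing[:5]}")
    cidx = [cell_index[c] for c in cells]
    if n_bins < 1 or n_bins > len(cidx):
        raise ValidationError("n_bins must be in [1, n_cells]")

    gidx = [m.gene_ids.index(g) for g in genes]
    max_expr = m.values[np.ix_(gidx, cidx)].max(axis=0)
    marker_expr = m.values[m.gene_ids.index(marker), cidx]

    rho, pval = scipy.stats.spearmanr(max_expr, marker_expr)

    order = np.argsort(marker_expr, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        vals = max_expr[chunk]
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({
            "bin_center": float(marker_expr[chunk].mean()),
            "mean_of_max": mean,
            "ci_low": mean - 1.96 * sem,
            "ci_high": mean + 1.96 * sem,
            "n": int(len(chunk)),
        })
    return MarkerTrend(pd.DataFrame(rows), float(rho), float(pval))
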