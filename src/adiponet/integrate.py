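"""Linking clonal bulk phenotypes to single-cell clusters.

Clonally expanded preadipocyte lines carry measurable metabolic phenotypes
(basal oxygen consumption OCR, extracellular acidification ECAR, radiolabeled
2-deoxy-glucose uptake, and post-differentiation PPARG expression as a proxy
for adipogenic capacity). Per phenotype, a *phenotype correlation vector*
holds the Spearman correlation between the phenotype and every gene across
clones; projecting that vector onto single cells (Spearman correlation with
each cell's expression profile) scores how strongly each cell expresses the
phenotype-associated gene signature. Cluster-level differences in these
projections are assessed by one-way ANOVA with Bonferroni control of the
family-wise error rate.

Also implemented: the clone-level clustering used to define the phenotype
groups (k-medoids with silhouette-based model selection over k, hierarchical
subclustering) and the extreme-clone comparison between clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.metrics import silhouette_score

from .errors import ParseError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger("adiponet.integrate")

PHENOTYPES = ("OCR", "ECAR", "glucose_uptake", "PPARG_post")


@dataclass
class PhenotypeTable:
    """Per-clone phenotype measurements; missing values allowed.

    Units follow the assays: OCR in pmol O2/min per DNA unit, ECAR in mpH/min
    per DNA unit, glucose uptake in DPM per protein unit, PPARG_post in
    relative mRNA units (measured after 18-21 days of differentiation).
    """

    data: pd.DataFrame  # index: clone ids; columns: phenotype names
    subjects: pd.Series | None = None  # optional clone -> subject map

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate clone ids in phenotype table")
        self.data = self.data.astype(float)

    @property
    def clone_ids(self) -> list[str]:
        return [str(c) for c in self.data.index]

    @property
    def phenotypes(self) -> list[str]:
        return list(self.data.columns)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV: clone_id, optional subject_id, one column per assay."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    if "clone_id" not in df.columns:
        raise ParseError(f"{path}: missing clone_id column")
    df = df.set_index("clone_id")
    subjects = None
    if "subject_id" in df.columns:
        subjects = df.pop("subject_id").astype(str)
    return PhenotypeTable(df, subjects)


@dataclass
class PhenotypeCorrelation:
    """Per-gene Spearman correlation of one phenotype across clones."""

    phenotype: str
    rho_by_gene: pd.Series  # index: gene ids; NaN for zero-variance genes
    n_used: int

    def __post_init__(self) -> None:
        finite = self.rho_by_gene.dropna()
        if len(finite) and ((finite < -1 - 1e-12).any() or (finite > 1 + 1e-12).any()):
            raise ValidationError("Spearman rho outside [-1, 1]")


@dataclass
class CellProjection:
    """Per-cell Spearman correlation with a phenotype correlation vector."""

    phenotype: str
    rho_by_cell: pd.Series  # index: cell ids; NaN for degenerate profiles
    n_genes: int


# ---------------------------------------------------------------------------
# Spearman machinery (vectorized; average ranks for ties)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, axis=-1, method="average")


def _pearson_rows_vs_vec(R: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of matrix R with vector r; NaN if degenerate."""
    Rc = R - R.mean(axis=1, keepdims=True)
    rc = r - r.mean()
    num = Rc @ rc
    den = np.sqrt((Rc * Rc).sum(axis=1) * (rc * rc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def phenotype_vectors(
    clonal: ExpressionMatrix, pheno: PhenotypeTable
) -> list[PhenotypeCorrelation]:
    """Spearman-correlate each phenotype with every gene across clones.

    Clone ids are inner-joined between expression (cell axis) and phenotype
    table; per phenotype only clones with a non-missing value contribute
    (pairwise-complete). Ties receive average ranks. Genes with zero variance
    across the contributing clones get NaN.
    """
    shared = [c for c in clonal.cell_ids if c in set(pheno.clone_ids)]
    if len(shared) < 3:
        raise ValidationError(
            f"need >=3 clones shared between expression and phenotypes, got {len(shared)}"
        )
    cidx = [clonal.cell_ids.index(c) for c in shared]
    X = clonal.values[:, cidx]  # gene x clone
    out = []
    for ph in pheno.phenotypes:
        y = pheno.data.loc[shared, ph].to_numpy()
        ok = np.isfinite(y)
        if ok.sum() < 3:
            logger.warning("phenotype %s has %d non-missing clones; correlations set to NaN",
                           ph, int(ok.sum()))
            rho = pd.Series(np.nan, index=clonal.gene_ids)
            out.append(PhenotypeCorrelation(ph, rho, int(ok.sum())))
            continue
        R = _rank_rows(X[:, ok])
        r = _rank_rows(y[ok])
        vals = _pearson_rows_vs_vec(R, r)
        out.append(PhenotypeCorrelation(ph, pd.Series(vals, index=clonal.gene_ids),
                                        int(ok.sum())))
    return out


def project_to_cells(
    pc: PhenotypeCorrelation, sc: ExpressionMatrix, min_genes: int = 10
) -> CellProjection:
    """Project a phenotype correlation vector onto single cells.

    Per cell: Spearman correlation between the vector's per-gene rho and the
    cell's expression, over genes shared between the two and with non-missing
    rho. Cells with a constant profile over those genes get NaN (warned).
    """
    rho = pc.rho_by_gene.dropna()
    shared = [g for g in sc.gene_ids if g in set(rho.index)]
    if len(shared) < min_genes:
        raise ValidationError(
            f"gene intersection {len(shared)} below floor {min_genes}"
        )
    gidx = [sc.gene_ids.index(g) for g in shared]
    E = sc.values[gidx, :]  # shared genes x cells
    R = _rank_rows(E.T)  # per-cell ranks over shared genes
    r = _rank_rows(rho.loc[shared].to_numpy())
    vals = _pearson_rows_vs_vec(R, r)
    n_bad = int(np.isnan(vals).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} cells have constant expression over the {len(shared)} "
            f"shared genes; projection recorded as missing", stacklevel=2,
        )
    return CellProjection(pc.phenotype, pd.Series(vals, index=sc.cell_ids), len(shared))


# ---------------------------------------------------------------------------
# ANOVA on projections


def compare_cluster_projections(
    projections: CellProjection | Sequence[CellProjection],
    labels: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of projection scores between clusters, per day x phenotype.

    ``labels`` is a table with columns cell_id, cluster and (optionally) day;
    without a day column all cells form one stratum. Within each day, cells
    are grouped by cluster and the projection scores compared by one-way
    ANOVA; Bonferroni correction is applied across ALL (day x phenotype)
    tests: FWER = min(1, m * p). Days with fewer than two clusters of >=2
    cells are skipped with a log notice.
    """
    if isinstance(projections, CellProjection):
        projections = [projections]
    lab = labels.copy()
    if "day" not in lab.columns:
        lab["day"] = 0
    rows = []
    for day, sub in lab.groupby("day", sort=True):
        for proj in projections:
            groups = []
            for _, cells in sub.groupby("cluster", sort=True):
                vals = proj.rho_by_cell.reindex(cells["cell_id"]).dropna().to_numpy()
                if len(vals) >= 2:
                    groups.append(vals)
            if len(groups) < 2:
                logger.info("day %r: fewer than two usable clusters; skipped", day)
                continue
            F, p = scipy.stats.f_oneway(*groups)
            rows.append({"day": day, "phenotype": proj.phenotype,
                         "F": float(F), "p": float(p)})
    if not rows:
        raise ValidationError("no (day, phenotype) stratum had two usable clusters")
    out = pd.DataFrame(rows)
    m = len(out)
    out["FWER"] = np.minimum(1.0, m * out["p"])
    logger.info("Bonferroni over m=%d tests; %d significant at FWER<%g",
                m, int((out["FWER"] < alpha).sum()), alpha)
    return out


# ---------------------------------------------------------------------------
# clone clustering


@dataclass
class ClonesClustering:
    k_star: int
    labels: pd.Series  # clone -> cluster id (0-based)
    silhouettes: dict[int, float] = field(default_factory=dict)


def _pam(D: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int = 0) -> np.ndarray:
    """k-medoids with deterministic BUILD init and Voronoi refinement.

    BUILD greedily picks medoids minimizing total distance (ties by index),
    so the default run is deterministic and clone-order invariant up to exact
    distance ties; optional random restarts (seeded) can only improve cost.
    """
    n = D.shape[0]

    def refine(medoids: list[int]) -> tuple[list[int], np.ndarray, float]:
        medoids = list(medoids)
        for _ in range(100):
            assign = np.argmin(D[:, medoids], axis=1)
            new = []
            for j in range(k):
                members = np.flatnonzero(assign == j)
                if members.size == 0:
                    new.append(medoids[j])
                    continue
                costs = D[np.ix_(members, members)].sum(axis=0)
                new.append(int(members[np.argmin(costs)]))
            if new == medoids:
                break
            medoids = new
        assign = np.argmin(D[:, medoids], axis=1)
        cost = float(D[np.arange(n), [medoids[j] for j in assign]].sum())
        return medoids, assign, cost

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(dmin - D[:, c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    best = refine(medoids)
    for _ in range(n_restarts):
        cand = refine(list(rng.choice(n, size=k, replace=False)))
        if cand[2] < best[2]:
            best = cand
    return best[1]


def cluster_clones(
    clonal: ExpressionMatrix,
    k_range: Iterable[int] = range(2, 11),
    rng_seed: int = 0,
    n_restarts: int = 5,
    silhouette_warn: float = 0.3,
) -> ClonesClustering:
    """k-medoids clustering of clone profiles with silhouette model selection.

    Euclidean distances between clone expression profiles; for each k in
    ``k_range`` a seeded k-medoids partition is computed and the k maximizing
    the average silhouette width is selected (ties to the smaller k). A low
    best silhouette (< ``silhouette_warn``) triggers a warning, indicating
    the data may form a single blob.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValidationError("k_range must contain integers >= 2")
    n = clonal.n_cells
    if n <= ks[0]:
        raise ValidationError(f"{n} clones cannot support k >= {ks[0]}")
    usable = [k for k in ks if k < n]
    dropped = [k for k in ks if k >= n]
    if dropped:
        logger.info("dropping k values %s (>= %d clones)", dropped, n)
    X = clonal.values.T  # clones x genes
    D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(X, "euclidean"))
    rng = np.random.default_rng(rng_seed)
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in usable:
        assign = _pam(D, k, rng, n_restarts=n_restarts)
        labels_by_k[k] = assign
        if len(np.unique(assign)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(D, assign, metric="precomputed"))
    k_star = max(usable, key=lambda k: (sil[k], -k))
    if sil[k_star] < silhouette_warn:
        warnings.warn(
            f"best average silhouette {sil[k_star]:.3f} < {silhouette_warn}; "
            "clones may not form distinct clusters", stacklevel=2,
        )
    labels = pd.Series(labels_by_k[k_star], index=clonal.cell_ids, name="cluster")
    logger.info("cluster_clones: k*=%d (silhouette %.3f)", k_star, sil[k_star])
    return ClonesClustering(k_star, labels, sil)


def subcluster_clones(clonal: ExpressionMatrix, n_clusters: int = 5) -> pd.Series:
    """Average-linkage hierarchical clustering on correlation distance.

    The tree is cut to yield ``n_clusters`` groups (with ~35 clones and the
    default of five, average group size is seven lines). Identical profiles
    have zero distance and always co-cluster.
    """
    if n_clusters < 2:
        raise ValidationError("n_clusters must be >= 2")
    n = clonal.n_cells
    if n < n_clusters:
        raise ValidationError(f"{n} clones cannot form {n_clusters} clusters")
    X = clonal.values.T
    d = scipy.spatial.distance.pdist(X, "correlation")
    d = np.maximum(d, 0.0)  # guard tiny negative rounding
    Z = scipy.cluster.hierarchy.linkage(d, method="average")
    flat = scipy.cluster.hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(flat - 1, index=clonal.cell_ids, name="subcluster")


# ---------------------------------------------------------------------------
# extreme-clone comparison


def extreme_clone_test(
    clonal: ExpressionMatrix,
    labels: pd.Series,
    pheno: PhenotypeTable,
    n_extreme: int = 7,
) -> pd.DataFrame:
    """Compare the most extreme clones of two clusters, per phenotype.

    "Most extreme" is defined by the projection of each clone's profile onto
    the axis joining the two cluster centroids, measured from the midpoint:
    the clones farthest out on their own cluster's side. The ``n_extreme``
    most extreme clones per cluster are compared by one-way ANOVA per
    phenotype, with Bonferroni correction across phenotypes. A selected clone
    missing a phenotype value is replaced by the next most extreme (logged).
    """
    labels = labels.reindex(clonal.cell_ids).dropna()
    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise ValidationError(f"exactly two clusters required, got {len(clusters)}")
    members = {c: [cl for cl in clonal.cell_ids if cl in labels.index and labels[cl] == c]
               for c in clusters}
    for c in clusters:
        if len(members[c]) < n_extreme:
            raise ValidationError(
                f"cluster {c!r} has {len(members[c])} clones < n_extreme={n_extreme}"
            )
    X = clonal.to_frame().T  # clones x genes
    cent = {c: X.loc[members[c]].mean(axis=0).to_numpy() for c in clusters}
    axis = cent[clusters[1]] - cent[clusters[0]]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("cluster centroids coincide; extremeness undefined")
    axis /= norm
    midpoint = (cent[clusters[0]] + cent[clusters[1]]) / 2
    proj = (X.to_numpy() - midpoint) @ axis
    proj = pd.Series(proj, index=X.index)

    sign = {clusters[0]: -1.0, clusters[1]: 1.0}
    selected: dict[object, list[str]] = {}
    for c in clusters:
        ranked = sorted(members[c], key=lambda cl: (-sign[c] * proj[cl], cl))
        selected[c] = ranked  # consumed per phenotype below

    rows = []
    for ph in pheno.phenotypes:
        groups = []
        for c in clusters:
            vals, taken = [], 0
            for cl in selected[c]:
                v = pheno.data.at[cl, ph] if cl in pheno.data.index else np.nan
                if np.isfinite(v):
                    vals.append(float(v))
                    taken += 1
                    if taken == n_extreme:
                        break
                else:
                    logger.info("clone %s missing %s; using next most extreme", cl, ph)
            if taken < n_extreme:
                logger.warning("cluster %r: only %d clones with %s values", c, taken, ph)
            groups.append(np.asarray(vals))
        if min(len(g) for g in groups) < 2:
            logger.warning("phenotype %s skipped: fewer than 2 values per group", ph)
            continue
        F, p = scipy.stats.f_oneway(*groups)
        rows.append({"phenotype": ph, "F": float(F), "p": float(p),
                     "n_A": len(groups[0]), "n_B": len(groups[1])})
    if not rows:
        raise ValidationError("no phenotype had enough values for the comparison")
    out = pd.DataFrame(rows)
    out["FWER"] = np.minimum(1.0, len(out) * out["p"])
    return out


def subject_center(clonal: ExpressionMatrix, subjects: pd.Series) -> ExpressionMatrix:
    """Remove per-subject mean expression from clone profiles.

    A simple surrogate for donor-effect normalization of clonal lines:
    each gene's mean over the clones of one subject is subtracted from those
    clones, so between-subject offsets cannot drive clone clustering.
    """
    if clonal.stage == "raw":
        raise ValidationError("subject centering expects log-scale expression")
    subjects = subjects.reindex(clonal.cell_ids)
    if subjects.isna().any():
        raise ValidationError("every clone needs a subject id for centering")
    vals = clonal.values.copy()
    for _, clones in subjects.groupby(subjects):
        idx = [clonal.cell_ids.index(c) for c in clones.index]
        vals[:, idx] -= vals[:, idx].mean(axis=1, keepdims=True)
    return ExpressionMatrix(vals, list(clonal.gene_ids), list(clonal.cell_ids),
                            stage=clonal.stage)
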