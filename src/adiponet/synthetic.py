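"""Synthetic fixtures with known ground truth.

Three generators mirror the data the pipeline consumes:

* :func:`simulate_ppi` — a random interactome containing planted gene
  supports that are guaranteed connected (random spanning tree per module
  plus extra within-module edges) on top of Erdos-Renyi background edges;
* :func:`simulate_counts` — negative-binomial UMI counts whose latent
  log2-mean is a sum of planted rank-1 module terms (per-cell activity x
  per-gene loading) plus a baseline, with lognormal per-cell library-size
  factors. NB (rather than Poisson) noise reproduces the overdispersion the
  z-score pipeline must survive;
* :func:`simulate_clones` — clonal expression with two planted clusters and
  gene programs whose per-clone activity drives the four metabolic
  phenotypes (OCR, ECAR, glucose uptake, post-differentiation PPARG) at a
  configurable effect size.

:func:`simulate_zscore_matrix` additionally provides the idealized
Gaussian-noise regime (z-level signal + unit noise) used for estimator-level
recovery analyses. Every generator is bit-deterministic given
``spec.rng_seed`` and returns its ground truth so tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import ExpressionMatrix, PPIGraph
from .integrate import PHENOTYPES, PhenotypeTable

import pandas as pd


@dataclass
class ModuleSpec:
    """One planted module: support size, activity SD, loading scale."""

    size: int
    activity_sd: float = 1.0
    loading_scale: float = 1.0


@dataclass
class SimulationSpec:
    """Parameters of all three generators; defaults give a detectable but
    noisy regime (unit activity SD and loadings against unit z-score noise).
    """

    n_genes: int = 300
    n_cells: int = 300
    n_clones: int = 35
    modules: list[ModuleSpec] = field(default_factory=lambda: [ModuleSpec(10)])
    background_edge_prob: float = 0.01
    within_module_edge_prob: float = 0.3
    nb_dispersion: float = 5.0  # NB size parameter; smaller = more overdispersed
    library_size_mean: float = 1.0  # mean per-cell scale factor
    library_size_sd: float = 0.3  # lognormal sigma of the factors
    baseline_log_mean: float = 3.0  # log2 scale; ~8 UMI per gene per cell
    # clone generator
    cluster_separation: float = 5.0  # per-marker-gene shift between clusters, SD units
    n_cluster_genes: int = 50
    program_size: int = 20
    phenotype_effects: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {ph: (i, 2.0) for i, ph in enumerate(PHENOTYPES)}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1 or self.n_clones < 1:
            raise ValidationError("dimensions must be positive")
        total = sum(m.size for m in self.modules)
        for m in self.modules:
            if m.size < 1:
                raise ValidationError("module size must be >= 1")
            if m.activity_sd < 0 or m.loading_scale < 0:
                raise ValidationError("module scales must be non-negative")
        if total > self.n_genes:
            raise ValidationError("planted supports exceed n_genes")
        if not 0 <= self.background_edge_prob <= 1:
            raise ValidationError("background_edge_prob must be in [0,1]")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValidationError("dispersion and library size must be positive")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _cell_ids(n: int) -> list[str]:
    return [f"C{i:04d}" for i in range(n)]


def _clone_ids(n: int) -> list[str]:
    return [f"CL{i:02d}" for i in range(n)]


def simulate_ppi(spec: SimulationSpec) -> tuple[PPIGraph, list[list[str]]]:
    """Random PPI graph with planted connected supports (ground truth returned)."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_ids(spec.n_genes)
    perm = rng.permutation(spec.n_genes)
    supports: list[list[str]] = []
    edges: set[tuple[str, str]] = set()
    pos = 0
    for mod in spec.modules:
        members = sorted(genes[i] for i in perm[pos:pos + mod.size])
        pos += mod.size
        supports.append(members)
        # random spanning tree keeps the support connected by construction
        shuffled = list(rng.permutation(members))
        for i in range(1, len(shuffled)):
            j = int(rng.integers(0, i))
            edges.add(tuple(sorted((shuffled[i], shuffled[j]))))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < spec.within_module_edge_prob:
                    edges.add(tuple(sorted((members[i], members[j]))))
    if spec.background_edge_prob > 0:
        iu, ju = np.triu_indices(spec.n_genes, k=1)
        mask = rng.random(iu.size) < spec.background_edge_prob
        for i, j in zip(iu[mask], ju[mask]):
            edges.add(tuple(sorted((genes[i], genes[j]))))
    return PPIGraph.from_edges(sorted(edges), nodes=genes), supports


def _loadings(
    rng: np.random.Generator, supports: list[list[str]], spec: SimulationSpec,
    genes: list[str],
) -> list[np.ndarray]:
    index = {g: i for i, g in enumerate(genes)}
    out = []
    for mod, sup in zip(spec.modules, supports):
        b = np.zeros(len(genes))
        b[[index[g] for g in sup]] = mod.loading_scale * rng.uniform(0.8, 1.2, len(sup))
        out.append(b)
    return out


def simulate_counts(
    spec: SimulationSpec, supports: list[list[str]]
) -> tuple[ExpressionMatrix, dict]:
    """NB-distributed UMI counts with planted rank-1 structure in the log-mean.

    latent log2-mean(gene, cell) = baseline + sum_k a_k(cell) * b_k(gene),
    counts ~ NegativeBinomial(size=nb_dispersion, mean=libsize * 2^latent).
    Returns the raw matrix and ground truth (activities, loadings, supports,
    library factors).
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    genes, cells = _gene_ids(spec.n_genes), _cell_ids(spec.n_cells)
    loadings = _loadings(rng, supports, spec, genes)
    activities = [
        rng.normal(0.0, mod.activity_sd, spec.n_cells) for mod in spec.modules
    ]
    latent = np.full((spec.n_genes, spec.n_cells), spec.baseline_log_mean)
    for a, b in zip(activities, loadings):
        latent += np.outer(b, a)
    lib = spec.library_size_mean * rng.lognormal(
        -spec.library_size_sd**2 / 2, spec.library_size_sd, spec.n_cells
    )
    mean = np.clip(lib[None, :] * np.exp2(latent), 1e-9, 1e7)
    r = spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
    truth = {
        "supports": supports,
        "activities": [a.tolist() for a in activities],
        "loadings": [b.tolist() for b in loadings],
        "library_factors": lib.tolist(),
    }
    return ExpressionMatrix(counts, genes, cells, stage="raw"), truth


def simulate_zscore_matrix(
    spec: SimulationSpec, supports: list[list[str]]
) -> tuple[ExpressionMatrix, dict]:
    """Planted rank-1 signal plus unit Gaussian noise, standardized per gene.

    The idealized regime of the decomposition model: Y = sum_k a_k b_k^T + E
    with E ~ N(0, 1), then each gene standardized (sample SD) so the result
    is a valid z-score-stage matrix.
    """
    rng = np.random.default_rng(spec.rng_seed + 2)
    genes, cells = _gene_ids(spec.n_genes), _cell_ids(spec.n_cells)
    loadings = _loadings(rng, supports, spec, genes)
    activities = [
        rng.normal(0.0, mod.activity_sd, spec.n_cells) for mod in spec.modules
    ]
    vals = rng.normal(0.0, 1.0, (spec.n_genes, spec.n_cells))
    for a, b in zip(activities, loadings):
        vals += np.outer(b, a)
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    truth = {
        "supports": supports,
        "activities": [a.tolist() for a in activities],
        "loadings": [b.tolist() for b in loadings],
    }
    return ExpressionMatrix(vals, genes, cells, stage="zscore"), truth


def simulate_clones(spec: SimulationSpec) -> tuple[ExpressionMatrix, PhenotypeTable, dict]:
    """Clonal expression with two planted clusters and phenotype-linked programs.

    Clones split evenly into clusters A/B separated by ``cluster_separation``
    SD on ``n_cluster_genes`` marker genes. Each phenotype named in
    ``phenotype_effects`` reads out one gene program: program genes share a
    per-clone latent activity t ~ N(0,1) and the phenotype equals
    effect_size * t + N(0,1). Returns expression (log stage), the phenotype
    table, and ground truth (labels, program gene ids, activities).
    """
    rng = np.random.default_rng(spec.rng_seed + 3)
    genes, clones = _gene_ids(spec.n_genes), _clone_ids(spec.n_clones)
    n_half = spec.n_clones // 2
    labels = np.array([0] * n_half + [1] * (spec.n_clones - n_half))

    vals = rng.normal(0.0, 1.0, (spec.n_genes, spec.n_clones))
    n_marker = min(spec.n_cluster_genes, spec.n_genes)
    vals[:n_marker, labels == 1] += spec.cluster_separation

    program_ids = sorted({pid for pid, _ in spec.phenotype_effects.values()})
    programs: dict[int, list[str]] = {}
    start = n_marker
    for pid in program_ids:
        lo = start + pid * spec.program_size
        hi = lo + spec.program_size
        if hi > spec.n_genes:
            raise ValidationError("n_genes too small for the requested programs")
        programs[pid] = genes[lo:hi]

    activities = {pid: rng.normal(0.0, 1.0, spec.n_clones) for pid in program_ids}
    index = {g: i for i, g in enumerate(genes)}
    for pid, members in programs.items():
        gidx = [index[g] for g in members]
        vals[gidx, :] += activities[pid][None, :]

    pheno = {}
    for ph, (pid, effect) in spec.phenotype_effects.items():
        pheno[ph] = effect * activities[pid] + rng.normal(0.0, 1.0, spec.n_clones)
    table = PhenotypeTable(pd.DataFrame(pheno, index=clones))

    expr = ExpressionMatrix(vals, genes, clones, stage="log")
    truth = {
        "cluster_labels": labels.tolist(),
        "programs": {str(pid): members for pid, members in programs.items()},
        "program_activities": {str(pid): a.tolist() for pid, a in activities.items()},
    }
    return expr, table, truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialize ground truth alongside generated fixtures."""
    Path(path).write_text(json.dumps(truth, indent=1))


def spec_to_json(spec: SimulationSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(spec), indent=1))


def spec_from_json(path: str | Path) -> SimulationSpec:
    raw = json.loads(Path(path).read_text())
    raw["modules"] = [ModuleSpec(**m) for m in raw.get("modules", [])]
    raw["phenotype_effects"] = {
        k: tuple(v) for k, v in raw.get("phenotype_effects", {}).items()
    }
    return SimulationSpec(**raw)
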