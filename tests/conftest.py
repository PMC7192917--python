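import numpy as np
import pytest

from adiponet import (
    ExpressionMatrix,
    PPIGraph,
    ModuleSpec,
    SimulationSpec,
    simulate_ppi,
    simulate_zscore_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    """3 genes x 2 cells with column sums {7, 4}."""
    return ExpressionMatrix(
        np.array([[0, 1], [2, 0], [5, 3]], dtype=float),
        ["GA", "GB", "GC"],
        ["c1", "c2"],
        stage="raw",
    )


@pytest.fixture
def path_graph():
    """Path A-B-C-D-E."""
    nodes = ["A", "B", "C", "D", "E"]
    return PPIGraph.from_edges(list(zip(nodes[:-1], nodes[1:])))


@pytest.fixture
def planted_case():
    """Seeded graph + z-level matrix with one planted 10-gene module."""
    spec = SimulationSpec(
        n_genes=100, n_cells=300, modules=[ModuleSpec(10)], rng_seed=7
    )
    graph, supports = simulate_ppi(spec)
    zmat, truth = simulate_zscore_matrix(spec, supports)
    return zmat, graph, supports, truth


def random_zscore_matrix(rng, n_genes, n_cells):
    """Valid zscore-stage matrix of pure noise."""
    vals = rng.normal(size=(n_genes, n_cells))
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    return ExpressionMatrix(
        vals, [f"G{i:03d}" for i in range(n_genes)],
        [f"C{i:03d}" for i in range(n_cells)], stage="zscore",
    )
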