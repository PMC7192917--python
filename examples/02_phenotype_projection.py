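"""Project clonal metabolic phenotypes onto single cells.

Simulates clonal preadipocyte lines whose glucose uptake reads out a planted
gene program, builds phenotype correlation vectors (per-gene Spearman rho
across clones), projects them onto single cells, and tests whether two cell
clusters differ in the projected scores (ANOVA + Bonferroni).
"""

import numpy as np
import pandas as pd

from adiponet import (
    ExpressionMatrix,
    SimulationSpec,
    compare_cluster_projections,
    phenotype_vectors,
    project_to_cells,
    simulate_clones,
)

spec = SimulationSpec(
    n_genes=200, n_clones=30,
    phenotype_effects={"glucose_uptake": (0, 2.0), "OCR": (1, 0.0)},
    rng_seed=2,
)
clonal, pheno, truth = simulate_clones(spec)
vectors = phenotype_vectors(clonal, pheno)

# single cells: one cluster expresses the glucose-linked program, one does not
rng = np.random.default_rng(2)
program = truth["programs"]["0"]
gidx = [clonal.gene_ids.index(g) for g in program]
vals = rng.normal(size=(200, 120))
vals[gidx, :60] += 1.5
sc = ExpressionMatrix(vals, clonal.gene_ids,
                      [f"c{i}" for i in range(120)], "log")

labels = pd.DataFrame({"cell_id": sc.cell_ids, "cluster": [0] * 60 + [1] * 60})
projections = [project_to_cells(v, sc) for v in vectors]
table = compare_cluster_projections(projections, labels)

for v in vectors:
    top = v.rho_by_gene.abs().nlargest(3)
    print(f"{v.phenotype:>15}: top |rho| genes {list(top.index)} "
          f"(rho up to {top.iloc[0]:.2f}, {v.n_used} clones)")
print(table.to_string(index=False))
# The glucose_uptake projection separates the clusters far more strongly
# (F an order of magnitude larger) because its correlation vector is anchored
# in the planted program. The zero-effect OCR vector is pure noise over genes,
# yet still reaches significance: its chance rank overlap with the shifted
# program genes is amplified by treating 120 cells as independent samples —
# a caveat to keep in mind when reading per-cell projection ANOVAs.
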