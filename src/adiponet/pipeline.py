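"""End-to-end pipeline: QC -> normalize -> detect modules -> project phenotypes.

:class:`RunConfig` collects every path and algorithm parameter;
:func:`run_pipeline` executes the stages in dependency order and writes a
manifest (file list + SHA-256 checksums + the echoed configuration) so a run
can be verified as reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as aio
from . import integrate, netdecomp
from .errors import ValidationError

logger = logging.getLogger("adiponet.pipeline")


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run.

    Precedence when built by the CLI: defaults < JSON config file < explicit
    command-line flags. The effective config is serialized verbatim into the
    output directory.
    """

    out_dir: str = "adiponet_run"
    counts: str | None = None
    network: str | None = None
    phenotypes: str | None = None
    clonal_counts: str | None = None
    labels: str | None = None
    # parameters
    min_detected: int = 1000
    constant_gene_policy: str = "drop"
    k_modules: int = 3
    max_size: int = 80
    n_seeds: int = 10
    min_gain: float = 1e-4
    deflate: bool = True
    top_n_cells: int = 100
    n_bins: int = 10
    n_extreme: int = 7
    k_min: int = 2
    k_max: int = 10
    min_shared_genes: int = 10
    rng_seed: int = 0

    def validate(self) -> None:
        if self.min_detected < 0:
            raise ValidationError("min_detected must be >= 0")
        if self.k_modules < 1 or self.max_size < 1 or self.n_seeds < 1:
            raise ValidationError("k_modules, max_size and n_seeds must be >= 1")
        if not (2 <= self.k_min <= self.k_max):
            raise ValidationError("need 2 <= k_min <= k_max")
        if self.min_gain < 0:
            raise ValidationError("min_gain must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_modules_json(dec: netdecomp.Decomposition, path: Path) -> None:
    payload = {
        "global_residual": dec.global_residual,
        "total_norm": dec.total_norm,
        "modules": [
            {
                "support": m.support,
                "loading": m.loading.tolist(),
                "residual_error": m.residual_error,
                "deflated": dec.deflated[i],
            }
            for i, m in enumerate(dec.modules)
        ],
    }
    path.write_text(json.dumps(payload, indent=1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage the config provides inputs for; return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": [], "files": {}}

    def emit(path: Path) -> None:
        written.append(path)

    stage = "config"
    try:
        cfg_path = out / "config.json"
        cfg_path.write_text(json.dumps(dataclasses.asdict(cfg), indent=1))
        emit(cfg_path)

        sc_z = None
        sc_log = None
        graph = None
        if cfg.counts:
            stage = "qc"
            raw = aio.read_counts(cfg.counts)
            kept = aio.qc_filter_cells(raw, cfg.min_detected)
            manifest["stages"].append({
                "stage": "qc", "cells_in": raw.n_cells, "cells_out": kept.n_cells,
                "genes": raw.n_genes,
            })
            stage = "normalize"
            sc_log = aio.log_transform(kept)
            sc_z = aio.zscore_genes(sc_log, cfg.constant_gene_policy)
            z_path = out / "zscores.tsv"
            sc_z.to_frame().to_csv(z_path, sep="\t")
            emit(z_path)
            manifest["stages"].append({
                "stage": "normalize", "genes_out": sc_z.n_genes,
            })

        modules = None
        if cfg.counts and cfg.network:
            stage = "detect"
            graph = aio.read_sif(cfg.network)
            sc_aligned, g_aligned = aio.align_to_graph(sc_z, graph)
            dec = netdecomp.detect_modules(
                sc_aligned, g_aligned, K=cfg.k_modules, n_seeds=cfg.n_seeds,
                max_size=cfg.max_size, min_gain=cfg.min_gain,
                deflate=cfg.deflate, rng_seed=cfg.rng_seed,
            )
            modules = dec
            mod_path = out / "modules.json"
            _write_modules_json(dec, mod_path)
            emit(mod_path)
            act = pd.DataFrame(
                {f"module_{i}": m.activity for i, m in enumerate(dec.modules)},
                index=dec.modules[0].cell_ids,
            )
            act_path = out / "activities.tsv"
            act.to_csv(act_path, sep="\t", index_label="cell_id")
            emit(act_path)
            manifest["stages"].append({
                "stage": "detect", "n_modules": len(dec.modules),
                "residuals": [m.residual_error for m in dec.modules],
            })

        if cfg.clonal_counts and cfg.phenotypes:
            stage = "project"
            clonal = aio.read_expression(cfg.clonal_counts)
            pheno = integrate.read_phenotypes(cfg.phenotypes)
            if pheno.subjects is not None:
                clonal = integrate.subject_center(clonal, pheno.subjects)
            vectors = integrate.phenotype_vectors(clonal, pheno)
            vec_path = out / "phenotype_vectors.tsv"
            pd.DataFrame({v.phenotype: v.rho_by_gene for v in vectors}).to_csv(
                vec_path, sep="\t", index_label="gene_id"
            )
            emit(vec_path)
            if sc_log is not None:
                projections = [
                    integrate.project_to_cells(v, sc_log, cfg.min_shared_genes)
                    for v in vectors
                ]
                proj_path = out / "projections.tsv"
                pd.DataFrame(
                    {p.phenotype: p.rho_by_cell for p in projections}
                ).to_csv(proj_path, sep="\t", index_label="cell_id")
                emit(proj_path)
                if cfg.labels:
                    stage = "compare"
                    labels = aio.read_labels(cfg.labels)
                    anova = integrate.compare_cluster_projections(projections, labels)
                    an_path = out / "projection_anova.tsv"
                    anova.to_csv(an_path, sep="\t", index=False)
                    emit(an_path)

            stage = "clones"
            clustering = integrate.cluster_clones(
                clonal, range(cfg.k_min, cfg.k_max + 1), rng_seed=cfg.rng_seed
            )
            lab_path = out / "clone_clusters.tsv"
            clustering.labels.to_frame().to_csv(lab_path, sep="\t", index_label="clone_id")
            emit(lab_path)
            manifest["stages"].append({
                "stage": "clones", "k_star": clustering.k_star,
                "silhouettes": clustering.silhouettes,
            })
            if clustering.k_star == 2:
                extreme = integrate.extreme_clone_test(
                    clonal, clustering.labels, pheno, cfg.n_extreme
                )
                ext_path = out / "extreme_clone_anova.tsv"
                extreme.to_csv(ext_path, sep="\t", index=False)
                emit(ext_path)
    except Exception as exc:
        manifest["error"] = {"stage": stage, "cause": str(exc)}
        manifest["files"] = {str(p): _sha256(p) for p in written if p.exists()}
        manifest["partial"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in written}
    manifest["partial"] = False
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d files in %s", len(written), out)
    return manifest
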