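"""End-to-end orchestration: simulate/load -> DE -> enrichment -> clustering -> integration.

One YAML config drives every stage; a single seed fans out to per-stage
derived seeds (fixed offsets) so each module run is independently
reproducible. All numeric outputs are TSV/JSON; a run manifest records
parameters and the sha256 of every output so reruns can be checked for
bit-identity. Any stage failure writes a FAILED marker naming the stage
and re-raises.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ripeomics import clustering, differential, enrichment, integration, io_formats
from ripeomics.synthetic_data import SimulationConfig, generate_dataset, write_dataset

logger = logging.getLogger("ripeomics")

SEED_OFFSETS = {"simulate": 0, "fcm": 101, "gsea": 202}

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    outdir: str = "ripeomics_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # alternative to simulate
    contrasts: list[list[str]] | None = None  # [[B, A], ...]; default: adjacent stages
    fpkm_threshold: float = 0.3
    deg_alpha: float = 0.05
    deg_lfc_min: float = 1.0
    dep_alpha: float = 0.05
    dep_fc_min: float = 1.3
    enrich_alpha: float = 0.05
    fcm_clusters: int = 6
    fcm_fuzzifier: float = 2.0
    fcm_tau: float = 0.5
    ward_clusters: int = 6
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_weight: float = 1.0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.outputs: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.outputs.append(p)
        return p


def _validate_contrasts(contrasts: list[list[str]], stages: list[str]) -> list[tuple[str, str]]:
    out = []
    for pair in contrasts:
        if len(pair) != 2:
            raise ValueError(f"contrast must be a [later, earlier] pair, got {pair}")
        b, a = pair
        for s in (b, a):
            if s not in stages:
                raise ValueError(f"contrast references unknown stage {s!r}")
        out.append((b, a))
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    stage_name = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage_name = "simulate"
        logger.info("=== stage: %s ===", stage_name)
        if config.inputs:
            counts = io_formats.load_expression_table(
                config.inputs["counts"], config.inputs["sample_sheet_rna"], kind="counts"
            )
            proteins = io_formats.load_expression_table(
                config.inputs["proteins"],
                config.inputs["sample_sheet_protein"],
                kind="protein_intensity",
            )
            lengths = io_formats.load_gene_lengths(config.inputs["lengths"])
            id_map = io_formats.load_id_map(config.inputs["id_map"])
            gene_sets = io_formats.load_gene_sets(config.inputs["gene_sets"])
            truth = None
        else:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed + SEED_OFFSETS["simulate"])
            for key in ("stages", "coupling", "set_size_range", "base_log2_range", "length_range"):
                if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_cfg = SimulationConfig(**sim_kwargs)
            dataset = generate_dataset(sim_cfg)
            simdir = outdir / "simulated"
            for p in write_dataset(dataset, simdir).values():
                run.outputs.append(p)
            counts, proteins = dataset.counts, dataset.proteins
            lengths, id_map, gene_sets = dataset.lengths, dataset.id_map, dataset.gene_sets
            truth = dataset.truth

        stages = counts.stages
        contrast_pairs = _validate_contrasts(
            config.contrasts
            if config.contrasts is not None
            else [[stages[i + 1], stages[i]] for i in range(len(stages) - 1)],
            stages,
        )

        # ------------------------------------------------------ fpkm + filter
        stage_name = "expression_filter"
        logger.info("=== stage: %s ===", stage_name)
        fpkm = io_formats.compute_fpkm(counts, lengths)
        io_formats.write_expression_table(fpkm, run.path("fpkm.tsv"))
        expressed = io_formats.filter_expressed(fpkm, threshold=config.fpkm_threshold)
        run.path("expressed_genes.txt").write_text("\n".join(expressed) + "\n")
        counts_expr = counts.subset_features(expressed)

        # ------------------------------------------------------ normalization
        stage_name = "normalize"
        logger.info("=== stage: %s ===", stage_name)
        sf = differential.estimate_size_factors(counts_expr)
        sf.factors.rename("size_factor").rename_axis("sample_id").to_csv(
            run.path("size_factors.tsv"), sep="\t"
        )
        norm = differential.normalize_counts(counts_expr, sf)

        # ------------------------------------------------------ DE / DEP
        stage_name = "differential"
        logger.info("=== stage: %s ===", stage_name)
        deg_results = {}
        dep_results = {}
        for b, a in contrast_pairs:
            deg = differential.test_differential_expression(
                norm, (a, b), alpha=config.deg_alpha, lfc_min=config.deg_lfc_min
            )
            dep = differential.test_differential_abundance(
                proteins, (a, b), alpha=config.dep_alpha, fc_min=config.dep_fc_min
            )
            deg_results[deg.contrast] = deg
            dep_results[dep.contrast] = dep
            differential.write_contrast_result(deg, run.path(f"deg_{deg.contrast}.tsv"))
            differential.write_contrast_result(dep, run.path(f"dep_{dep.contrast}.tsv"))

        venns = {}
        if len(contrast_pairs) == 3:
            for direction in ("up", "down"):
                for omics, results in (("rna", deg_results), ("protein", dep_results)):
                    named = {c: set(r.called(direction)) for c, r in results.items()}
                    regions = differential.venn_regions(named)
                    venns[f"{omics}_{direction}"] = {
                        "&".join(k): v for k, v in regions.items()
                    }
        run.path("venn_regions.json").write_text(json.dumps(venns, indent=2, sort_keys=True))

        # ------------------------------------------------------ enrichment
        stage_name = "enrichment"
        logger.info("=== stage: %s ===", stage_name)
        background = set(expressed)
        enr_tables = {}
        for c, deg in deg_results.items():
            de_genes = set(deg.called()) & background
            if not de_genes:
                continue
            table = enrichment.fisher_enrichment_test(
                de_genes, background, gene_sets, alpha=config.enrich_alpha
            )
            enr_tables[c] = table
            table.to_csv(run.path(f"enrichment_{c}.tsv"), sep="\t")
        if len(enr_tables) >= 2:
            matrix = enrichment.enrichment_heatmap_cluster(enr_tables)
            matrix.z_scores.to_csv(run.path("enrichment_matrix_z.tsv"), sep="\t")
            run.path("enrichment_matrix_row_order.txt").write_text(
                "\n".join(matrix.row_order) + "\n"
            )

        # ------------------------------------------------------ clustering
        stage_name = "clustering"
        logger.info("=== stage: %s ===", stage_name)
        dep_union = sorted(set().union(*(r.called() for r in dep_results.values())))
        fcm_outputs = {}
        if len(dep_union) >= config.fcm_clusters:
            prot_sm = proteins.stage_means(log2=True).loc[
                [p for p in dep_union if p in proteins.values.index]
            ]
            fcm = clustering.fuzzy_cmeans(
                prot_sm,
                c=config.fcm_clusters,
                m=config.fcm_fuzzifier,
                seed=config.seed + SEED_OFFSETS["fcm"],
            )
            assign = clustering.assign_fuzzy_clusters(fcm, tau=config.fcm_tau)
            fcm.centers.rename_axis("cluster").to_csv(run.path("fcm_centers.tsv"), sep="\t")
            fcm.membership.rename_axis("feature_id").to_csv(
                run.path("fcm_membership.tsv"), sep="\t"
            )
            assign.rename_axis("feature_id").to_csv(run.path("fcm_assignments.tsv"), sep="\t")
            fcm_outputs["n_assigned"] = int((assign != "unassigned").sum())
            fcm_outputs["n_items"] = int(len(assign))

        pca_rna, var_rna = clustering.pca_scores(counts_expr)
        pca_prot, var_prot = clustering.pca_scores(proteins)
        pca_rna.rename_axis("sample_id").to_csv(run.path("pca_rna.tsv"), sep="\t")
        pca_prot.rename_axis("sample_id").to_csv(run.path("pca_protein.tsv"), sep="\t")
        clustering.sample_correlation_matrix(counts_expr).rename_axis("sample_id").to_csv(
            run.path("sample_correlation_rna.tsv"), sep="\t"
        )
        clustering.sample_correlation_matrix(proteins).rename_axis("sample_id").to_csv(
            run.path("sample_correlation_protein.tsv"), sep="\t"
        )

        # ------------------------------------------------------ integration
        stage_name = "integration"
        logger.info("=== stage: %s ===", stage_name)
        paired = integration.pair_omics(counts, proteins, id_map)
        paired, summary = integration.per_gene_correlation(paired)
        paired.per_gene_r.rename_axis("gene_id").to_csv(
            run.path("per_gene_correlation.tsv"), sep="\t"
        )
        corr_json = {
            "stage_r": summary.stage_r,
            "stage_r2": summary.stage_r2,
            "fraction_positive": summary.fraction_positive,
            "mean_r": summary.mean_r,
            "n_genes": summary.n_genes,
        }
        run.path("correlation_summary.json").write_text(json.dumps(corr_json, indent=2))

        gsea_table = integration.gsea(
            paired.per_gene_r,
            gene_sets,
            n_perm=config.gsea_n_perm,
            seed=config.seed + SEED_OFFSETS["gsea"],
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
            weight=config.gsea_weight,
        )
        gsea_table.to_csv(run.path("gsea.tsv"), sep="\t")

        # ward co-clustering of paired centred profiles (rna || protein stage means)
        co_profiles = pd.concat(
            [
                paired.centered("rna").add_prefix("rna_"),
                paired.centered("protein").add_prefix("prot_"),
            ],
            axis=1,
        )
        ward = clustering.ward_hierarchical(co_profiles, k=config.ward_clusters)
        ward.assignments.rename_axis("gene_id").to_csv(
            run.path("ward_coclusters.tsv"), sep="\t"
        )
        run.path("ward_leaf_order.txt").write_text("\n".join(ward.leaf_order) + "\n")

        stat_rows = []
        last_contrast = deg_results[list(deg_results)[-1]]
        for name, gs in gene_sets.items():
            members = [m for m in gs.members if m in last_contrast.table.index]
            if not members:
                continue
            mean_lfc, direction = integration.set_stat_mean(last_contrast, members)
            stat_rows.append((name, mean_lfc, direction))
        pd.DataFrame(stat_rows, columns=["set", "stat_mean", "direction"]).to_csv(
            run.path("stat_mean.tsv"), sep="\t", index=False
        )

        # ------------------------------------------------------ manifest
        stage_name = "manifest"
        logger.info("=== stage: %s ===", stage_name)
        manifest = {
            "parameters": asdict(config),
            "fcm": fcm_outputs,
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p)
                for p in sorted(set(run.outputs))
                if p.exists()
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage_name}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
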