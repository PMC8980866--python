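"""Paired multi-omics simulator with planted ground truth.

Generates a gene-level negative-binomial count matrix and a log-normal
protein intensity matrix over a staged time course (default 4 stages x 3
replicates), driven by six temporal templates (monotone up/down, early
peak, late peak, transient dip, flat). Protein latent levels are coupled
to the per-stage across-gene standardized mRNA latent through a
stage-decaying coupling schedule ``rho_s``, so the across-gene
mRNA-protein correlation at each stage is a planted, recoverable
parameter. Planted gene sets (template-aligned sets, a decoupled set,
random background sets) give every downstream stage a recovery oracle.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ripeomics.io_formats import (
    ExpressionMatrix,
    GeneLengthTable,
    GeneSet,
    GeneSetCollection,
    IdMap,
    write_expression_table,
    write_gene_lengths,
    write_gene_sets,
    write_id_map,
    write_sample_sheet,
)

TEMPLATE_NAMES = (
    "monotone_up",
    "monotone_down",
    "early_peak",
    "late_peak",
    "transient_dip",
    "flat",
)

DEFAULT_STAGES = ("10DAP", "18DAP", "26DAP", "34DAP")
DEFAULT_COUPLING = (0.8, 0.7, 0.55, 0.40)
DEFAULT_FRACTIONS = {
    "monotone_up": 0.1,
    "monotone_down": 0.1,
    "early_peak": 0.1,
    "late_peak": 0.1,
    "transient_dip": 0.1,
    "flat": 0.5,
}

__all__ = [
    "TEMPLATE_NAMES",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "template_shapes",
    "generate_dataset",
    "simulate_counts",
    "simulate_proteins",
    "plant_gene_sets",
    "write_dataset",
    "load_config",
    "save_config",
]


def template_shapes(n_stages: int) -> dict[str, np.ndarray]:
    """Unit template shapes over ``n_stages`` stages (log2 offsets per unit effect).

    Shapes are scaled so the largest adjacent-stage step has magnitude 1;
    multiplying by the configured effect size therefore yields that log2
    fold change between at least one adjacent stage pair.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    up = np.arange(n_stages, dtype=float)
    early = np.zeros(n_stages)
    early[1] = 1.0
    late = np.zeros(n_stages)
    late[-1] = 1.0
    dip = np.zeros(n_stages)
    dip[0] = 1.0
    dip[-1] = 1.0
    return {
        "monotone_up": up,
        "monotone_down": up[::-1].copy(),
        "early_peak": early,
        "late_peak": late,
        "transient_dip": dip,
        "flat": np.zeros(n_stages),
    }


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_proteins: int = 600
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 3
    template_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    effect_size: float = 2.0  # log2FC of the largest adjacent step, non-flat templates
    dispersion: float = 0.03  # NB phi: var = mu + phi * mu^2 (pooled-replicate design)
    library_size: float = 2e6
    library_jitter: float = 0.1  # +/- fraction, uniform
    protein_noise_sd: float = 0.15  # replicate-level log2 noise (TMT-like CV)
    protein_scale: float = 2.0  # log2 units per latent z
    protein_base: float = 10.0  # log2 baseline intensity
    coupling: tuple[float, ...] = DEFAULT_COUPLING  # rho_s per stage
    n_background_sets: int = 50
    set_size_range: tuple[int, int] = (15, 40)
    aligned_set_purity: float = 0.9
    decoupled_set_size: int = 20
    base_log2_range: tuple[float, float] = (3.0, 9.0)
    length_range: tuple[int, int] = (500, 10000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins must be <= n_genes")
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ValueError("need n_genes >= 1 and n_replicates >= 2")
        total = sum(self.template_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template fractions must sum to 1, got {total}")
        unknown = set(self.template_fractions) - set(TEMPLATE_NAMES)
        if unknown:
            raise ValueError(f"unknown template names: {sorted(unknown)}")
        if len(self.coupling) != len(self.stages):
            raise ValueError("coupling schedule length must match number of stages")
        if any(not 0.0 <= r <= 1.0 for r in self.coupling):
            raise ValueError("coupling values must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid set size range")
        if hi > self.n_proteins:
            raise ValueError("set size range exceeds number of proteins")
        if self.decoupled_set_size > self.n_proteins:
            raise ValueError("decoupled set larger than protein panel")
        if not 0.0 < self.aligned_set_purity <= 1.0:
            raise ValueError("aligned_set_purity must be in (0, 1]")

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """Adjacent stage pairs as (later, earlier)."""
        return [(self.stages[i + 1], self.stages[i]) for i in range(len(self.stages) - 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for every recovery test."""

    templates: pd.Series  # gene_id -> template name
    de_status: pd.DataFrame  # genes x contrast labels, values up/down/unchanged (mRNA)
    protein_de_status: pd.DataFrame  # panel genes x contrasts, from planted protein latent
    coupling: tuple[float, ...]
    stages: tuple[str, ...]
    aligned_sets: dict[str, str]  # template name -> set name
    decoupled_set: str
    decoupled_genes: tuple[str, ...]
    panel_genes: tuple[str, ...]  # genes with a measured protein

    def de_genes(self, contrast: str, direction: str | None = None) -> list[str]:
        col = self.de_status[contrast]
        if direction is None:
            mask = col != "unchanged"
        else:
            mask = col == direction
        return list(self.de_status.index[mask])


@dataclass
class SyntheticDataset:
    counts: ExpressionMatrix
    proteins: ExpressionMatrix
    lengths: GeneLengthTable
    id_map: IdMap
    gene_sets: GeneSetCollection
    truth: SyntheticTruth
    config: SimulationConfig


def _assign_templates(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic template counts (largest remainder), randomized placement."""
    G = config.n_genes
    names = [t for t in TEMPLATE_NAMES if t in config.template_fractions]
    fracs = np.array([config.template_fractions[t] for t in names])
    counts = np.floor(fracs * G).astype(int)
    remainder = G - counts.sum()
    order = np.argsort(-(fracs * G - counts))
    for i in range(remainder):
        counts[order[i % len(names)]] += 1
    labels = np.repeat(names, counts)
    return rng.permutation(labels)


def _latent_log2_means(
    config: SimulationConfig, templates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene per-stage log2 expression means: baseline + scaled template shape."""
    shapes = template_shapes(len(config.stages))
    lo, hi = config.base_log2_range
    base = rng.uniform(lo, hi, size=config.n_genes)
    shape_mat = np.stack([shapes[t] for t in templates])
    return base[:, None] + config.effect_size * shape_mat


def _sample_names(config: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    names, stages, reps = [], [], []
    for s in config.stages:
        for r in range(1, config.n_replicates + 1):
            names.append(f"{s}_R{r}")
            stages.append(s)
            reps.append(r)
    meta = pd.DataFrame(
        {"stage": stages, "replicate": reps}, index=pd.Index(names, name="sample_id")
    )
    return names, meta


def simulate_counts(
    latent_log2: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Negative-binomial counts around library-scaled latent means.

    ``counts[g, j] ~ NB(mu, var = mu + phi * mu^2)`` with
    ``mu = lib_j * 2^latent[g, s(j)] / sum_g 2^latent[g, s(j)]``.
    With ``dispersion == 0`` draws are Poisson.
    """
    if not np.all(np.isfinite(latent_log2)):
        raise ValueError("latent means must be finite")
    G, S = latent_log2.shape
    names, meta = _sample_names(config)
    phi = config.dispersion
    cols = {}
    for j, name in enumerate(names):
        s = j // config.n_replicates
        lib = config.library_size * (
            1.0 + config.library_jitter * rng.uniform(-1.0, 1.0)
        )
        q = np.exp2(latent_log2[:, s])
        total = q.sum()
        mu = lib * q / total if total > 0 else np.zeros(G)
        if phi > 0:
            # numpy NB(n, p): mean n(1-p)/p -> n = 1/phi, p = 1/(1 + phi*mu)
            n = 1.0 / phi
            p = 1.0 / (1.0 + phi * mu)
            draws = rng.negative_binomial(n, p)
        else:
            draws = rng.poisson(mu)
        cols[name] = draws.astype(float)
    if gene_ids is None:
        gene_ids = [f"GENE_{i:05d}" for i in range(G)]
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="feature_id"))
    return ExpressionMatrix(values, meta, "counts")


def simulate_proteins(
    mrna_latent_log2: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    protein_ids: Sequence[str],
    decoupled_mask: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Protein intensities coupled to the standardized mRNA latent.

    At each stage the mRNA latent (restricted to the protein panel) is
    standardized across genes to ``z``; the protein latent is
    ``rho_eff * z + sqrt(1 - rho_eff^2) * eps`` with a gene-level noise
    term ``eps`` shared across stages (a per-gene translational offset).
    Decoupled genes drop the ``z`` term entirely (their protein latent is
    the pure gene offset), and the coupled genes' ``rho_eff`` is inflated
    by ``1 / (1 - f_decoupled)`` so the panel-wide across-gene correlation
    matches the configured ``rho_s`` schedule exactly at the latent level.

    Intensities are ``2 ** (base + scale * z_protein + replicate noise)``.
    """
    P, S = mrna_latent_log2.shape
    if decoupled_mask is None:
        decoupled_mask = np.zeros(P, dtype=bool)
    f_dec = decoupled_mask.mean()
    eps_gene = rng.standard_normal(P)
    z_prot = np.empty((P, S))
    for s in range(S):
        lat = mrna_latent_log2[:, s]
        sd = lat.std()
        if sd == 0:
            z = np.zeros(P)
        else:
            z = (lat - lat.mean()) / sd
        rho_eff = min(1.0, config.coupling[s] / (1.0 - f_dec)) if f_dec < 1 else 0.0
        z_prot[:, s] = rho_eff * z + np.sqrt(max(0.0, 1.0 - rho_eff**2)) * eps_gene
        z_prot[decoupled_mask, s] = eps_gene[decoupled_mask]
    names, meta = _sample_names(config)
    cols = {}
    for j, name in enumerate(names):
        s = j // config.n_replicates
        noise = rng.normal(0.0, config.protein_noise_sd, size=P)
        cols[name] = np.exp2(
            config.protein_base + config.protein_scale * z_prot[:, s] + noise
        )
    values = pd.DataFrame(cols, index=pd.Index(protein_ids, name="feature_id"))
    return ExpressionMatrix(values, meta, "protein_intensity"), z_prot


def plant_gene_sets(
    templates: pd.Series,
    panel_genes: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, dict[str, str], str, tuple[str, ...]]:
    """Background random sets plus template-aligned and decoupled planted sets.

    Returns ``(collection, aligned_sets, decoupled_name, decoupled_genes)``.
    All members are drawn from the protein panel so every set overlaps the
    paired (GSEA-rankable) gene space. Template-aligned sets draw at least
    ``aligned_set_purity`` of their members from that template's genes.
    """
    lo, hi = config.set_size_range
    panel = list(panel_genes)
    panel_templates = templates.loc[panel]
    sets: list[GeneSet] = []
    aligned: dict[str, str] = {}
    used_by_aligned: set[str] = set()
    for t in TEMPLATE_NAMES:
        if config.template_fractions.get(t, 0.0) <= 0.0:
            continue  # template not planted: nothing to align a set to
        pool = list(panel_templates.index[panel_templates == t])
        size = int(rng.integers(lo, hi + 1))
        n_pure = int(np.ceil(config.aligned_set_purity * size))
        if len(pool) < n_pure:
            raise ValueError(
                f"infeasible set geometry: template {t!r} has {len(pool)} panel genes, "
                f"need {n_pure}"
            )
        pure = list(rng.choice(pool, size=n_pure, replace=False))
        others = [g for g in panel if g not in set(pure)]
        fill = list(rng.choice(others, size=size - n_pure, replace=False))
        name = f"SET_{t.upper()}"
        sets.append(GeneSet(name, f"planted template-aligned set ({t})", tuple(pure + fill)))
        aligned[t] = name
        used_by_aligned.update(pure + fill)
    free = [g for g in panel if g not in used_by_aligned]
    if len(free) < config.decoupled_set_size:
        raise ValueError("infeasible set geometry: not enough free panel genes for decoupled set")
    dec_genes = tuple(rng.choice(free, size=config.decoupled_set_size, replace=False))
    dec_name = "SET_DECOUPLED"
    sets.append(GeneSet(dec_name, "planted decoupled set (rho forced to 0)", dec_genes))
    for i in range(config.n_background_sets):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(panel, size=size, replace=False))
        sets.append(GeneSet(f"SET_BG_{i:03d}", "random background set", members))
    return GeneSetCollection(sets), aligned, dec_name, dec_genes


def _de_truth(config: SimulationConfig, templates: np.ndarray, gene_ids: Sequence[str]) -> pd.DataFrame:
    shapes = template_shapes(len(config.stages))
    labels = [f"{b}vs{a}" for b, a in config.contrasts]
    out = pd.DataFrame(
        "unchanged", index=pd.Index(gene_ids, name="feature_id"), columns=labels
    )
    for i, (b, a) in enumerate(config.contrasts):
        step = np.array([shapes[t][i + 1] - shapes[t][i] for t in templates])
        lfc = config.effect_size * step
        out.iloc[lfc > 1.0, i] = "up"
        out.iloc[lfc < -1.0, i] = "down"
    return out


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate the full paired dataset; a pure function of ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = _assign_templates(config, rng)
    gene_ids = [f"GENE_{i:05d}" for i in range(config.n_genes)]
    latent = _latent_log2_means(config, templates, rng)
    lo, hi = config.length_range
    lengths = GeneLengthTable(
        pd.Series(
            np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes)).astype(np.int64),
            index=pd.Index(gene_ids, name="feature_id"),
        )
    )
    panel_idx = np.sort(rng.choice(config.n_genes, size=config.n_proteins, replace=False))
    panel_genes = [gene_ids[i] for i in panel_idx]
    protein_ids = [f"PROT_{gene_ids[i][5:]}" for i in panel_idx]
    id_map = IdMap(list(zip(panel_genes, protein_ids)))

    tmpl_series = pd.Series(templates, index=pd.Index(gene_ids, name="feature_id"))
    gene_sets, aligned, dec_name, dec_genes = plant_gene_sets(
        tmpl_series, panel_genes, config, rng
    )
    decoupled_mask = np.isin(panel_genes, dec_genes)

    counts = simulate_counts(latent, config, rng, gene_ids=gene_ids)
    proteins, z_prot = simulate_proteins(
        latent[panel_idx, :], config, rng, protein_ids, decoupled_mask=decoupled_mask
    )
    # protein DE truth from the planted protein latent (log2FC = scale * delta z)
    fc_cut = np.log2(1.3)
    prot_labels = [f"{b}vs{a}" for b, a in config.contrasts]
    prot_de = pd.DataFrame(
        "unchanged", index=pd.Index(panel_genes, name="feature_id"), columns=prot_labels
    )
    for i in range(len(config.stages) - 1):
        lfc = config.protein_scale * (z_prot[:, i + 1] - z_prot[:, i])
        prot_de.iloc[lfc > fc_cut, i] = "up"
        prot_de.iloc[lfc < -fc_cut, i] = "down"
    truth = SyntheticTruth(
        templates=tmpl_series,
        de_status=_de_truth(config, templates, gene_ids),
        protein_de_status=prot_de,
        coupling=tuple(config.coupling),
        stages=tuple(config.stages),
        aligned_sets=aligned,
        decoupled_set=dec_name,
        decoupled_genes=tuple(dec_genes),
        panel_genes=tuple(panel_genes),
    )
    return SyntheticDataset(counts, proteins, lengths, id_map, gene_sets, truth, config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all simulated tables (plus truth labels) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "proteins": outdir / "proteins.tsv",
        "sample_sheet_rna": outdir / "samples_rna.tsv",
        "sample_sheet_protein": outdir / "samples_protein.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "id_map": outdir / "id_map.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "templates": outdir / "truth_templates.tsv",
        "de_status": outdir / "truth_de_status.tsv",
        "protein_de_status": outdir / "truth_protein_de_status.tsv",
    }
    write_expression_table(dataset.counts, paths["counts"])
    write_expression_table(dataset.proteins, paths["proteins"])
    write_sample_sheet(dataset.counts.sample_meta, paths["sample_sheet_rna"])
    write_sample_sheet(dataset.proteins.sample_meta, paths["sample_sheet_protein"])
    write_gene_lengths(dataset.lengths, paths["lengths"])
    write_id_map(dataset.id_map, paths["id_map"])
    write_gene_sets(dataset.gene_sets, paths["gene_sets"])
    dataset.truth.templates.rename("template").to_csv(paths["templates"], sep="\t")
    dataset.truth.de_status.to_csv(paths["de_status"], sep="\t")
    dataset.truth.protein_de_status.to_csv(paths["protein_de_status"], sep="\t")
    return paths


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["template_fractions"] = dict(config.template_fractions)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    for key in ("stages", "coupling", "set_size_range", "base_log2_range", "length_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg
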