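"""mRNA-protein pairing, correlation analysis and correlation-ranked GSEA.

Paired genes carry log2(x+1) stage-mean profiles for both omics.
Per-stage (across-gene) Pearson correlations quantify how tightly protein
levels track transcripts at each time point; per-gene Pearson
correlations across stage means feed the correlation-ranked GSEA. The
GSEA enrichment score is the classic weighted Kolmogorov-Smirnov running
sum; the permutation null draws size-matched random gene sets from the
ranked universe (gene-set permutation: the ranking statistic is a
per-gene correlation, so phenotype labels cannot be permuted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ripeomics.differential import ContrastResult
from ripeomics.io_formats import ExpressionMatrix, GeneSetCollection, IdMap

__all__ = [
    "PairedOmics",
    "CorrelationSummary",
    "pair_omics",
    "stage_correlation",
    "per_gene_correlation",
    "correlation_summary",
    "gsea_enrichment_score",
    "gsea",
    "set_stat_mean",
]


@dataclass
class PairedOmics:
    """Per-gene aligned mRNA and protein measurements over a shared stage axis."""

    genes: pd.DataFrame  # index gene_id, column protein_id
    stages: list[str]
    rna_stage_means: pd.DataFrame  # genes x stages, log2(x+1) replicate means
    prot_stage_means: pd.DataFrame
    rna_values: pd.DataFrame  # genes x rna samples (raw scale)
    prot_values: pd.DataFrame
    rna_meta: pd.DataFrame
    prot_meta: pd.DataFrame
    per_gene_r: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    def centered(self, omics: str) -> pd.DataFrame:
        """Stage means minus the per-gene mean (the scatter/co-clustering scale)."""
        df = self.rna_stage_means if omics == "rna" else self.prot_stage_means
        return df.sub(df.mean(axis=1), axis=0)


@dataclass
class CorrelationSummary:
    stage_r: dict[str, float]
    stage_r2: dict[str, float]
    fraction_positive: float
    mean_r: float
    n_genes: int


def pair_omics(rna: ExpressionMatrix, prot: ExpressionMatrix, id_map: IdMap) -> PairedOmics:
    """Align mRNA and protein matrices through the gene<->protein ID map.

    Stage labels must agree between the omics (replicate counts may
    differ). One record is produced per mapped gene present in both
    matrices; stage means are replicate means of log2(x+1).
    """
    if list(rna.stages) != list(prot.stages):
        raise ValueError(
            f"stage labels disagree between omics: {rna.stages} vs {prot.stages}"
        )
    keep_genes = []
    keep_prots = []
    for g, p in id_map.pairs:
        if g in rna.values.index and p in prot.values.index:
            keep_genes.append(g)
            keep_prots.append(p)
    if not keep_genes:
        raise ValueError("no overlap between mapped genes and the two matrices")
    rna_sub = rna.values.loc[keep_genes]
    prot_sub = prot.values.loc[keep_prots]
    prot_sub.index = pd.Index(keep_genes, name="feature_id")
    rna_sm = rna.stage_means(log2=True).loc[keep_genes]
    prot_sm = prot.stage_means(log2=True).loc[keep_prots]
    prot_sm.index = pd.Index(keep_genes, name="feature_id")
    genes = pd.DataFrame(
        {"protein_id": keep_prots}, index=pd.Index(keep_genes, name="gene_id")
    )
    return PairedOmics(
        genes=genes,
        stages=list(rna.stages),
        rna_stage_means=rna_sm,
        prot_stage_means=prot_sm,
        rna_values=rna_sub,
        prot_values=prot_sub,
        rna_meta=rna.sample_meta.copy(),
        prot_meta=prot.sample_meta.copy(),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def stage_correlation(paired: PairedOmics, stage: str) -> tuple[float, float]:
    """Across-gene Pearson r (and R^2) between the two omics at one stage.

    Computed on uncentered log2 stage means: at a single stage the
    per-gene centering used for scatter plots removes the baseline signal
    the coupling acts on, so the uncentered values are what estimate the
    stage's coupling strength.
    """
    if stage not in paired.stages:
        raise KeyError(f"unknown stage {stage!r}")
    x = paired.rna_stage_means[stage].to_numpy(dtype=float)
    y = paired.prot_stage_means[stage].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 genes with defined values")
    r = _pearson(x[ok], y[ok])
    return r, r * r


def per_gene_correlation(
    paired: PairedOmics, mode: str = "stage_means"
) -> tuple[PairedOmics, CorrelationSummary]:
    """Per-gene Pearson r between mRNA and protein profiles, plus summaries.

    ``mode="stage_means"`` (default) correlates the S stage-mean values;
    ``mode="replicates"`` correlates all stage/replicate combinations by
    matching replicate indices within stages. Genes with zero variance in
    either profile get NaN and are excluded from summary denominators.
    """
    if len(paired.stages) < 3:
        raise ValueError("need at least 3 stages for per-gene correlations")
    if mode == "stage_means":
        X = paired.rna_stage_means.to_numpy(dtype=float)
        Y = paired.prot_stage_means.to_numpy(dtype=float)
    elif mode == "replicates":
        cols_x, cols_y = [], []
        for s in paired.stages:
            rx = paired.rna_meta.index[paired.rna_meta["stage"] == s]
            ry = paired.prot_meta.index[paired.prot_meta["stage"] == s]
            for cx, cy in zip(rx, ry):
                cols_x.append(cx)
                cols_y.append(cy)
        X = np.log2(paired.rna_values[cols_x].to_numpy(dtype=float) + 1.0)
        Y = np.log2(paired.prot_values[cols_y].to_numpy(dtype=float) + 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    den = np.sqrt((Xc**2).sum(axis=1) * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Xc * Yc).sum(axis=1) / den, -1.0, 1.0)
    r[den == 0] = np.nan
    r_series = pd.Series(r, index=paired.genes.index, name="pearson_r")
    paired.per_gene_r = r_series
    defined = r_series.dropna()
    summary = CorrelationSummary(
        stage_r={s: stage_correlation(paired, s)[0] for s in paired.stages},
        stage_r2={s: stage_correlation(paired, s)[1] for s in paired.stages},
        fraction_positive=float((defined > 0).mean()) if len(defined) else np.nan,
        mean_r=float(defined.mean()) if len(defined) else np.nan,
        n_genes=int(len(defined)),
    )
    return paired, summary


def correlation_summary(paired: PairedOmics, mode: str = "stage_means") -> CorrelationSummary:
    return per_gene_correlation(paired, mode=mode)[1]


# ---------------------------------------------------------------------------
# GSEA


def gsea_enrichment_score(
    scores: pd.Series, members: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov-Smirnov enrichment score of a gene set.

    ``scores`` maps gene -> ranking statistic; genes are ranked by
    decreasing score. Hits increment the running sum by
    ``|score|^weight / sum_hits |score|^weight``; misses decrement by
    ``1 / (N - N_hits)``. The ES is the running-sum value of maximal
    absolute deviation; the leading edge contains the members at or
    before the extremum (at or after, for negative ES).

    Returns ``(ES, running_sum, leading_edge_members)``.
    """
    ranked = scores.sort_values(ascending=False, kind="stable")
    genes = list(ranked.index)
    member_set = set(members) & set(genes)
    if not member_set:
        raise ValueError("gene set does not overlap the ranked list")
    if len(member_set) == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    hit = np.fromiter((g in member_set for g in genes), dtype=bool, count=len(genes))
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores are exactly 0: fall back to unweighted hits
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit) / float(len(genes) - hit.sum())
    running = np.cumsum(steps)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_max:], hit[i_max:]) if h]
    return es, running, leading


def _es_only(order_w: np.ndarray, hit: np.ndarray) -> float:
    """ES for precomputed |score|^p in rank order and a boolean hit vector."""
    hw = np.where(hit, order_w, 0.0)
    total = hw.sum()
    if total == 0:
        hw = hit.astype(float)
        total = hw.sum()
    steps = hw / total - (~hit) / float(len(hit) - hit.sum())
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    scores: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Correlation-ranked GSEA with a size-matched random-set null.

    Sets are intersected with the ranked universe and filtered to
    ``[min_size, max_size]``. For each surviving size, ``n_perm`` random
    gene sets of that size are drawn (deterministically from ``seed``);
    NOM p = (1 + #{same-sign |perm ES| >= |ES|}) / (1 + #same-sign perms)
    and NES = ES / mean |same-sign perm ES|.

    Returns a DataFrame indexed by set name with columns
    ``size, ES, NES, NOM_p, leading_edge``.
    """
    scores = scores.dropna()
    ranked = scores.sort_values(ascending=False, kind="stable")
    genes = list(ranked.index)
    N = len(genes)
    surviving: dict[str, list[str]] = {}
    for name, gs in sets.items():
        members = [g for g in gs.members if g in ranked.index]
        if min_size <= len(members) <= max_size and len(members) < N:
            surviving[name] = members
    if not surviving:
        raise ValueError("no gene set survives the size filter")
    rng = np.random.default_rng(seed)
    order_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    pos = {g: i for i, g in enumerate(genes)}
    null_es: dict[int, np.ndarray] = {}
    for size in sorted({len(m) for m in surviving.values()}):
        es_arr = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(N, size=size, replace=False)
            hit = np.zeros(N, dtype=bool)
            hit[idx] = True
            es_arr[b] = _es_only(order_w, hit)
        null_es[size] = es_arr
    rows = []
    for name, members in surviving.items():
        es, _, leading = gsea_enrichment_score(scores, members, weight=weight)
        null = null_es[len(members)]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        nom_p = (1 + n_extreme) / (1 + n_same)
        denom_pool = np.abs(null[same_sign]) if n_same else np.abs(null)
        mean_abs = float(denom_pool.mean()) if denom_pool.size else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        rows.append((name, len(members), es, nes, nom_p, ",".join(leading)))
    out = pd.DataFrame(
        rows, columns=["set", "size", "ES", "NES", "NOM_p", "leading_edge"]
    ).set_index("set")
    return out


def set_stat_mean(contrast: ContrastResult, members: Iterable[str]) -> tuple[float, int]:
    """Mean log2FC over the set's tested members and its direction (sign)."""
    idx = [m for m in members if m in contrast.table.index]
    if not idx:
        raise ValueError("gene set does not intersect the tested features")
    mean_lfc = float(contrast.table.loc[idx, "log2FC"].mean())
    return mean_lfc, int(np.sign(mean_lfc))
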