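"""Count normalization and differential expression/abundance calling.

Size factors follow the median-of-ratios scheme (each sample's median
ratio to a per-gene geometric-mean reference, restricted to genes with no
zero count), rescaled to unit geometric mean. Differential calls use a
two-sided Welch t-test on log2-transformed replicate values; genes gate
on the BH-adjusted p (padj < alpha and |log2FC| > lfc_min), proteins gate
on the raw p and a fold-change window (p < alpha and FC > fc_min or
FC < 1/fc_min). The gene/protein asymmetry (adjusted vs raw p) is
deliberate and preserved from the upstream analysis convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ripeomics.enrichment import bh_adjust
from ripeomics.io_formats import ExpressionMatrix

__all__ = [
    "SizeFactors",
    "ContrastResult",
    "estimate_size_factors",
    "normalize_counts",
    "test_differential_expression",
    "test_differential_abundance",
    "venn_regions",
    "write_contrast_result",
]

STATUSES = ("up", "down", "unchanged", "untestable")


@dataclass
class SizeFactors:
    factors: pd.Series  # sample_id -> s_j > 0

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


@dataclass
class ContrastResult:
    """Per-feature statistics for one stage-pair contrast (B relative to A)."""

    contrast: str  # e.g. "18DAPvs10DAP"
    stage_a: str
    stage_b: str
    table: pd.DataFrame  # feature-indexed: mean_A, mean_B, log2FC[, FC], p, padj, status

    @property
    def features(self) -> list[str]:
        return list(self.table.index)

    def called(self, direction: str | None = None) -> list[str]:
        if direction is None:
            mask = self.table["status"].isin(("up", "down"))
        else:
            mask = self.table["status"] == direction
        return list(self.table.index[mask])


def estimate_size_factors(
    counts: ExpressionMatrix, pseudo_reference: bool = False
) -> SizeFactors:
    """Median-of-ratios size factors, rescaled to exact unit geometric mean.

    The reference is the per-gene geometric mean over samples; genes with
    any zero count are excluded from the reference unless
    ``pseudo_reference`` is set, in which case the geometric mean is taken
    over positive counts only (for matrices where no gene is all-positive).
    """
    if counts.kind != "counts":
        raise ValueError(f"expected a counts matrix, got kind={counts.kind!r}")
    X = counts.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logX = np.log(X)
    if pseudo_reference:
        usable = (X > 0).any(axis=1)
        if not usable.any():
            raise ValueError("no gene with a positive count in any sample")
        masked = np.where(X > 0, logX, np.nan)
        log_ref = np.nanmean(masked[usable], axis=1)
    else:
        usable = (X > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene with non-zero counts in all samples; "
                "retry with pseudo_reference=True"
            )
        log_ref = logX[usable].mean(axis=1)
    with np.errstate(invalid="ignore"):
        ratios = X[usable] / np.exp(log_ref)[:, None]
        ratios = np.where(np.isfinite(ratios) & (ratios > 0), ratios, np.nan)
    raw = np.nanmedian(ratios, axis=0)
    s = raw / np.exp(np.mean(np.log(raw)))  # enforce exact unit geometric mean
    return SizeFactors(pd.Series(s, index=counts.values.columns))


def normalize_counts(counts: ExpressionMatrix, size_factors: SizeFactors) -> ExpressionMatrix:
    missing = [s for s in counts.sample_ids if s not in size_factors.factors.index]
    if missing:
        raise ValueError(f"size factors missing for samples: {missing}")
    s = size_factors.factors.loc[counts.sample_ids]
    values = counts.values / s
    return ExpressionMatrix(values, counts.sample_meta.copy(), counts.kind)


def _welch_log2(a: np.ndarray, b: np.ndarray, method: str = "welch") -> np.ndarray:
    """Two-sided t-test p-values per row; degenerate rows get p = 1.

    ``method`` selects Welch (default) or pooled-variance ("pooled").
    """
    if method not in ("welch", "pooled"):
        raise ValueError(f"unknown test method {method!r}")
    res = stats.ttest_ind(b, a, axis=1, equal_var=(method == "pooled"))
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: nan from scipy -> 1.0 so BH input is complete
    p = np.where(np.isnan(p), 1.0, p)
    return p


def _group_matrices(
    matrix: ExpressionMatrix, stage_a: str, stage_b: str
) -> tuple[np.ndarray, np.ndarray]:
    sa = matrix.stage_samples(stage_a)
    sb = matrix.stage_samples(stage_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"each group needs >= 2 replicates (got {len(sa)} for {stage_a!r}, "
            f"{len(sb)} for {stage_b!r})"
        )
    return (
        matrix.values[sa].to_numpy(dtype=float),
        matrix.values[sb].to_numpy(dtype=float),
    )


def test_differential_expression(
    norm: ExpressionMatrix,
    groups: tuple[str, str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
    method: str = "welch",
) -> ContrastResult:
    """Call DE genes for the contrast ``groups = (stage_A, stage_B)``.

    log2FC = log2((mean_B + c0) / (mean_A + c0)); p from a two-sided Welch
    t-test on log2(value + c0) replicate values; padj by BH over all tested
    genes. Status is ``up`` iff padj < alpha and log2FC > lfc_min (strict),
    ``down`` for the mirrored thresholds.
    """
    stage_a, stage_b = groups
    A, B = _group_matrices(norm, stage_a, stage_b)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    p = _welch_log2(np.log2(A + pseudocount), np.log2(B + pseudocount), method=method)
    padj = bh_adjust(p)
    status = np.full(len(p), "unchanged", dtype=object)
    status[(padj < alpha) & (log2fc > lfc_min)] = "up"
    status[(padj < alpha) & (log2fc < -lfc_min)] = "down"
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": log2fc,
            "p": p,
            "padj": padj,
            "status": status,
        },
        index=norm.values.index,
    )
    return ContrastResult(f"{stage_b}vs{stage_a}", stage_a, stage_b, table)


def test_differential_abundance(
    prot: ExpressionMatrix,
    groups: tuple[str, str],
    alpha: float = 0.05,
    fc_min: float = 1.3,
    method: str = "welch",
) -> ContrastResult:
    """Call DE proteins for ``groups = (stage_A, stage_B)``.

    FC = mean_B / mean_A on the intensity scale; p from a two-sided Welch
    t-test on log2 intensities. Status gates on the *raw* p: ``up`` iff
    p < alpha and FC > fc_min (strict), ``down`` iff p < alpha and
    FC < 1/fc_min. padj is reported for reference but does not gate.
    """
    if prot.kind != "protein_intensity":
        raise ValueError(f"expected protein intensities, got kind={prot.kind!r}")
    stage_a, stage_b = groups
    A, B = _group_matrices(prot, stage_a, stage_b)
    if (A <= 0).any() or (B <= 0).any():
        raise ValueError("non-positive protein intensity; log2 is undefined")
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    fc = mean_b / mean_a
    p = _welch_log2(np.log2(A), np.log2(B), method=method)
    padj = bh_adjust(p)
    status = np.full(len(p), "unchanged", dtype=object)
    status[(p < alpha) & (fc > fc_min)] = "up"
    status[(p < alpha) & (fc < 1.0 / fc_min)] = "down"
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "FC": fc,
            "log2FC": np.log2(fc),
            "p": p,
            "padj": padj,
            "status": status,
        },
        index=prot.values.index,
    )
    return ContrastResult(f"{stage_b}vs{stage_a}", stage_a, stage_b, table)


def venn_regions(sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Counts of the 7 disjoint regions of a three-set Venn diagram.

    Keys are sorted tuples of the set names whose exclusive intersection
    the region represents, e.g. ``("A",)`` or ``("A", "B", "C")``.
    """
    if len(sets) != 3:
        raise ValueError("venn_regions requires exactly three named sets")
    names = list(sets)
    as_sets = {n: set(sets[n]) for n in names}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, 4):
        for combo in combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(set(), *(as_sets[n] for n in names if n not in combo))
            regions[tuple(sorted(combo))] = len(inside - outside)
    return regions


def write_contrast_result(result: ContrastResult, path: str | Path) -> None:
    cols = ["mean_A", "mean_B"]
    cols += ["FC"] if "FC" in result.table.columns else []
    cols += ["log2FC", "p", "padj", "status"]
    result.table[cols].rename_axis("feature_id").to_csv(path, sep="\t")


def read_contrast_result(path: str | Path, contrast: str | None = None) -> ContrastResult:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if contrast is None:
        contrast = Path(path).stem
    if "vs" in contrast:
        stage_b, stage_a = contrast.split("vs", 1)
    else:
        stage_b = stage_a = ""
    return ContrastResult(contrast, stage_a, stage_b, table)
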