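"""Over-representation testing and enrichment-matrix clustering.

Categories are tested with a two-tailed Fisher exact test (the
minimum-likelihood convention: the p-value sums all hypergeometric tables
with the same margins whose point probability does not exceed the
observed one). p-values are corrected by Benjamini-Hochberg; a category
is called enriched only when padj < alpha AND the odds ratio exceeds 1,
so depletion is never reported as enrichment.

For the cross-group heatmap view, per-group p-values are assembled into a
category x group matrix (p = 1 where a category went untested), filtered
to categories with p < 0.05 in at least one group, transformed to
-log10(p), z-scored per category row, and clustered by average-linkage
(UPGMA) on Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from ripeomics.io_formats import GeneSetCollection

__all__ = [
    "EnrichmentMatrix",
    "bh_adjust",
    "fisher_enrichment_test",
    "enrichment_heatmap_cluster",
]


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    padj_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted
    scale, mapped back to the original order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    """Sample odds ratio of the 2x2 table, Haldane 0.5 correction on zero cells."""
    a = float(k)
    b = float(n - k)
    c = float(K - k)
    d = float(N - K - n + k)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment_test(
    de_set: Iterable[str],
    background: Iterable[str],
    categories: GeneSetCollection,
    alpha: float = 0.05,
    namespaces: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-tailed Fisher over-representation of ``de_set`` in each category.

    Categories are intersected with the background before testing;
    categories with zero background overlap are skipped with a warning.
    BH adjustment is applied per namespace when ``namespaces`` (category
    name -> namespace label) is given, otherwise pooled over all tested
    categories.

    Returns a DataFrame indexed by category with columns
    ``k, n, K, N, odds_ratio, p, padj, enriched``.
    """
    de = set(de_set)
    bg = set(background)
    if not de:
        raise ValueError("empty DE set")
    if not de <= bg:
        raise ValueError("DE set must be a subset of the background")
    N = len(bg)
    n = len(de)
    rows = []
    for name, gs in categories.items():
        members = set(gs.members) & bg
        if not members:
            warnings.warn(f"category {name!r} has no background overlap; skipped", stacklevel=2)
            continue
        K = len(members)
        k = len(members & de)
        table = [[k, n - k], [K - k, N - K - n + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append((name, k, n, K, N, _odds_ratio(k, n, K, N), min(p, 1.0)))
    if not rows:
        raise ValueError("no category overlaps the background")
    out = pd.DataFrame(
        rows, columns=["category", "k", "n", "K", "N", "odds_ratio", "p"]
    ).set_index("category")
    if namespaces is None:
        out["padj"] = bh_adjust(out["p"])
    else:
        out["padj"] = np.nan
        ns = pd.Series({c: namespaces.get(c, "") for c in out.index})
        for label in ns.unique():
            idx = ns.index[ns == label]
            out.loc[idx, "padj"] = bh_adjust(out.loc[idx, "p"])
    out["enriched"] = (out["padj"] < alpha) & (out["odds_ratio"] > 1.0)
    return out


@dataclass
class EnrichmentMatrix:
    """Filtered category x group p-value matrix with its clustered view."""

    p_matrix: pd.DataFrame  # categories x groups, raw p (1.0 where untested)
    neg_log10: pd.DataFrame  # x = -log10(p)
    z_scores: pd.DataFrame  # per-row z-transform of x (0 where variance is 0)
    row_order: list[str]  # dendrogram leaf order (category names)
    linkage_matrix: np.ndarray | None


def enrichment_heatmap_cluster(
    tables: Mapping[str, pd.DataFrame], p_threshold: float = 0.05
) -> EnrichmentMatrix:
    """Cluster -log10(p) enrichment profiles of categories across groups.

    ``tables`` maps group label -> fisher_enrichment_test output. Only
    categories with p < ``p_threshold`` in at least one group are
    retained; a category absent from some group's table gets p = 1 there.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 groups")
    groups = list(tables)
    cats: list[str] = []
    for t in tables.values():
        for c in t.index:
            if c not in cats:
                cats.append(c)
    p = pd.DataFrame(1.0, index=pd.Index(cats, name="category"), columns=groups)
    for g, t in tables.items():
        p.loc[t.index, g] = t["p"].to_numpy()
    keep = (p < p_threshold).any(axis=1)
    p = p.loc[keep]
    if p.shape[0] == 0:
        warnings.warn("no category passes the p-value filter; empty result", stacklevel=2)
        empty = p.copy()
        return EnrichmentMatrix(empty, empty.copy(), empty.copy(), [], None)
    x = -np.log10(p)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    z = x.sub(mu, axis=0)
    nonzero = sd > 0
    z.loc[nonzero] = z.loc[nonzero].div(sd[nonzero], axis=0)
    z.loc[~nonzero] = 0.0
    if z.shape[0] > 1:
        Z = linkage(pdist(z.to_numpy(), metric="euclidean"), method="average")
        order = [z.index[i] for i in leaves_list(Z)]
    else:
        Z = None
        order = list(z.index)
    return EnrichmentMatrix(p, x, z, order, Z)
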