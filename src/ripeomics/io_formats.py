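"""Tabular I/O for expression matrices, gene lengths, ID maps and gene sets.

All on-disk formats are plain tab-separated UTF-8 text: expression
matrices carry a header row of sample IDs and a first column of feature
IDs; sample sheets have columns ``sample_id``, ``stage``, ``replicate``;
gene sets use the standard GMT layout; ID maps are two-column TSV.
Feature and sample order is always preserved, never sorted silently.

Also hosts the two matrix-level derived quantities every downstream
module consumes: FPKM (computed against within-matrix column totals) and
the expressed-gene filter (max FPKM strictly above a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_KINDS = ("counts", "fpkm", "protein_intensity")

__all__ = [
    "ExpressionMatrix",
    "GeneLengthTable",
    "IdMap",
    "GeneSet",
    "GeneSetCollection",
    "load_sample_sheet",
    "load_expression_table",
    "write_expression_table",
    "load_gene_lengths",
    "write_gene_lengths",
    "load_id_map",
    "write_id_map",
    "load_gene_sets",
    "write_gene_sets",
    "compute_fpkm",
    "filter_expressed",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Features x samples numeric table with per-sample stage/replicate metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns.
        Entries must be finite and non-negative.
    sample_meta
        DataFrame indexed by sample ID with columns ``stage`` and
        ``replicate``; must cover every column of ``values``.
    kind
        One of ``"counts"``, ``"fpkm"``, ``"protein_intensity"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.values.shape[0] == 0:
            raise ValueError("no features")
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        for col in ("stage", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
        # keep metadata aligned to the matrix column order
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stage levels")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in order of first appearance."""
        return list(dict.fromkeys(self.sample_meta["stage"]))

    def stage_samples(self, stage: str) -> list[str]:
        sel = self.sample_meta.index[self.sample_meta["stage"] == stage]
        if len(sel) == 0:
            raise KeyError(f"unknown stage {stage!r}")
        return list(sel)

    def stage_means(self, log2: bool = False, pseudocount: float = 1.0) -> pd.DataFrame:
        """Per-feature replicate means at each stage.

        With ``log2=True`` each value is transformed to ``log2(x + pseudocount)``
        before averaging (transform-then-average).
        """
        vals = self.values
        if log2:
            vals = np.log2(vals + pseudocount)
        out = {s: vals[self.stage_samples(s)].mean(axis=1) for s in self.stages}
        return pd.DataFrame(out, index=self.values.index)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.values.index]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[ids].copy(), self.sample_meta.copy(), self.kind)


@dataclass
class GeneLengthTable:
    """Feature ID -> length in base pairs (positive integers)."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        _check_unique(list(self.lengths.index), "feature")
        if len(self.lengths) and (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive gene length for {bad!r}")
        self.lengths = self.lengths.astype(np.int64)

    def require_covers(self, feature_ids: Iterable[str]) -> None:
        missing = [f for f in feature_ids if f not in self.lengths.index]
        if missing:
            raise ValueError(f"gene lengths missing for: {missing[:5]}")

    def __getitem__(self, feature_id: str) -> int:
        return int(self.lengths[feature_id])


class IdMap:
    """Bidirectional 1:1 map between gene IDs and protein IDs."""

    def __init__(self, pairs: Iterable[tuple[str, str]], policy: str | None = None):
        if policy not in (None, "first", "drop"):
            raise ValueError(f"unknown collapse policy {policy!r}")
        seen_pairs: set[tuple[str, str]] = set()
        g2p: dict[str, str] = {}
        p2g: dict[str, str] = {}
        conflicts: list[tuple[str, str]] = []
        dropped: set[str] = set()
        ordered: list[tuple[str, str]] = []
        for g, p in pairs:
            if (g, p) in seen_pairs:
                raise ValueError(f"duplicate pair ({g!r}, {p!r})")
            seen_pairs.add((g, p))
            if g in g2p or p in p2g:
                conflicts.append((g, p))
                if policy == "drop":
                    dropped.add(g)
                    dropped.add(p)
                continue
            g2p[g] = p
            p2g[p] = g
            ordered.append((g, p))
        if conflicts and policy is None:
            raise ValueError(
                "ID map is not 1:1 and no collapse policy given; offending pairs: "
                f"{conflicts[:10]}"
            )
        if policy == "drop" and dropped:
            ordered = [(g, p) for g, p in ordered if g not in dropped and p not in dropped]
            g2p = dict(ordered)
            p2g = {p: g for g, p in ordered}
        self.pairs: list[tuple[str, str]] = ordered
        self._g2p = g2p
        self._p2g = p2g

    def __len__(self) -> int:
        return len(self.pairs)

    def protein_for(self, gene_id: str) -> str:
        return self._g2p[gene_id]

    def gene_for(self, protein_id: str) -> str:
        return self._p2g[protein_id]

    def genes(self) -> list[str]:
        return [g for g, _ in self.pairs]

    def proteins(self) -> list[str]:
        return [p for _, p in self.pairs]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._g2p


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


class GeneSetCollection(Mapping[str, GeneSet]):
    """Ordered mapping of set name -> :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise ValueError(f"duplicate gene set name {gs.name!r}")
            self._sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection([self._sets[n] for n in names])


# ---------------------------------------------------------------------------
# readers / writers


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    for col in ("sample_id", "stage", "replicate"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    _check_unique(list(sheet["sample_id"]), "sample")
    return sheet.set_index("sample_id")


def load_expression_table(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    kind: str = "counts",
) -> ExpressionMatrix:
    """Load a feature x sample TSV (header = sample IDs, first column = feature IDs)."""
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = load_sample_sheet(sample_sheet)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[0] == 0:
        raise ValueError("no features")
    feature_col = raw.columns[0]
    features = list(raw[feature_col])
    _check_unique(features, "feature")
    samples = list(raw.columns[1:])
    missing = [s for s in samples if s not in sample_sheet.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    numeric = {}
    for s in samples:
        col = pd.to_numeric(raw[s], errors="coerce")
        if col.isna().any():
            i = int(col.index[col.isna()][0])
            raise ValueError(
                f"non-numeric value {raw[s].iloc[i]!r} at feature {features[i]!r}, sample {s!r}"
            )
        numeric[s] = col.to_numpy(dtype=float)
    values = pd.DataFrame(numeric, index=pd.Index(features, name=feature_col))
    return ExpressionMatrix(values, sample_sheet, kind)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("feature_id").to_csv(path, sep="\t")


def write_sample_sheet(sample_meta: pd.DataFrame, path: str | Path) -> None:
    sample_meta.rename_axis("sample_id").to_csv(path, sep="\t")


def load_gene_lengths(path: str | Path) -> GeneLengthTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError("gene length table must have exactly two columns")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="feature_id"))
    return GeneLengthTable(ser)


def write_gene_lengths(table: GeneLengthTable, path: str | Path) -> None:
    table.lengths.rename("length").rename_axis("feature_id").to_csv(path, sep="\t")


def load_id_map(
    path: str | Path, header: bool = True, policy: str | None = None
) -> IdMap:
    df = pd.read_csv(path, sep="\t", dtype=str, header=0 if header else None)
    if df.shape[1] != 2:
        raise ValueError("ID map must have exactly two columns")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return IdMap(pairs, policy=policy)


def write_id_map(id_map: IdMap, path: str | Path) -> None:
    pd.DataFrame(id_map.pairs, columns=["gene_id", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Load a GMT file (tab-separated: name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: set has zero members")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m != ""]
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has zero members")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"GMT set {name!r}: {len(members) - len(unique)} duplicate member(s) dropped",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, desc, tuple(unique)))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection.values():
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# derived quantities


def compute_fpkm(counts: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Fragments per kilobase per million, against within-matrix column totals.

    ``fpkm[i, j] = counts[i, j] * 1e9 / (length_i * N_j)`` where ``N_j`` is
    the column sum of counts. The per-sample total of mapped fragments is
    approximated by the column sum, which is standard for matrix-level FPKM
    when alignments are unavailable.
    """
    if counts.kind != "counts":
        raise ValueError(f"expected a counts matrix, got kind={counts.kind!r}")
    lengths.require_covers(counts.feature_ids)
    totals = counts.values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    L = lengths.lengths.loc[counts.feature_ids].to_numpy(dtype=float)
    fpkm = counts.values.to_numpy(dtype=float) * 1e9 / (L[:, None] * totals.to_numpy()[None, :])
    out = pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(out, counts.sample_meta.copy(), "fpkm")


def filter_expressed(
    fpkm: ExpressionMatrix, threshold: float = 0.3, min_samples: int = 1
) -> list[str]:
    """Feature IDs with FPKM strictly above ``threshold`` in >= ``min_samples`` samples.

    The default (any sample) treats a gene as expressed when its maximum
    FPKM over all samples exceeds the threshold.
    """
    if fpkm.kind != "fpkm":
        raise ValueError(f"expected an fpkm matrix, got kind={fpkm.kind!r}")
    n_above = (fpkm.values > threshold).sum(axis=1)
    keep = n_above >= min_samples
    return list(fpkm.values.index[keep])
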