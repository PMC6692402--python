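"""Core domain types and interval arithmetic.

Every coordinate in the package is 0-based, half-open (BED native):
an interval ``[start, end)`` covers ``end - start`` base pairs. GFF3
input (1-based, inclusive) is converted on read and never afterwards.

The central containers are thin dataclasses around pandas DataFrames
with fixed column schemas, so that downstream modules can use vectorised
pandas/numpy operations while the constructors enforce the invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MARKS = ("H3K4me3", "H3K9me2", "RNAPII", "H3K27ac", "other")

PEAK_COLUMNS = ["chrom", "start", "end", "intensity", "name"]
LOOP_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "id", "pet_count", "fdr",
]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss",
                "category", "is_te"]
EQTL_COLUMNS = ["pair_id", "chrom", "start", "end", "gene_id"]


class ValidationError(ValueError):
    """An input violates a declared invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValidationError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("names and lengths differ in number")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, lengths: dict) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(int(v) for v in lengths.values()))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def as_dict(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @classmethod
    def infer(cls, *interval_frames) -> "GenomeLayout":
        """Infer a layout from coordinate maxima of interval tables.

        Accepts frames with chrom/end or chrom1/end1+chrom2/end2 columns.
        """
        maxima: dict = {}
        for df in interval_frames:
            if df is None or len(df) == 0:
                continue
            if "chrom" in df.columns:
                pairs = [("chrom", "end")]
            else:
                pairs = [("chrom1", "end1"), ("chrom2", "end2")]
            for c, e in pairs:
                for chrom, end in df.groupby(c, sort=False)[e].max().items():
                    maxima[chrom] = max(maxima.get(chrom, 0), int(end))
        if not maxima:
            raise ValidationError("cannot infer a layout from empty inputs")
        names = sorted(maxima)
        return cls(tuple(names), tuple(maxima[n] for n in names))


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout | None,
                       chrom_col: str = "chrom", start_col: str = "start",
                       end_col: str = "end", what: str = "interval") -> None:
    """Check 0 <= start < end <= chrom length for every row."""
    if len(df) == 0:
        return
    if (df[start_col] < 0).any() or (df[start_col] >= df[end_col]).any():
        bad = df.index[(df[start_col] < 0) | (df[start_col] >= df[end_col])][0]
        raise ValidationError(
            f"invalid {what} at row {bad}: require 0 <= start < end")
    if layout is not None:
        for chrom, end_max in df.groupby(chrom_col, sort=False)[end_col].max().items():
            if chrom not in layout:
                raise ValidationError(f"unknown chromosome {chrom!r}")
            if end_max > layout.length(chrom):
                raise ValidationError(
                    f"{what} on {chrom} exceeds chromosome length")


def sort_key(layout: GenomeLayout | None):
    """Total order on (chrom index, start, end); lexicographic chrom if no layout."""
    if layout is None:
        return lambda s: s
    order = {c: i for i, c in enumerate(layout.chrom_names)}
    return lambda s: s.map(order) if s.dtype == object else s


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Binding-site intervals of one mark with an intensity score.

    ``df`` columns: chrom, start, end, intensity, name. Peak breadth is
    ``end - start`` and is exposed as a computed column.
    """

    mark: str
    df: pd.DataFrame
    layout: GenomeLayout | None = None

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("start", "end"):
            df[col] = df[col].astype(np.int64)
        if "name" not in df.columns:
            df["name"] = [f"{self.mark}_peak{i}" for i in range(len(df))]
        if "intensity" not in df.columns:
            df["intensity"] = 0.0
        df["intensity"] = df["intensity"].astype(float)
        validate_intervals(df, self.layout, what="peak")
        if (df["intensity"] < 0).any():
            raise ValidationError("peak intensity must be nonnegative")
        df = df[PEAK_COLUMNS]
        key = sort_key(self.layout)
        df = df.sort_values(["chrom", "start", "end"], key=key,
                            kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def breadth(self) -> pd.Series:
        return self.df["end"] - self.df["start"]

    def tree(self) -> dict:
        return build_trees(self.df)


@dataclass
class LoopSet:
    """Anchor-anchor chromatin interactions of one mark.

    Intrachromosomal loops are stored with anchor_a preceding anchor_b in
    genome order. ``pet_count`` is the PET (paired-end tag) support and
    ``fdr`` the caller's false-discovery rate for the cluster.
    """

    mark: str
    df: pd.DataFrame
    layout: GenomeLayout | None = None

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("start1", "end1", "start2", "end2"):
            df[col] = df[col].astype(np.int64)
        if "id" not in df.columns:
            df["id"] = [f"{self.mark}_loop{i}" for i in range(len(df))]
        if "pet_count" not in df.columns:
            df["pet_count"] = 1
        if "fdr" not in df.columns:
            df["fdr"] = 0.0
        df["pet_count"] = df["pet_count"].astype(np.int64)
        df["fdr"] = df["fdr"].astype(float)
        if (df["pet_count"] < 1).any():
            raise ValidationError("pet_count must be >= 1")
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
            raise ValidationError("fdr must lie in [0, 1]")
        validate_intervals(df, self.layout, "chrom1", "start1", "end1", "anchor")
        validate_intervals(df, self.layout, "chrom2", "start2", "end2", "anchor")
        # canonical anchor order for intrachromosomal loops
        intra = df["chrom1"] == df["chrom2"]
        flip = intra & ((df["start1"] > df["start2"]) |
                        ((df["start1"] == df["start2"]) & (df["end1"] > df["end2"])))
        if flip.any():
            a = df.loc[flip, ["chrom1", "start1", "end1"]].to_numpy()
            df.loc[flip, ["chrom1", "start1", "end1"]] = \
                df.loc[flip, ["chrom2", "start2", "end2"]].to_numpy()
            df.loc[flip, ["chrom2", "start2", "end2"]] = a
            for col in ("start1", "end1", "start2", "end2"):
                df[col] = df[col].astype(np.int64)
        extra = [c for c in df.columns if c not in LOOP_COLUMNS]
        df = df[LOOP_COLUMNS + extra]
        key = sort_key(self.layout)
        df = df.sort_values(["chrom1", "start1", "chrom2", "start2"], key=key,
                            kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def is_intra(self) -> pd.Series:
        return self.df["chrom1"] == self.df["chrom2"]

    def intra(self) -> "LoopSet":
        return LoopSet(self.mark, self.df[self.is_intra], self.layout)

    @property
    def span(self) -> pd.Series:
        """Full genomic span end2 - start1 of intrachromosomal loops (NaN inter)."""
        s = (self.df["end2"] - self.df["start1"]).astype(float)
        s[~self.is_intra] = np.nan
        return s


@dataclass
class GeneTable:
    """Gene models with strand-aware TSS and pan-genome category.

    TSS = start on the + strand, end - 1 on the - strand. ``category`` is
    the pan-genome class (core / distributed / unknown).
    """

    df: pd.DataFrame
    layout: GenomeLayout | None = None

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("start", "end"):
            df[col] = df[col].astype(np.int64)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        if "category" not in df.columns:
            df["category"] = "unknown"
        if "is_te" not in df.columns:
            df["is_te"] = False
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        validate_intervals(df, self.layout, what="gene")
        df = df[GENE_COLUMNS]
        key = sort_key(self.layout)
        df = df.sort_values(["chrom", "start", "end"], key=key,
                            kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self):
        return len(self.df)

    def promoters(self, window: int, layout: GenomeLayout | None = None) -> pd.DataFrame:
        """Promoter intervals [tss - window, tss + window) clipped to the chromosome."""
        layout = layout or self.layout
        p = self.df[["gene_id", "chrom", "tss"]].copy()
        p["start"] = (p["tss"] - window).clip(lower=0)
        p["end"] = p["tss"] + window
        if window == 0:
            p["end"] = p["tss"] + 1
        if layout is not None:
            lengths = p["chrom"].map(layout.as_dict())
            p["end"] = np.minimum(p["end"], lengths)
        return p[["gene_id", "chrom", "start", "end"]]


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM values; NaN marks missing cells."""

    df: pd.DataFrame  # index: gene ids, columns: tissue ids

    def __post_init__(self):
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if (self.df.to_numpy(dtype=float) < 0).any():
            raise ValidationError("FPKM values must be nonnegative")
        self.df = self.df.astype(float)

    @property
    def gene_ids(self):
        return list(self.df.index)

    @property
    def tissue_ids(self):
        return list(self.df.columns)

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------

def build_trees(df: pd.DataFrame, chrom_col: str = "chrom",
                start_col: str = "start", end_col: str = "end") -> dict:
    """Per-chromosome IntervalTree of row indices for >=1 bp overlap queries."""
    trees: dict = {}
    for chrom, sub in df.groupby(chrom_col, sort=False):
        t = IntervalTree()
        for idx, s, e in zip(sub.index, sub[start_col], sub[end_col]):
            t[int(s):int(e)] = idx
        trees[chrom] = t
    return trees


def overlapping(trees: dict, chrom: str, start: int, end: int) -> list:
    """Row indices of intervals overlapping [start, end) by >= 1 bp."""
    t = trees.get(chrom)
    if t is None:
        return []
    return [iv.data for iv in t.overlap(int(start), int(end))]


def merge_intervals(intervals) -> list:
    """Merge intervals overlapping by >= 1 bp (half-open: touching stays split).

    ``intervals``: iterable of (start, end). Returns sorted disjoint list.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list = []
    for s, e in ivs:
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_lists(a: list, b: list) -> list:
    """Intersection of two sorted disjoint interval lists."""
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_lists(a: list, b: list) -> list:
    """a minus b, both sorted disjoint interval lists."""
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def union_lists(a: list, b: list) -> list:
    return merge_intervals(list(a) + list(b))


def complement_list(a: list, length: int) -> list:
    """Complement of a sorted disjoint list within [0, length)."""
    out, cur = [], 0
    for s, e in a:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def total_bp(a: list) -> int:
    return int(sum(e - s for s, e in a))


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
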