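"""Readers and writers for the genomic text formats the pipeline touches.

All outputs are tab-separated with LF line endings; BED/BEDPE carry no
header, TSV tables carry a single header row. BED/BEDPE coordinates are
written as stored (0-based half-open); GFF3 is converted to and from its
native 1-based inclusive convention at the boundary.

BEDPE dialect: columns 1-6 are the two anchors, column 7 the loop id,
column 8 the PET count, column 9 the FDR; further columns are preserved
untouched as opaque annotations.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (EQTL_COLUMNS, GeneTable, GenomeLayout, ExpressionMatrix,
                   LoopSet, ParseError, PeakSet, ValidationError)


def _numeric(value: str, line_no: int, path, kind=float):
    try:
        return kind(value)
    except ValueError:
        raise ParseError(f"{path}:{line_no}: cannot parse {value!r}") from None


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeLayout:
    """Two-column ``chrom<TAB>length`` file -> GenomeLayout."""
    names, lengths = [], []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{i}: expected 2 columns")
        names.append(parts[0])
        lengths.append(int(_numeric(parts[1], i, path, int)))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    lines = [f"{c}\t{l}" for c, l in zip(layout.chrom_names, layout.chrom_lengths)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# peaks (BED)
# ---------------------------------------------------------------------------

def read_peaks(path, mark: str, layout: GenomeLayout | None = None) -> PeakSet:
    """BED file (>= 3 columns; column 4 = score, defaults to 0) -> PeakSet."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{i}: expected >= 3 columns")
        chrom = parts[0]
        start = int(_numeric(parts[1], i, path, int))
        end = int(_numeric(parts[2], i, path, int))
        if start >= end or start < 0:
            raise ValidationError(f"{path}:{i}: require 0 <= start < end")
        score = _numeric(parts[3], i, path) if len(parts) >= 4 and parts[3] != "." else 0.0
        name = parts[4] if len(parts) >= 5 else f"{mark}_peak{len(rows)}"
        rows.append((chrom, start, end, score, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity", "name"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "intensity", "name"])
    return PeakSet(mark, df, layout)


def write_peaks(peaks: PeakSet, path) -> None:
    """BED: chrom, start, end, intensity, name (name carries any label)."""
    with open(path, "w", newline="\n") as fh:
        for row in peaks.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{row.intensity:g}\t{row.name}\n")


# ---------------------------------------------------------------------------
# loops (BEDPE)
# ---------------------------------------------------------------------------

def read_loops(path, mark: str, layout: GenomeLayout | None = None) -> LoopSet:
    """BEDPE (6 mandatory columns; 7-9 = id, pet_count, fdr) -> LoopSet."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ParseError(f"{path}:{i}: expected >= 6 columns")
        c1, s1, e1, c2, s2, e2 = parts[:6]
        s1, e1 = int(_numeric(s1, i, path, int)), int(_numeric(e1, i, path, int))
        s2, e2 = int(_numeric(s2, i, path, int)), int(_numeric(e2, i, path, int))
        if s1 >= e1 or s2 >= e2 or s1 < 0 or s2 < 0:
            raise ValidationError(f"{path}:{i}: require 0 <= start < end")
        loop_id = parts[6] if len(parts) >= 7 else f"{mark}_loop{len(rows)}"
        pets = int(_numeric(parts[7], i, path, int)) if len(parts) >= 8 else 1
        if pets < 1:
            raise ValidationError(f"{path}:{i}: pet_count must be >= 1")
        fdr = _numeric(parts[8], i, path) if len(parts) >= 9 else 0.0
        rows.append((c1, s1, e1, c2, s2, e2, loop_id, pets, fdr))
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                     "chrom2", "start2", "end2",
                                     "id", "pet_count", "fdr"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom1", "start1", "end1",
                                   "chrom2", "start2", "end2",
                                   "id", "pet_count", "fdr"])
    return LoopSet(mark, df, layout)


def write_loops(loops: LoopSet, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for row in loops.df.itertuples(index=False):
            fh.write(f"{row.chrom1}\t{row.start1}\t{row.end1}\t"
                     f"{row.chrom2}\t{row.start2}\t{row.end2}\t"
                     f"{row.id}\t{row.pet_count}\t{row.fdr:g}\n")


# ---------------------------------------------------------------------------
# expression (TSV)
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """TSV: header = tissue ids, first column = gene id, cells numeric FPKM.

    ``NA`` / empty cells are treated as missing and excluded pairwise from
    correlations downstream. Ragged rows and duplicate gene ids are errors.
    """
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        tissues = header[1:]
        genes, values = [], []
        for i, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(f"{path}:{i}: ragged row "
                                 f"({len(row)} != {len(header)} columns)")
            genes.append(row[0])
            vals = []
            for cell in row[1:]:
                if cell in ("NA", "", "NaN", "nan"):
                    vals.append(np.nan)
                else:
                    vals.append(_numeric(cell, i, path))
            values.append(vals)
    df = pd.DataFrame(values, index=genes, columns=tissues, dtype=float)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# genes (GFF3 / BED12)
# ---------------------------------------------------------------------------

def _parse_gff_attributes(attrs: str) -> dict:
    out = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes(path, layout: GenomeLayout | None = None) -> GeneTable:
    """Gene records from GFF3 (``gene`` features) or BED12.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. The optional GFF3 attributes ``category`` (core /
    distributed) and ``is_te`` are picked up when present.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    first_data = next((l for l in text if l.strip() and not l.startswith("#")), "")
    n_cols = len(first_data.split("\t"))
    rows = []
    if n_cols >= 12 and not _looks_like_gff(first_data):
        for i, line in enumerate(text, 1):
            if not line.strip() or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(f"{path}:{i}: expected 12 BED columns")
            if p[5] not in ("+", "-"):
                raise ValidationError(f"{path}:{i}: missing strand")
            rows.append((p[3], p[0], int(p[1]), int(p[2]), p[5],
                         "unknown", False))
    else:
        for i, line in enumerate(text, 1):
            if not line.strip() or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 9:
                raise ParseError(f"{path}:{i}: expected 9 GFF3 columns")
            if p[2] != "gene":
                continue
            if p[6] not in ("+", "-"):
                raise ValidationError(f"{path}:{i}: missing strand")
            attrs = _parse_gff_attributes(p[8])
            gid = attrs.get("ID") or attrs.get("gene_id")
            if not gid:
                raise ParseError(f"{path}:{i}: gene feature without ID attribute")
            start = int(p[3]) - 1  # GFF3 1-based inclusive -> 0-based half-open
            end = int(p[4])
            rows.append((gid, p[0], start, end, p[6],
                         attrs.get("category", "unknown"),
                         attrs.get("is_te", "false").lower() == "true"))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "category", "is_te"])
    if df.empty:
        df = pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                   "strand", "category", "is_te"])
    return GeneTable(df, layout)


def _looks_like_gff(line: str) -> bool:
    p = line.split("\t")
    return len(p) >= 9 and p[2] and not p[1].isdigit()


def write_genes(genes: GeneTable, path) -> None:
    """Write the gene-only GFF3 dialect this package reads back."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.df.itertuples(index=False):
            attrs = (f"ID={row.gene_id};category={row.category};"
                     f"is_te={'true' if row.is_te else 'false'}")
            fh.write(f"{row.chrom}\tchialoop\tgene\t{row.start + 1}\t{row.end}"
                     f"\t.\t{row.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# variants and eQTL pairs (TSV)
# ---------------------------------------------------------------------------

def read_variants(path, var_class: str) -> pd.DataFrame:
    """BED-like TSV -> DataFrame(chrom, start, end, id, var_class)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "id"],
                     usecols=[0, 1, 2, 3] if _has_four_cols(path) else [0, 1, 2])
    if "id" not in df.columns or df["id"].isna().any():
        df["id"] = [f"{var_class}_{i}" for i in range(len(df))]
    df["class"] = var_class
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValidationError(f"{path}: invalid variant interval")
    return df[["chrom", "start", "end", "id", "class"]]


def _has_four_cols(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.split("\t")) >= 4
    return False


def read_eqtl_pairs(path) -> pd.DataFrame:
    """TSV with header: pair_id, chrom, start, end, gene_id[, extra...]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValidationError(f"{path}: invalid eQTL interval")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Single-header TSV, LF endings, no index."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    """3- or 4-column BED from a chrom/start/end[/name] frame."""
    with open(path, "w", newline="\n") as fh:
        for row in intervals.itertuples(index=False):
            line = f"{row.chrom}\t{row.start}\t{row.end}"
            if name_col:
                line += f"\t{getattr(row, name_col)}"
            fh.write(line + "\n")
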