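"""Anchor vs basal peak classification and promoter chromatin models.

A binding site that overlaps (>= 1 bp) a loop anchor of its mark is an
*anchor* peak — it participates in chromatin interactions. The remaining
peaks are *basal*. Genes are then assigned to the promoter–promoter
interaction (PPI) model when their promoter overlaps an anchor peak, to
the basal-promoter (BP) model when it overlaps only basal peaks, and are
otherwise unmarked. Anchor overlap takes precedence over basal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (ExpressionMatrix, GeneTable, LoopSet, PeakSet,
                   build_trees, overlapping, warn)


@dataclass
class AnchorAssignment:
    """Per-peak anchor/basal labels with the loop ids each peak anchors."""

    mark: str
    df: pd.DataFrame  # peak columns + label + loop_ids (comma-joined)

    @property
    def anchor_fraction(self) -> float:
        if len(self.df) == 0:
            return float("nan")
        return float((self.df["label"] == "anchor").mean())

    @property
    def n_anchor(self) -> int:
        return int((self.df["label"] == "anchor").sum())


def classify_peaks(peaks: PeakSet, loops: LoopSet) -> AnchorAssignment:
    """Label each peak anchor/basal by >= 1 bp overlap with any loop anchor."""
    if peaks.mark != loops.mark:
        warn(f"classifying {peaks.mark} peaks against {loops.mark} loops")
    df = peaks.df.copy()
    if len(df) == 0:
        df["label"] = pd.Series(dtype=object)
        df["loop_ids"] = pd.Series(dtype=object)
        return AnchorAssignment(peaks.mark, df)
    trees = build_trees(df)
    peak_chroms = set(df["chrom"])
    loop_ids: list = [[] for _ in range(len(df))]
    missing = set()
    for row in loops.df.itertuples(index=False):
        for chrom, start, end in ((row.chrom1, row.start1, row.end1),
                                  (row.chrom2, row.start2, row.end2)):
            if chrom not in peak_chroms:
                missing.add(chrom)
                continue
            for idx in overlapping(trees, chrom, start, end):
                loop_ids[idx].append(row.id)
    if missing:
        warn(f"loops on chromosomes absent from peaks ignored: {sorted(missing)}")
    df["loop_ids"] = [",".join(sorted(set(ids))) for ids in loop_ids]
    df["label"] = np.where(df["loop_ids"] != "", "anchor", "basal")
    return AnchorAssignment(peaks.mark, df)


def assign_gene_models(genes: GeneTable, peaks: PeakSet,
                       assignment: AnchorAssignment,
                       promoter_window: int = 2000) -> pd.DataFrame:
    """Assign each gene to PPI / BP / unmarked by promoter-peak overlap.

    The promoter is ``[tss - w, tss + w)`` clipped to the chromosome.
    Returns a frame with gene_id, model, mark, promoter coordinates.
    """
    if promoter_window < 0:
        raise ValueError("promoter_window must be >= 0")
    prom = genes.promoters(promoter_window)
    labelled = assignment.df
    trees = build_trees(labelled)
    models = []
    for row in prom.itertuples(index=False):
        hits = overlapping(trees, row.chrom, row.start, row.end)
        labels = set(labelled["label"].iloc[hits]) if hits else set()
        if "anchor" in labels:
            model = "PPI"
        elif "basal" in labels:
            model = "BP"
        else:
            model = "unmarked"
        models.append(model)
    out = prom.copy()
    out["model"] = models
    out["mark"] = assignment.mark
    return out[["gene_id", "model", "mark", "chrom", "start", "end"]]


def expression_breadth(expr: ExpressionMatrix, threshold: float = 1.0) -> pd.Series:
    """Number of tissues in which each gene has FPKM >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (expr.df >= threshold).sum(axis=1).astype(int)


def core_distributed_composition(labels: pd.DataFrame,
                                 genes: GeneTable) -> pd.DataFrame:
    """Per-model fractions of core / distributed / unknown pan-genome genes.

    Models with zero genes are reported as NaN rows (undefined), not zeros.
    """
    cat = genes.df.set_index("gene_id")["category"]
    merged = labels[["gene_id", "model"]].copy()
    merged["category"] = merged["gene_id"].map(cat).fillna("unknown")
    out = []
    for model in ("PPI", "BP", "unmarked"):
        sub = merged[merged["model"] == model]
        n = len(sub)
        if n == 0:
            out.append((model, 0, np.nan, np.nan, np.nan))
        else:
            counts = sub["category"].value_counts()
            out.append((model, n,
                        counts.get("core", 0) / n,
                        counts.get("distributed", 0) / n,
                        counts.get("unknown", 0) / n))
    return pd.DataFrame(out, columns=["model", "n_genes", "core",
                                      "distributed", "unknown"])
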