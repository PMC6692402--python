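"""Chromatin interaction domain (CID) calling and genome module partition.

A CID is a genomic region spanned by continuous, connected loops of one
mark. Calling proceeds in four steps: (1) group intrachromosomal loops
into connected components (two loops are connected when any anchor of one
overlaps any anchor of the other by >= 1 bp); (2) take each component's
span as a candidate domain; (3) compute base-pair loop coverage — the
number of loops whose full span covers the position — and keep maximal
runs at or above a coverage threshold; (4) filter runs by genomic span.

The genome then partitions into modules: MID = H3K9me2 ∩ H3K4me3 domains,
HID = H3K9me2-only, AID = H3K4me3-only, TID = RNAPII-only, and GAP for
the remainder. The module labels tile each chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (GenomeLayout, LoopSet, complement_list, intersect_lists,
                   merge_intervals, subtract_lists, total_bp, union_lists)

MODULE_LABELS = ("HID", "AID", "MID", "TID", "GAP")


@dataclass
class DomainSet:
    """Non-overlapping domains of one mark with the parameters that made them."""

    mark: str
    df: pd.DataFrame  # chrom, start, end
    params: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.df)

    def by_chrom(self) -> dict:
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = list(zip(sub["start"], sub["end"]))
        return {c: sorted(v) for c, v in out.items()}


@dataclass
class ModulePartition:
    """Exact tiling of the genome into HID/AID/MID/TID/GAP intervals."""

    df: pd.DataFrame          # chrom, start, end, label
    summary: pd.DataFrame     # label, bp, fraction
    hid_aid_relations: pd.DataFrame


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def loop_components(loops: LoopSet) -> tuple[list, int]:
    """Connected groups of intrachromosomal loops under anchor overlap.

    Returns ``(groups, n_inter_filtered)`` where each group is a list of
    loop ids; interchromosomal loops are excluded and counted. Loops are
    connected when any anchor of one overlaps any anchor of the other;
    groups are the transitive closure. A linear sweep over sorted anchors
    unions chains of pairwise-overlapping anchors, which is exactly the
    transitive closure of the overlap relation.
    """
    df = loops.df
    intra = df["chrom1"] == df["chrom2"]
    n_inter = int((~intra).sum())
    df = df[intra].reset_index(drop=True)
    n = len(df)
    if n == 0:
        return [], n_inter
    uf = _UnionFind(n)
    anchors = []
    for i, row in enumerate(df.itertuples(index=False)):
        anchors.append((row.chrom1, row.start1, row.end1, i))
        anchors.append((row.chrom2, row.start2, row.end2, i))
    anchors.sort()
    prev_chrom, run_end, run_rep = None, -1, -1
    for chrom, start, end, i in anchors:
        if chrom == prev_chrom and start < run_end:
            uf.union(run_rep, i)
            run_end = max(run_end, end)
        else:
            prev_chrom, run_end, run_rep = chrom, end, i
    groups: dict = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(df["id"].iloc[i])
    return list(groups.values()), n_inter


# ---------------------------------------------------------------------------
# CID calling
# ---------------------------------------------------------------------------

def call_cids(loops: LoopSet, layout: GenomeLayout,
              coverage_threshold: int = 2,
              min_span: int = 10_000, max_span: int = 1_000_000,
              min_pet_count: int = 1) -> DomainSet:
    """Call coverage-supported interaction domains for one mark.

    Loop coverage at a base pair is the number of loops whose full span
    ``[anchor_a.start, anchor_b.end)`` covers it. Within each connected
    component's candidate span, maximal runs with coverage >= threshold
    and span within ``[min_span, max_span]`` become domains.
    """
    if coverage_threshold < 1:
        raise ValueError("coverage_threshold must be >= 1")
    if min_span >= max_span:
        raise ValueError("require min_span < max_span")
    df = loops.df
    keep = (df["chrom1"] == df["chrom2"]) & (df["pet_count"] >= min_pet_count)
    df = df[keep].reset_index(drop=True)
    sub = LoopSet(loops.mark, df, layout) if len(df) else None
    params = dict(coverage_threshold=coverage_threshold, min_span=min_span,
                  max_span=max_span, min_pet_count=min_pet_count)
    if sub is None:
        return DomainSet(loops.mark, pd.DataFrame(
            columns=["chrom", "start", "end"]), params)
    groups, _ = loop_components(sub)
    by_id = sub.df.set_index("id")
    domains = []
    for group in groups:
        rows = by_id.loc[group]
        chrom = rows["chrom1"].iloc[0]
        cand_start = int(rows["start1"].min())
        cand_end = int(rows["end2"].max())
        # local coverage profile over the candidate span
        cov = np.zeros(cand_end - cand_start + 1, dtype=np.int32)
        starts = rows["start1"].to_numpy() - cand_start
        ends = rows["end2"].to_numpy() - cand_start
        np.add.at(cov, starts, 1)
        np.add.at(cov, ends, -1)
        cov = np.cumsum(cov[:-1])
        above = cov >= coverage_threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for run_s, run_e in zip(edges[::2], edges[1::2]):
            span = int(run_e - run_s)
            if min_span <= span <= max_span:
                domains.append((chrom, cand_start + int(run_s),
                                cand_start + int(run_e)))
    out = pd.DataFrame(domains, columns=["chrom", "start", "end"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return DomainSet(loops.mark, out, params)


def merge_related_segments(domains: DomainSet, gap_tolerance: int = 20_000) -> DomainSet:
    """Merge domains separated by gaps <= tolerance into related segments."""
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    segments = []
    for chrom, ivs in domains.by_chrom().items():
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e <= gap_tolerance:
                cur_e = max(cur_e, e)
            else:
                segments.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        segments.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(segments, columns=["chrom", "start", "end"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    params = dict(domains.params, gap_tolerance=gap_tolerance, related=True)
    return DomainSet(domains.mark, out, params)


# ---------------------------------------------------------------------------
# genome partition
# ---------------------------------------------------------------------------

def _relations(a_list: list, b_list: list) -> dict:
    """Fig-style intersection categories of A segments against B segments."""
    counts = dict(isolated=0, partial_overlap=0, a_in_b=0, b_in_a=0)
    for s, e in a_list:
        hits = [(bs, be) for bs, be in b_list if bs < e and s < be]
        if not hits:
            counts["isolated"] += 1
        elif any(bs <= s and e <= be for bs, be in hits):
            counts["a_in_b"] += 1
        elif any(s <= bs and be <= e for bs, be in hits):
            counts["b_in_a"] += 1
        else:
            counts["partial_overlap"] += 1
    return counts


def partition_modules(k9: DomainSet, k4: DomainSet, pii: DomainSet,
                      layout: GenomeLayout) -> ModulePartition:
    """Partition the genome into HID/AID/MID/TID/GAP modules.

    MID = K9 ∩ K4; HID = K9 − K4; AID = K4 − K9; TID = PII − (K9 ∪ K4);
    GAP = genome − (K9 ∪ K4 ∪ PII). The output intervals tile every
    chromosome exactly (integer bp, no overlaps, no gaps).
    """
    k9_by, k4_by, pii_by = k9.by_chrom(), k4.by_chrom(), pii.by_chrom()
    tiles = []
    rel = dict(isolated=0, partial_overlap=0, a_in_b=0, b_in_a=0)
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        a = merge_intervals(k9_by.get(chrom, []))
        b = merge_intervals(k4_by.get(chrom, []))
        p = merge_intervals(pii_by.get(chrom, []))
        mid = intersect_lists(a, b)
        hid = subtract_lists(a, b)
        aid = subtract_lists(b, a)
        ab = union_lists(a, b)
        tid = subtract_lists(p, ab)
        gap = complement_list(union_lists(ab, p), length)
        for label, ivs in (("HID", hid), ("AID", aid), ("MID", mid),
                           ("TID", tid), ("GAP", gap)):
            tiles.extend((chrom, s, e, label) for s, e in ivs)
        for k, v in _relations(b, a).items():  # AID-related vs HID-related
            rel[k] += v
    df = pd.DataFrame(tiles, columns=["chrom", "start", "end", "label"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    bp = df.assign(bp=df["end"] - df["start"]).groupby("label")["bp"].sum()
    summary = pd.DataFrame({
        "label": MODULE_LABELS,
        "bp": [int(bp.get(l, 0)) for l in MODULE_LABELS],
    })
    summary["fraction"] = summary["bp"] / layout.total_bp
    relations = pd.DataFrame(
        [("isolated", rel["isolated"]),
         ("partial_overlap", rel["partial_overlap"]),
         ("AID_within_HID", rel["a_in_b"]),
         ("HID_within_AID", rel["b_in_a"])],
        columns=["relation", "count"])
    return ModulePartition(df, summary, relations)
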