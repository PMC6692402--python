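"""Cross-variety comparison: differential peaks and loop gain/loss.

Peak sets from two varieties mapped to one reference are merged (>= 1 bp
overlap chains collapse), per-interval read counts are tested for
differential occupancy under a negative-binomial model with
method-of-moments common dispersion (exact conditional binomial when the
dispersion is zero), and differential peaks are attributed to overlapping
genetic-variant classes. Variety-specific loops are detected by anchor
matching and classified as PAV-associated or mark-conversion events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import LoopSet, PeakSet, build_trees, merge_intervals, overlapping

VARIANT_PRIORITY = ("PAV", "InDel", "SNP", "inversion", "translocation")


def merge_peak_sets(peaks1: PeakSet, peaks2: PeakSet) -> pd.DataFrame:
    """Merge two varieties' peaks; >= 1 bp overlap chains collapse.

    Returns chrom, start, end plus comma-joined contributing peak names
    per variety (provenance). Half-open touching intervals stay separate.
    """
    both = pd.concat([
        peaks1.df.assign(variety=1),
        peaks2.df.assign(variety=2),
    ], ignore_index=True)
    rows = []
    for chrom, sub in both.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start < cur[1]:
                cur[1] = max(cur[1], r.end)
                cur[1 + r.variety].append(r.name)
            else:
                if cur is not None:
                    rows.append((chrom, *cur[:2],
                                 ",".join(cur[2]), ",".join(cur[3])))
                cur = [r.start, r.end, [], []]
                cur[1 + r.variety].append(r.name)
        if cur is not None:
            rows.append((chrom, *cur[:2], ",".join(cur[2]), ",".join(cur[3])))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                      "peaks_variety1", "peaks_variety2"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (columns = samples)."""
    logs = np.log(counts.astype(float))
    logs[~np.isfinite(logs)] = np.nan
    ref = np.nanmean(logs, axis=1)
    ok = np.isfinite(ref)
    if not ok.any():
        return np.ones(counts.shape[1])
    sf = np.exp(np.nanmedian(logs[ok] - ref[ok, None], axis=0))
    sf[~np.isfinite(sf) | (sf == 0)] = 1.0
    return sf


def _common_dispersion(norm1: np.ndarray, norm2: np.ndarray) -> float:
    """Method-of-moments common NB dispersion from equal-mean pairs.

    Under H0 both normalized counts share mean mu, so
    E[(k1-k2)^2] = 2*mu + 2*alpha*mu^2; solving across intervals gives a
    pooled alpha, floored at zero.
    """
    mu = (norm1 + norm2) / 2
    keep = mu > 0
    if keep.sum() < 2:
        return 0.0
    num = np.mean((norm1[keep] - norm2[keep]) ** 2 - 2 * mu[keep])
    den = np.mean(2 * mu[keep] ** 2)
    if den <= 0:
        return 0.0
    return float(max(0.0, num / den))


def call_differential_peaks(merged: pd.DataFrame, counts: pd.DataFrame,
                            alpha: float = 0.05, lfc_min: float = 1.0,
                            dispersion: float | None = None,
                            size_factors=None) -> pd.DataFrame:
    """Differential occupancy between two varieties on merged intervals.

    ``counts`` columns starting with ``v1`` belong to variety 1 and
    ``v2`` to variety 2 (one or more replicates each). Size factors are
    median-of-ratios; the per-interval two-sided test uses the exact
    conditional binomial when the pooled dispersion is zero and a Wald
    z-test on the log ratio of normalized means otherwise. Benjamini-
    Hochberg adjusted p-values and the |log2FC| > ``lfc_min`` rule set
    status up/down/stable; log2FC uses normalized means + pseudocount 1.
    """
    c1_cols = [c for c in counts.columns if c.startswith("v1")]
    c2_cols = [c for c in counts.columns if c.startswith("v2")]
    if not c1_cols or not c2_cols:
        raise ValueError("counts needs v1* and v2* columns")
    raw = counts[c1_cols + c2_cols].to_numpy()
    if (raw < 0).any():
        raise ValueError("counts must be nonnegative")
    sf = _size_factors(raw) if size_factors is None \
        else np.asarray(size_factors, dtype=float)
    norm = raw / sf
    norm1 = norm[:, :len(c1_cols)].mean(axis=1)
    norm2 = norm[:, len(c1_cols):].mean(axis=1)
    disp = _common_dispersion(norm1, norm2) if dispersion is None else float(dispersion)
    k1 = counts[c1_cols].sum(axis=1).to_numpy()
    k2 = counts[c2_cols].sum(axis=1).to_numpy()
    s1 = sf[:len(c1_cols)].sum()
    s2 = sf[len(c1_cols):].sum()
    pvals = np.ones(len(merged))
    for i in range(len(merged)):
        n = int(k1[i] + k2[i])
        if n == 0:
            pvals[i] = 1.0
            continue
        if disp == 0:
            p0 = s1 / (s1 + s2)
            pvals[i] = stats.binomtest(int(k1[i]), n, p0).pvalue
        else:
            m1, m2 = norm1[i] + 0.5, norm2[i] + 0.5
            var = 1.0 / m1 + 1.0 / m2 + 2 * disp
            z = np.log(m1 / m2) / np.sqrt(var)
            pvals[i] = 2 * stats.norm.sf(abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1]
    log2fc = np.log2((norm1 + 1) / (norm2 + 1))
    status = np.where(
        (padj < alpha) & (log2fc > lfc_min), "up",
        np.where((padj < alpha) & (log2fc < -lfc_min), "down", "stable"))
    out = merged[["chrom", "start", "end"]].copy()
    out["count_v1"] = k1
    out["count_v2"] = k2
    out["log2_fold_change"] = log2fc
    out["p_value"] = pvals
    out["adjusted_p"] = padj
    out["status"] = status
    out.attrs["dispersion"] = disp
    out.attrs["size_factors"] = sf.tolist()
    return out


def attribute_variants(diff: pd.DataFrame, variant_sets: list) -> pd.DataFrame:
    """Annotate differential peaks with overlapping variant classes.

    The primary class is the one with the largest overlapped bp; ties
    break by the fixed order PAV > InDel > SNP > inversion > translocation.
    Peaks overlapping nothing get class ``none``. Also attaches summary
    proportions over status != stable peaks as ``.attrs['summary']``.
    """
    variants = pd.concat(variant_sets, ignore_index=True) if variant_sets \
        else pd.DataFrame(columns=["chrom", "start", "end", "id", "class"])
    trees = build_trees(variants)
    prio = {c: i for i, c in enumerate(VARIANT_PRIORITY)}
    all_classes, primaries = [], []
    for row in diff.itertuples(index=False):
        hits = overlapping(trees, row.chrom, row.start, row.end)
        bp_by_class: dict = {}
        for i in hits:
            v = variants.iloc[i]
            bp = min(row.end, v["end"]) - max(row.start, v["start"])
            bp_by_class[v["class"]] = bp_by_class.get(v["class"], 0) + bp
        if not bp_by_class:
            all_classes.append("none")
            primaries.append("none")
        else:
            all_classes.append(",".join(sorted(bp_by_class)))
            primaries.append(min(bp_by_class,
                                 key=lambda c: (-bp_by_class[c], prio.get(c, 99))))
    out = diff.copy()
    out["variant_classes"] = all_classes
    out["primary_class"] = primaries
    differential = out[out["status"] != "stable"]
    if len(differential):
        summary = (differential["primary_class"].value_counts(normalize=True)
                   .rename_axis("class").reset_index(name="proportion"))
    else:
        summary = pd.DataFrame(columns=["class", "proportion"])
    out.attrs["summary"] = summary
    return out


def variety_specific_loops(loops1: LoopSet, loops2: LoopSet,
                           pavs: pd.DataFrame,
                           opposing_peaks2: PeakSet,
                           anchor_slop: int = 2000) -> pd.DataFrame:
    """Loops of variety 1 absent from variety 2, with a candidate cause.

    A loop is present in the other set when some loop there has both
    anchors overlapping the query anchors extended by ``anchor_slop``.
    Absent loops are PAV_associated when an anchor overlaps a PAV,
    mark_conversion when an anchor overlaps an opposing-mark peak of the
    other variety (PAV takes precedence), else unexplained.
    """
    t2a = build_trees(loops2.df, "chrom1", "start1", "end1")
    t2b = build_trees(loops2.df, "chrom2", "start2", "end2")
    pav_trees = build_trees(pavs) if len(pavs) else {}
    opp_trees = build_trees(opposing_peaks2.df)
    rows = []
    for row in loops1.df.itertuples(index=False):
        a = (row.chrom1, row.start1 - anchor_slop, row.end1 + anchor_slop)
        b = (row.chrom2, row.start2 - anchor_slop, row.end2 + anchor_slop)
        cand = set()
        for qa, qb in ((a, b), (b, a)):
            first = set(overlapping(t2a, *qa))
            second = set(overlapping(t2b, *qb))
            cand |= first & second
        present = bool(cand)
        if present:
            rows.append((row.id, "both", ""))
            continue
        anchors = ((row.chrom1, row.start1, row.end1),
                   (row.chrom2, row.start2, row.end2))
        if any(overlapping(pav_trees, *an) for an in anchors):
            cause = "PAV_associated"
        elif any(overlapping(opp_trees, *an) for an in anchors):
            cause = "mark_conversion"
        else:
            cause = "unexplained"
        rows.append((row.id, "variety1_only", cause))
    return pd.DataFrame(rows, columns=["loop_id", "present_in", "cause"])
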