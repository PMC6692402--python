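"""Spatial loop support for eQTL / e-trait pairs.

An eQTL-gene pair is loop-supported when some chromatin loop (of any
mark) has one anchor overlapping the eQTL interval and the other anchor
overlapping the target gene's promoter. Contact frequency is the summed
PET count over supporting loops. Support is compared against simulated
pairs matched on genomic distance, with a one-sided rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneTable, GenomeLayout, build_trees, overlapping, warn


def classify_cis_trans(pairs: pd.DataFrame, genes: GeneTable,
                       cis_max_distance: int = 1_000_000) -> pd.DataFrame:
    """Label pairs cis / trans by chromosome and interval gap.

    cis: same chromosome and gap between the eQTL interval and the gene
    body <= ``cis_max_distance`` (containment means gap 0); anything on a
    different chromosome is trans; unknown gene ids become unclassified.
    """
    gdf = genes.df.set_index("gene_id")
    labels = []
    for row in pairs.itertuples(index=False):
        if row.gene_id not in gdf.index:
            warn(f"unknown gene id {row.gene_id!r}; pair unclassified")
            labels.append("unclassified")
            continue
        g = gdf.loc[row.gene_id]
        if g["chrom"] != row.chrom:
            labels.append("trans")
            continue
        gap = max(g["start"] - row.end, row.start - g["end"], 0)
        labels.append("cis" if gap <= cis_max_distance else "trans")
    out = pairs.copy()
    out["cis_trans"] = labels
    return out


def find_loop_supported_pairs(pairs: pd.DataFrame, loop_sets: list,
                              genes: GeneTable, promoter_window: int = 2000,
                              slop: int = 0) -> pd.DataFrame:
    """Flag pairs connected by a loop between eQTL and gene promoter.

    ``loop_sets`` is a list of LoopSet (all marks are eligible). A loop
    supports a pair when one anchor overlaps the eQTL interval +- slop
    and the other overlaps the promoter +- slop, in either orientation.
    Adds supported, supporting_loops and contact_frequency columns.
    """
    prom = genes.promoters(promoter_window).set_index("gene_id")
    supported, loop_ids_col, freq = [], [], []
    indexed = []
    for ls in loop_sets:
        df = ls.df
        indexed.append((df,
                        build_trees(df, "chrom1", "start1", "end1"),
                        build_trees(df, "chrom2", "start2", "end2")))
    for row in pairs.itertuples(index=False):
        e = (row.chrom, row.start - slop, row.end + slop)
        hits, pets = [], 0
        if row.gene_id in prom.index:
            p = prom.loc[row.gene_id]
            pq = (p["chrom"], p["start"] - slop, p["end"] + slop)
            for df, ta, tb in indexed:
                ids = (set(overlapping(ta, *e)) & set(overlapping(tb, *pq))) | \
                      (set(overlapping(ta, *pq)) & set(overlapping(tb, *e)))
                for i in ids:
                    hits.append(df["id"].iloc[i])
                    pets += int(df["pet_count"].iloc[i])
        supported.append(bool(hits))
        loop_ids_col.append(",".join(sorted(set(hits))))
        freq.append(pets)
    out = pairs.copy()
    out["supported"] = supported
    out["supporting_loops"] = loop_ids_col
    out["contact_frequency"] = freq
    return out


def simulate_matched_pairs(pairs: pd.DataFrame, genes: GeneTable,
                           layout: GenomeLayout, n_sims: int = 1,
                           tolerance: float = 0.1, seed: int = 0,
                           eqtl_width: int | None = None) -> list:
    """Random (locus, gene) pairs matched on the real distance distribution.

    For each real same-chromosome pair at distance d (eQTL midpoint to
    TSS), a random gene is drawn and a locus placed at a distance within
    ``d*(1±tolerance)`` on a random side, clipped to the chromosome.
    Interchromosomal real pairs are matched by a random gene plus a
    random locus on a different chromosome. Deterministic per seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    gdf = genes.df
    tss_by_gene = gdf.set_index("gene_id")["tss"]
    chrom_by_gene = gdf.set_index("gene_id")["chrom"]
    widths = (pairs["end"] - pairs["start"]).to_numpy()
    default_w = int(np.median(widths)) if len(widths) else 10_000
    out = []
    for _ in range(n_sims):
        rows = []
        for j, row in enumerate(pairs.itertuples(index=False)):
            w = int(eqtl_width or widths[j] or default_w)
            gchrom = chrom_by_gene.get(row.gene_id)
            intra = gchrom == row.chrom
            for _try in range(200):
                g = gdf.iloc[rng.integers(len(gdf))]
                if intra:
                    mid = (row.start + row.end) // 2
                    d = abs(mid - int(tss_by_gene[row.gene_id]))
                    dd = d * rng.uniform(1 - tolerance, 1 + tolerance)
                    side = rng.choice([-1, 1])
                    center = int(g["tss"] + side * dd)
                    s = center - w // 2
                    e = s + w
                    if s >= 0 and e <= layout.length(g["chrom"]):
                        rows.append((f"sim{j}", g["chrom"], s, e, g["gene_id"]))
                        break
                else:
                    others = [c for c in layout.chrom_names if c != g["chrom"]]
                    if not others:
                        continue
                    c = others[rng.integers(len(others))]
                    s = int(rng.integers(0, max(1, layout.length(c) - w)))
                    rows.append((f"sim{j}", c, s, s + w, g["gene_id"]))
                    break
        out.append(pd.DataFrame(
            rows, columns=["pair_id", "chrom", "start", "end", "gene_id"]))
    return out


def contact_frequency_test(real: pd.DataFrame, simulated: list,
                           loop_sets: list, genes: GeneTable,
                           promoter_window: int = 2000,
                           slop: int = 0) -> dict:
    """One-sided rank-sum test: real contact frequency > simulated.

    ``real`` must already carry contact_frequency (from
    find_loop_supported_pairs); simulated tables are scored identically.
    """
    if len(real) < 10:
        raise ValueError("need >= 10 real pairs for the rank-sum test")
    sim_freq = []
    for sim in simulated:
        scored = find_loop_supported_pairs(sim, loop_sets, genes,
                                           promoter_window, slop)
        sim_freq.append(scored["contact_frequency"].to_numpy())
    sim_all = np.concatenate(sim_freq) if sim_freq else np.array([])
    real_f = real["contact_frequency"].to_numpy()
    if real_f.max() == 0 and (sim_all.size == 0 or sim_all.max() == 0):
        return dict(p_value=1.0, statistic=np.nan, degenerate=True,
                    median_real=0.0, median_simulated=0.0,
                    n_real=len(real_f), n_simulated=int(sim_all.size))
    stat, p = stats.mannwhitneyu(real_f, sim_all, alternative="greater")
    return dict(p_value=float(p), statistic=float(stat), degenerate=False,
                median_real=float(np.median(real_f)),
                median_simulated=float(np.median(sim_all)),
                n_real=len(real_f), n_simulated=int(sim_all.size))
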