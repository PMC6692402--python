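"""Synthetic fixture datasets with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-mark loop sets whose loops chain into connected components
with continuous base-pair coverage inside planted domains, isolated
loops and basal peaks outside them, a peak at every loop anchor with a
configurable anchor fraction, multi-tissue FPKM expression with elevated
correlation for looped gene pairs, and eQTL/e-trait pairs of which a
planted fraction is joined to the target promoter by a loop.

Determinism: one parent seed; every stage draws from its own child
generator derived from (seed, stage name), so adding a stage never
perturbs another stage's stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (GeneTable, GenomeLayout, ExpressionMatrix, LoopSet,
                   PeakSet, ValidationError, build_trees, overlapping, warn)

DEFAULT_SPAN_RANGES = {
    "H3K9me2": (150_000, 400_000),
    "H3K4me3": (50_000, 150_000),
    "RNAPII": (80_000, 250_000),
}
DEFAULT_ANCHOR_WIDTHS = {"H3K9me2": 8_000, "H3K4me3": 2_000, "RNAPII": 3_000}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the conditions the analysis is validated under: a toy
    genome of 2 x 5 Mb chromosomes, 1000 genes, 20 tissues, an anchor
    fraction of 0.43 and a planted loop-supported eQTL fraction of 0.12.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 1000
    n_tissues: int = 20
    anchor_fraction: float = 0.43
    domains_per_mark: dict = field(
        default_factory=lambda: {"H3K9me2": 5, "H3K4me3": 5, "RNAPII": 5})
    span_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SPAN_RANGES))
    anchors_per_domain: int = 8
    isolated_loops_per_mark: int = 30
    coexpr_rho: float = 0.5
    n_eqtl_pairs: int = 500
    supported_fraction: float = 0.12
    trans_fraction: float = 0.24
    pet_geometric_p: float = 0.35
    core_fraction_anchor: float = 0.7
    core_fraction_other: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length <= 0 or self.n_genes < 0:
            raise ValidationError("counts must be positive")
        for frac in (self.anchor_fraction, self.supported_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")
        if not 0 <= self.coexpr_rho < 1:
            raise ValidationError("coexpr_rho must lie in [0, 1)")
        total = sum(n * self.span_ranges[m][1]
                    for m, n in self.domains_per_mark.items())
        if total > 0.9 * self.n_chroms * self.chrom_length:
            raise ValidationError(
                "requested domains cannot be packed into the genome")


@dataclass
class SyntheticTruth:
    """Ground truth describing only generated objects."""

    planted_domains: dict          # mark -> DataFrame(chrom, start, end)
    looped_pair_ids: list          # [(gene_id, gene_id), ...]
    supported_eqtl_ids: list       # pair ids planted with a connecting loop


def _child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage stream from (seed, stage name)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31 - 1)
    return np.random.default_rng(child)


def _pet_counts(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Truncated geometric PET counts, minimum 1 (heavy-tailed support)."""
    return rng.geometric(p, size=n)


class _SpanLedger:
    """Per-mark record of intrachromosomal loop spans already placed.

    Used to keep independently placed loops from stacking base-pair
    coverage >= 2 outside planted domains, which would read as a domain.
    """

    def __init__(self):
        self.trees: dict = {}

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        t = self.trees.get(chrom)
        if t is None:
            return 0
        best = 0
        for iv in t.overlap(start, end):
            best = max(best, min(end, iv.end) - max(start, iv.begin))
        return best

    def add(self, chrom: str, start: int, end: int) -> None:
        self.trees.setdefault(chrom, IntervalTree())[start:end] = True


def _plant_domains(cfg: SimulationConfig, rng: np.random.Generator,
                   layout: GenomeLayout) -> dict:
    """Allocate non-overlapping domain slots round-robin across chromosomes."""
    cursors = {c: 150_000 for c in layout.chrom_names}
    placed: dict = {m: [] for m in cfg.domains_per_mark}
    order = []
    for mark, count in cfg.domains_per_mark.items():
        order.extend([mark] * count)
    rng.shuffle(order)
    chroms = list(layout.chrom_names)
    ci = 0
    for mark in order:
        lo, hi = cfg.span_ranges[mark]
        span = int(rng.integers(lo, hi + 1))
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            start = cursors[chrom]
            gap = int(rng.integers(60_000, 150_000))
            if start + span + gap < layout.length(chrom) - 100_000:
                placed[mark].append((chrom, start, start + span))
                cursors[chrom] = start + span + gap
                break
        else:
            raise ValidationError(
                f"cannot place a {mark} domain of span {span}; "
                "domains exceed the chromosome")
    return {m: pd.DataFrame(v, columns=["chrom", "start", "end"])
            for m, v in placed.items()}


def _domain_loops(rng: np.random.Generator, chrom: str, start: int, end: int,
                  width: int, n_anchors: int, pet_p: float) -> list:
    """Chained loops filling [start, end) with coverage >= 2 everywhere.

    Anchor positions are jittered but the first and last anchors pin the
    planted boundaries. Loops join anchor i to anchor i+2 (overlapping
    spans), plus one loop spanning the whole domain so that the edge
    regions also reach coverage 2.
    """
    n = max(4, n_anchors)
    centers = np.linspace(start + width // 2, end - width // 2, n)
    jitter = (centers[1] - centers[0]) * 0.2
    centers[1:-1] += rng.uniform(-jitter, jitter, size=n - 2)
    anchors = [(int(c - width // 2), int(c + width // 2)) for c in centers]
    anchors[0] = (start, start + width)
    anchors[-1] = (end - width, end)
    loops = []
    for i in range(n - 2):
        a, b = anchors[i], anchors[i + 2]
        loops.append((chrom, a[0], a[1], chrom, b[0], b[1]))
    loops.append((chrom, anchors[0][0], anchors[0][1],
                  chrom, anchors[-1][0], anchors[-1][1]))
    pets = _pet_counts(rng, len(loops), pet_p)
    return [l + (int(p),) for l, p in zip(loops, pets)]


def simulate_dataset(cfg: SimulationConfig):
    """Generate the full fixture.

    Returns ``(layout, peaks, loops, genes, expr, eqtl_pairs, truth)``
    where ``peaks`` and ``loops`` are dicts keyed by mark. Deterministic
    for a fixed config and seed. Every loop anchor carries a peak of its
    mark; the share of peaks overlapping an anchor is ``anchor_fraction``
    up to integer rounding.
    """
    cfg.validate()
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(cfg.n_chroms)),
        tuple([cfg.chrom_length] * cfg.n_chroms))

    rng_dom = _child_rng(cfg.seed, "domains")
    planted = _plant_domains(cfg, rng_dom, layout)

    ledgers = {m: _SpanLedger() for m in cfg.domains_per_mark}
    loop_rows: dict = {m: [] for m in cfg.domains_per_mark}
    for mark, doms in planted.items():
        rng_m = _child_rng(cfg.seed, f"loops:{mark}")
        width = DEFAULT_ANCHOR_WIDTHS.get(mark, 3000)
        for row in doms.itertuples(index=False):
            loop_rows[mark].extend(_domain_loops(
                rng_m, row.chrom, row.start, row.end, width,
                cfg.anchors_per_domain, cfg.pet_geometric_p))
            ledgers[mark].add(row.chrom, row.start, row.end)
        for _ in range(cfg.isolated_loops_per_mark):
            chrom = layout.chrom_names[rng_m.integers(cfg.n_chroms)]
            span = int(rng_m.integers(10_000, 40_000))
            for _try in range(100):
                s = int(rng_m.integers(0, layout.length(chrom) - span - width))
                if ledgers[mark].overlap_bp(chrom, s, s + span + width) == 0:
                    pet = int(_pet_counts(rng_m, 1, cfg.pet_geometric_p)[0])
                    loop_rows[mark].append(
                        (chrom, s, s + width, chrom, s + span,
                         s + span + width, pet))
                    ledgers[mark].add(chrom, s, s + span + width)
                    break

    loops_by_mark: dict = {}
    for mark, rows in loop_rows.items():
        df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                         "chrom2", "start2", "end2",
                                         "pet_count"])
        df["id"] = [f"{mark}_L{i}" for i in range(len(df))]
        df["fdr"] = 0.01
        loops_by_mark[mark] = LoopSet(mark, df, layout)

    # genes: one inside each H3K4me3 anchor (PPI candidates), rest scattered
    rng_g = _child_rng(cfg.seed, "genes")
    k4_loops = loops_by_mark["H3K4me3"].df
    k4_anchor_ivs = sorted({(r.chrom1, r.start1, r.end1) for r in
                            k4_loops.itertuples(index=False)} |
                           {(r.chrom2, r.start2, r.end2) for r in
                            k4_loops.itertuples(index=False)})
    gene_rows = []
    anchor_gene_of: dict = {}
    for c, s, e in k4_anchor_ivs:
        gid = f"gene{len(gene_rows):05d}"
        tss = int((s + e) // 2)
        glen = int(rng_g.integers(2000, 6000))
        strand = "+" if rng_g.random() < 0.5 else "-"
        if strand == "+":
            gs, ge = tss, min(tss + glen, cfg.chrom_length)
        else:
            gs, ge = max(0, tss - glen + 1), tss + 1
        cat = "core" if rng_g.random() < cfg.core_fraction_anchor else "distributed"
        gene_rows.append((gid, c, gs, ge, strand, cat, False))
        anchor_gene_of[(c, s, e)] = gid
    for _ in range(max(0, cfg.n_genes - len(gene_rows))):
        gid = f"gene{len(gene_rows):05d}"
        chrom = layout.chrom_names[rng_g.integers(cfg.n_chroms)]
        glen = int(rng_g.integers(2000, 6000))
        s = int(rng_g.integers(0, cfg.chrom_length - glen))
        strand = "+" if rng_g.random() < 0.5 else "-"
        cat = "core" if rng_g.random() < cfg.core_fraction_other else "distributed"
        gene_rows.append((gid, chrom, s, s + glen, strand, cat, False))
    genes = GeneTable(pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand",
                            "category", "is_te"]), layout)

    looped_pairs = []
    for r in k4_loops.itertuples(index=False):
        g1 = anchor_gene_of.get((r.chrom1, r.start1, r.end1))
        g2 = anchor_gene_of.get((r.chrom2, r.start2, r.end2))
        if g1 and g2 and g1 != g2:
            looped_pairs.append((g1, g2))
    looped_pairs = sorted(set(tuple(sorted(p)) for p in looped_pairs))

    # eQTL pairs (appends the planted connecting loops to loops_by_mark)
    eqtl_pairs, supported_ids = simulate_eqtl_pairs(
        genes, loops_by_mark, layout, cfg.n_eqtl_pairs,
        cfg.supported_fraction, cfg.seed, trans_fraction=cfg.trans_fraction,
        span_ledgers=ledgers)

    # peaks: one at every (final) loop anchor, plus basal peaks scattered
    # clear of all anchors so the anchor fraction is exact up to rounding
    all_anchor_rows = [
        (c, s, e)
        for ls in loops_by_mark.values()
        for r in ls.df.itertuples(index=False)
        for c, s, e in ((r.chrom1, r.start1, r.end1),
                        (r.chrom2, r.start2, r.end2))]
    occ_trees = build_trees(pd.DataFrame(
        all_anchor_rows, columns=["chrom", "start", "end"]))
    peaks_by_mark: dict = {}
    for mark, ls in loops_by_mark.items():
        rng_p = _child_rng(cfg.seed, f"peaks:{mark}")
        anchor_ivs = sorted({(r.chrom1, r.start1, r.end1) for r in
                             ls.df.itertuples(index=False)} |
                            {(r.chrom2, r.start2, r.end2) for r in
                             ls.df.itertuples(index=False)})
        width = DEFAULT_ANCHOR_WIDTHS.get(mark, 3000)
        n_anchor = len(anchor_ivs)
        f = cfg.anchor_fraction
        n_basal = int(round(n_anchor * (1 - f) / f)) if f > 0 else 0
        rows = [(c, s, e, float(rng_p.lognormal(2.0, 0.5)))
                for c, s, e in anchor_ivs]
        for _ in range(n_basal):
            chrom = layout.chrom_names[rng_p.integers(cfg.n_chroms)]
            placed = False
            for _try in range(200):
                s = int(rng_p.integers(0, layout.length(chrom) - width))
                if not overlapping(occ_trees, chrom, s, s + width):
                    rows.append((chrom, s, s + width,
                                 float(rng_p.lognormal(1.5, 0.5))))
                    placed = True
                    break
            if not placed:
                warn(f"could not place a basal {mark} peak; fraction drifts")
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity"])
        peaks_by_mark[mark] = PeakSet(mark, df, layout)

    expr = simulate_expression(genes, looped_pairs, cfg.coexpr_rho,
                               cfg.n_tissues, cfg.seed)
    truth = SyntheticTruth(planted, looped_pairs, supported_ids)
    return layout, peaks_by_mark, loops_by_mark, genes, expr, eqtl_pairs, truth


def simulate_expression(genes: GeneTable, looped_pairs: list, rho: float,
                        n_tissues: int = 20, seed: int = 0,
                        activity: pd.Series | None = None) -> ExpressionMatrix:
    """FPKM matrix in which looped gene pairs share a latent tissue profile.

    Genes in one connected component of the looped-pair graph share a
    latent profile L; a member's log-signal is sqrt(rho)*L +
    sqrt(1-rho)*noise, exponentiated and rescaled to median FPKM 5.
    ``activity`` (per-gene additive log offsets) can plant expression
    differences, e.g. a degree-dependent trend.
    """
    if not 0 <= rho < 1:
        raise ValidationError("rho must lie in [0, 1)")
    for g1, g2 in looped_pairs:
        if g1 not in set(genes.df["gene_id"]) or g2 not in set(genes.df["gene_id"]):
            raise ValidationError(f"looped pair names unknown gene: {g1}, {g2}")
    rng = _child_rng(seed, "expression")
    ids = list(genes.df["gene_id"])
    pos = {g: i for i, g in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    in_component = np.zeros(len(ids), bool)
    for g1, g2 in looped_pairs:
        r1, r2 = find(pos[g1]), find(pos[g2])
        if r1 != r2:
            parent[r2] = r1
        in_component[pos[g1]] = in_component[pos[g2]] = True
    noise = rng.standard_normal((len(ids), n_tissues))
    latent_draws = rng.standard_normal((len(ids), n_tissues))
    comp_latent: dict = {}
    X = np.empty((len(ids), n_tissues))
    for i in range(len(ids)):
        if in_component[i]:
            root = find(i)
            lat = comp_latent.setdefault(root, latent_draws[root])
            X[i] = np.sqrt(rho) * lat + np.sqrt(1 - rho) * noise[i]
        else:
            X[i] = noise[i]
    if activity is not None:
        offsets = pd.Series(activity).reindex(ids).fillna(0.0).to_numpy()
        X = X + offsets[:, None]
    fpkm = np.exp(X)
    med = np.median(fpkm)
    if med > 0:
        fpkm *= 5.0 / med
    df = pd.DataFrame(fpkm, index=ids,
                      columns=[f"tissue{t + 1:02d}" for t in range(n_tissues)])
    return ExpressionMatrix(df)


def simulate_eqtl_pairs(genes: GeneTable, loops_by_mark: dict,
                        layout: GenomeLayout, n_pairs: int,
                        supported_fraction: float, seed: int,
                        trans_fraction: float = 0.24,
                        promoter_window: int = 2000,
                        span_ledgers: dict | None = None):
    """eQTL/e-trait pairs; a planted subset is loop-connected.

    Exactly ``round(n_pairs * supported_fraction)`` pairs receive a loop
    joining the eQTL interval to the target promoter (assigned round-
    robin across marks; trans pairs get interchromosomal loops).
    Unsupported pairs draw distances from the same distribution but
    their eQTL intervals are placed clear of every loop anchor, so they
    cannot be supported by construction. The planted intrachromosomal
    loop spans avoid stacking on existing same-mark spans (via
    ``span_ledgers``) so they cannot fake domain-level coverage.
    Returns ``(pairs, supported_ids)``; ``loops_by_mark`` is updated with
    the planted loops.
    """
    rng = _child_rng(seed, "eqtl")
    n_supported = int(round(n_pairs * supported_fraction))
    if supported_fraction > 0 and n_supported < 1:
        warn("supported_fraction * n_pairs < 1; planting 0 supported pairs")
    gdf = genes.df
    marks = sorted(loops_by_mark)
    if span_ledgers is None:
        span_ledgers = {m: _SpanLedger() for m in marks}
        for m in marks:
            sub = loops_by_mark[m].df
            intra = sub[sub["chrom1"] == sub["chrom2"]]
            for r in intra.itertuples(index=False):
                span_ledgers[m].add(r.chrom1, r.start1, r.end2)
    planted_loops: dict = {m: [] for m in marks}
    anchor_rows = [
        (c, s, e) for ls in loops_by_mark.values()
        for r in ls.df.itertuples(index=False)
        for c, s, e in ((r.chrom1, r.start1, r.end1),
                        (r.chrom2, r.start2, r.end2))]
    anchor_trees = build_trees(pd.DataFrame(
        anchor_rows, columns=["chrom", "start", "end"]))

    def _add_anchor(chrom, s, e):
        anchor_trees.setdefault(chrom, IntervalTree())[s:e] = -1

    rows, supported_ids = [], []
    width = 10_000
    for j in range(n_pairs):
        pid = f"eqtl{j:04d}"
        supported = j < n_supported
        mark = marks[j % len(marks)] if marks else None
        is_trans = rng.random() < trans_fraction
        placed = None
        for _try in range(300):
            g = gdf.iloc[int(rng.integers(len(gdf)))]
            tss = int(g["tss"])
            d = int(rng.lognormal(np.log(150_000), 0.6))
            if is_trans:
                others = [c for c in layout.chrom_names if c != g["chrom"]]
                if not others:
                    continue
                chrom = others[int(rng.integers(len(others)))]
                s = int(rng.integers(0, layout.length(chrom) - width))
            else:
                chrom = g["chrom"]
                side = -1 if rng.random() < 0.5 else 1
                s = min(max(0, tss + side * d - width // 2),
                        layout.length(chrom) - width)
            if supported:
                if not is_trans and mark is not None:
                    ps = max(0, tss - promoter_window)
                    pe = min(layout.length(g["chrom"]), tss + promoter_window)
                    lo, hi = min(s, ps), max(s + width, pe)
                    # keep planted spans off existing same-mark spans
                    if span_ledgers[mark].overlap_bp(chrom, lo, hi) > 5000:
                        continue
                placed = (g, chrom, s, is_trans)
                break
            else:
                if not overlapping(anchor_trees, chrom, s, s + width):
                    placed = (g, chrom, s, is_trans)
                    break
        if placed is None:
            warn(f"could not place eQTL pair {pid}; skipping")
            continue
        g, chrom, s, is_trans = placed
        tss = int(g["tss"])
        rows.append((pid, chrom, s, s + width, g["gene_id"]))
        if supported and mark is not None:
            ps = max(0, tss - promoter_window)
            pe = min(layout.length(g["chrom"]), tss + promoter_window)
            pet = int(_pet_counts(rng, 1, 0.35)[0]) + 2
            planted_loops[mark].append(
                (chrom, s, s + width, g["chrom"], ps, pe, pet))
            supported_ids.append(pid)
            _add_anchor(chrom, s, s + width)
            _add_anchor(g["chrom"], ps, pe)
            if not is_trans:
                span_ledgers[mark].add(chrom, min(s, ps), max(s + width, pe))
    for mark in marks:
        if not planted_loops[mark]:
            continue
        add = pd.DataFrame(planted_loops[mark],
                           columns=["chrom1", "start1", "end1",
                                    "chrom2", "start2", "end2", "pet_count"])
        base = loops_by_mark[mark].df
        add["id"] = [f"{mark}_eqtlL{i}" for i in range(len(add))]
        add["fdr"] = 0.01
        merged = pd.concat([base, add], ignore_index=True)
        loops_by_mark[mark] = LoopSet(mark, merged, layout)
    pairs = pd.DataFrame(rows, columns=["pair_id", "chrom", "start", "end",
                                        "gene_id"])
    return pairs, supported_ids
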