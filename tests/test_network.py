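import numpy as np
import pandas as pd
import pytest

from chialoop import (GeneTable, LoopSet, build_gene_network,
                      degree_expression_table, extract_subnetworks)
from chialoop.core import ExpressionMatrix
from chialoop.simulate import simulate_expression
from conftest import random_genes, random_loops


def _genes(rows):
    return GeneTable(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "category", "is_te"]))


def _loops(rows):
    return LoopSet("H3K4me3", pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                       "end2", "id", "pet_count", "fdr"]))


def test_edges_from_promoter_anchor_overlap():
    genes = _genes([("gA", "chr1", 1000, 3000, "+", "unknown", False),
                    ("gB", "chr1", 50_000, 52_000, "+", "unknown", False),
                    ("gC", "chr1", 50_500, 52_500, "+", "unknown", False)])
    # one anchor over gA's promoter, other over gB+gC promoters
    loops = _loops([("chr1", 500, 1500, "chr1", 49_500, 51_000,
                     "L1", 5, 0.0)])
    net = build_gene_network(loops, genes, promoter_window=2000)
    assert set(map(frozenset, net.graph.edges)) == \
        {frozenset({"gA", "gB"}), frozenset({"gA", "gC"})}


def test_self_loop_counted_not_edged():
    genes = _genes([("gA", "chr1", 10_000, 12_000, "+", "unknown", False)])
    loops = _loops([("chr1", 9000, 10_500, "chr1", 10_800, 11_500,
                     "L1", 3, 0.0)])
    net = build_gene_network(loops, genes, promoter_window=2000)
    assert net.graph.number_of_edges() == 0
    assert net.report["n_self_loop_events"] == 1


def brute_network(loops, genes, window):
    prom = genes.promoters(window)
    edges = {}
    for l in loops.df.itertuples(index=False):
        g1, g2 = set(), set()
        for p in prom.itertuples(index=False):
            if p.chrom == l.chrom1 and p.start < l.end1 and l.start1 < p.end:
                g1.add(p.gene_id)
            if p.chrom == l.chrom2 and p.start < l.end2 and l.start2 < p.end:
                g2.add(p.gene_id)
        for a in g1:
            for b in g2:
                if a != b:
                    key = frozenset({a, b})
                    edges.setdefault(key, set()).add(l.id)
    return edges


def test_network_matches_bruteforce_enumeration():
    rng = np.random.default_rng(31)
    for _ in range(50):
        genes = random_genes(rng, int(rng.integers(2, 50)))
        loops = random_loops(rng, int(rng.integers(1, 30)))
        net = build_gene_network(loops, genes, 2000)
        expect = brute_network(loops, genes, 2000)
        got = {frozenset({u, v}): d["loop_ids"]
               for u, v, d in net.graph.edges(data=True)}
        assert got == expect


def test_degree_sum_equals_twice_edges(sim_data):
    net = build_gene_network(sim_data["loops"]["H3K4me3"], sim_data["genes"])
    assert int(net.degrees.sum()) == 2 * net.graph.number_of_edges()


def test_extract_subnetworks_thresholds_and_ranking():
    genes = _genes([(f"g{i}", "chr1", i * 10_000, i * 10_000 + 2000, "+",
                     "unknown", False) for i in range(6)])
    rows = []
    # chain g0-g1-g2 with strong support, pair g3-g4 weak (pets 3 < 4)
    for i, (a, b, pets) in enumerate([(0, 1, 5), (1, 2, 6), (3, 4, 3)]):
        rows.append(("chr1", a * 10_000, a * 10_000 + 1500,
                     "chr1", b * 10_000, b * 10_000 + 1500,
                     f"L{i}", pets, 0.0))
    net = build_gene_network(_loops(rows), genes, promoter_window=2000)
    subs = extract_subnetworks(net, min_intra_pets=4, min_inter_pets=6,
                               top_k=10)
    assert subs == [["g0", "g1", "g2"]]
    top1 = extract_subnetworks(net, min_intra_pets=1, min_inter_pets=1,
                               top_k=1)
    assert top1 == [["g0", "g1", "g2"]]


def test_subnetworks_invariant_to_edge_order():
    rng = np.random.default_rng(4)
    genes = random_genes(rng, 40)
    loops = random_loops(rng, 25)
    net1 = build_gene_network(loops, genes, 2000)
    shuffled = LoopSet(loops.mark,
                       loops.df.sample(frac=1, random_state=9))
    net2 = build_gene_network(shuffled, genes, 2000)
    assert extract_subnetworks(net1, 2, 2, 50) == \
        extract_subnetworks(net2, 2, 2, 50)


def test_degree_expression_trend_detected():
    """Planted degree-scaled expression yields a positive trend."""
    rng = np.random.default_rng(8)
    n = 200
    genes = _genes([(f"g{i}", "chr1", i * 20_000, i * 20_000 + 2000, "+",
                     "unknown", False) for i in range(n)])
    # star-like pairing: hubs acquire high degree
    pairs, rows = [], []
    k = 0
    for hub in range(0, 40):
        for spoke in range(40 + hub * 4, 40 + hub * 4 + hub % 5 + 1):
            if spoke >= n:
                continue
            pairs.append((f"g{hub}", f"g{spoke}"))
            rows.append(("chr1", hub * 20_000, hub * 20_000 + 1500,
                         "chr1", spoke * 20_000, spoke * 20_000 + 1500,
                         f"L{k}", 3, 0.0))
            k += 1
    net = build_gene_network(_loops(rows), genes, promoter_window=2000)
    deg = net.degrees
    activity = pd.Series({g: 0.5 * deg.get(g, 0) for g in genes.df["gene_id"]})
    expr = simulate_expression(genes, [], rho=0.0, n_tissues=20, seed=3,
                               activity=activity)
    table = degree_expression_table(net, expr, "tissue01")
    assert table.attrs["trend"]["spearman_rho"] > 0
    assert table.attrs["trend"]["p_value"] < 0.05


def test_degree_expression_edge_cases():
    genes = _genes([("gA", "chr1", 0, 2000, "+", "unknown", False),
                    ("gB", "chr1", 30_000, 32_000, "+", "unknown", False)])
    loops = _loops([("chr1", 0, 1000, "chr1", 30_000, 31_000, "L", 2, 0.0)])
    net = build_gene_network(loops, genes, 2000)
    expr = ExpressionMatrix(pd.DataFrame(
        np.ones((2, 3)), index=["gA", "gB"], columns=["t1", "t2", "t3"]))
    table = degree_expression_table(net, expr, "t1")
    assert set(table["degree_class"]) == {"1"}
    assert table.attrs["trend"] is None
    with pytest.raises(KeyError):
        degree_expression_table(net, expr, "missing")
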