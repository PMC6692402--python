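import numpy as np
import pandas as pd
import pytest

from chialoop import (GeneTable, GenomeLayout, LoopSet, classify_cis_trans,
                      contact_frequency_test, find_loop_supported_pairs,
                      simulate_matched_pairs)


def _genes(rows):
    return GeneTable(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "category", "is_te"]))


def _loops(rows, mark="H3K4me3"):
    return LoopSet(mark, pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                       "end2", "id", "pet_count", "fdr"]))


@pytest.fixture
def genes():
    return _genes([
        ("gNear", "chr1", 5000, 8000, "+", "unknown", False),
        ("gFar", "chr1", 4_000_000, 4_003_000, "+", "unknown", False),
        ("gOther", "chr2", 100_000, 103_000, "+", "unknown", False),
    ])


def test_cis_trans_rules(genes):
    pairs = pd.DataFrame({
        "pair_id": ["contained", "crosschrom", "far"],
        "chrom": ["chr1", "chr2", "chr1"],
        "start": [4000, 0, 1_500_000],
        "end": [9000, 10_000, 1_510_000],
        "gene_id": ["gNear", "gNear", "gFar"],
    })
    out = classify_cis_trans(pairs, genes, cis_max_distance=1_000_000)
    got = out.set_index("pair_id")["cis_trans"]
    assert got["contained"] == "cis"      # containment -> gap 0
    assert got["crosschrom"] == "trans"
    assert got["far"] == "trans"          # gap ~2.49 Mb > 1 Mb
    unknown = pd.DataFrame({"pair_id": ["x"], "chrom": ["chr1"],
                            "start": [0], "end": [100],
                            "gene_id": ["missing"]})
    with pytest.warns(UserWarning):
        out2 = classify_cis_trans(unknown, genes)
    assert out2.iloc[0]["cis_trans"] == "unclassified"


def test_loop_support_two_sided_requirement(genes):
    pairs = pd.DataFrame({
        "pair_id": ["sup", "onesided"],
        "chrom": ["chr1", "chr1"],
        "start": [1000, 1000],
        "end": [2000, 2000],
        "gene_id": ["gNear", "gFar"],
    })
    loops = [_loops([
        # joins eQTL [1000,2000) to gNear promoter (tss 5000, window 2000)
        ("chr1", 1000, 2000, "chr1", 4000, 6000, "support", 7, 0.0),
        # both anchors on the eQTL only
        ("chr1", 900, 1500, "chr1", 1500, 2100, "useless", 3, 0.0),
    ])]
    out = find_loop_supported_pairs(pairs, loops, genes, promoter_window=2000)
    by_id = out.set_index("pair_id")
    assert bool(by_id.loc["sup", "supported"])
    assert by_id.loc["sup", "contact_frequency"] == 7
    assert by_id.loc["sup", "supporting_loops"] == "support"
    assert not bool(by_id.loc["onesided", "supported"])


def brute_support(pairs, loop_sets, genes, window):
    prom = genes.promoters(window).set_index("gene_id")
    flags = []
    for p in pairs.itertuples(index=False):
        hit = False
        if p.gene_id in prom.index:
            pr = prom.loc[p.gene_id]
            for ls in loop_sets:
                for l in ls.df.itertuples(index=False):
                    a = (l.chrom1, l.start1, l.end1)
                    b = (l.chrom2, l.start2, l.end2)
                    for (c1, s1, e1), (c2, s2, e2) in ((a, b), (b, a)):
                        if (c1 == p.chrom and s1 < p.end and p.start < e1 and
                                c2 == pr["chrom"] and s2 < pr["end"] and
                                pr["start"] < e2):
                            hit = True
        flags.append(hit)
    return flags


def test_support_matches_bruteforce_triple_loop():
    rng = np.random.default_rng(29)
    for _ in range(40):
        n_genes = int(rng.integers(3, 20))
        grows = []
        for i in range(n_genes):
            s = int(rng.integers(0, 200_000))
            grows.append((f"g{i}", "chr1", s, s + 2000, "+", "unknown", False))
        genes = _genes(grows)
        lrows = []
        for i in range(int(rng.integers(1, 25))):
            s1 = int(rng.integers(0, 200_000))
            s2 = int(rng.integers(0, 200_000))
            lrows.append(("chr1", s1, s1 + 2500, "chr1", s2, s2 + 2500,
                          f"L{i}", int(rng.integers(1, 9)), 0.0))
        loop_sets = [_loops(lrows)]
        prows = []
        for i in range(int(rng.integers(1, 30))):
            s = int(rng.integers(0, 200_000))
            prows.append((f"e{i}", "chr1", s, s + 3000,
                          f"g{int(rng.integers(n_genes))}"))
        pairs = pd.DataFrame(prows, columns=["pair_id", "chrom", "start",
                                             "end", "gene_id"])
        got = find_loop_supported_pairs(pairs, loop_sets, genes, 2000)
        assert got["supported"].tolist() == \
            brute_support(pairs, loop_sets, genes, 2000)


def test_supported_implies_positive_frequency(sim_data):
    out = find_loop_supported_pairs(sim_data["eqtl"],
                                    list(sim_data["loops"].values()),
                                    sim_data["genes"])
    sup = out[out["supported"]]
    assert (sup["contact_frequency"] >= 1).all()
    unsup = out[~out["supported"]]
    assert (unsup["contact_frequency"] == 0).all()


def test_simulated_pairs_distance_matched(sim_data):
    layout, genes = sim_data["layout"], sim_data["genes"]
    pairs = sim_data["eqtl"]
    sims = simulate_matched_pairs(pairs, genes, layout, n_sims=2,
                                  tolerance=0.1, seed=9)
    assert len(sims) == 2
    # determinism
    again = simulate_matched_pairs(pairs, genes, layout, n_sims=2,
                                   tolerance=0.1, seed=9)
    pd.testing.assert_frame_equal(sims[0], again[0])
    tss = genes.df.set_index("gene_id")["tss"]
    chrom_of = genes.df.set_index("gene_id")["chrom"]

    def dists(tab):
        out = []
        for r in tab.itertuples(index=False):
            if chrom_of[r.gene_id] == r.chrom:
                out.append(abs((r.start + r.end) // 2 - tss[r.gene_id]))
        return np.array(out)

    from scipy import stats
    d_real, d_sim = dists(pairs), dists(sims[0])
    p = stats.mannwhitneyu(d_real, d_sim).pvalue
    assert p > 0.05  # same distance distribution


def test_contact_frequency_test_preconditions(genes):
    few = pd.DataFrame({"pair_id": ["a"], "chrom": ["chr1"], "start": [0],
                        "end": [100], "gene_id": ["gNear"],
                        "contact_frequency": [1]})
    with pytest.raises(ValueError):
        contact_frequency_test(few, [], [], genes)


def test_contact_frequency_planted_separation(sim_data):
    out = find_loop_supported_pairs(sim_data["eqtl"],
                                    list(sim_data["loops"].values()),
                                    sim_data["genes"])
    sup = out[out["supported"]]
    sims = simulate_matched_pairs(out, sim_data["genes"], sim_data["layout"],
                                  n_sims=2, seed=3)
    res = contact_frequency_test(sup, sims, list(sim_data["loops"].values()),
                                 sim_data["genes"])
    assert res["p_value"] < 0.001
    assert res["median_real"] >= 1
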