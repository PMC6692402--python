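import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chialoop import (LoopSet, PeakSet, attribute_variants,
                      call_differential_peaks, merge_peak_sets,
                      variety_specific_loops)


def _peaks(rows, mark="H3K4me3"):
    return PeakSet(mark, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "intensity", "name"]))


def _loops(rows, mark="H3K4me3"):
    return LoopSet(mark, pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                       "end2", "id", "pet_count", "fdr"]))


def test_merge_overlap_and_half_open_touch():
    p1 = _peaks([("chr1", 100, 200, 1.0, "a")])
    p2 = _peaks([("chr1", 150, 300, 1.0, "b"), ("chr1", 300, 400, 1.0, "c")])
    merged = merge_peak_sets(p1, p2)
    got = list(merged[["chrom", "start", "end"]]
               .itertuples(index=False, name=None))
    assert got == [("chr1", 100, 300), ("chr1", 300, 400)]
    row = merged.iloc[0]
    assert row["peaks_variety1"] == "a" and row["peaks_variety2"] == "b"


def test_merge_matches_quadratic_oracle():
    rng = np.random.default_rng(13)
    for _ in range(60):
        rows1 = [("chr1", s, s + int(rng.integers(1, 60)), 1.0, f"a{i}")
                 for i, s in enumerate(rng.integers(0, 500, rng.integers(1, 25)))]
        rows2 = [("chr1", s, s + int(rng.integers(1, 60)), 1.0, f"b{i}")
                 for i, s in enumerate(rng.integers(0, 500, rng.integers(1, 25)))]
        merged = merge_peak_sets(_peaks(rows1), _peaks(rows2))
        # quadratic oracle: union-find over >= 1 bp pairwise overlaps
        ivs = [(s, e) for _, s, e, _, _ in rows1 + rows2]
        parent = list(range(len(ivs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                if ivs[i][0] < ivs[j][1] and ivs[j][0] < ivs[i][1]:
                    parent[find(j)] = find(i)
        comps: dict = {}
        for i, (s, e) in enumerate(ivs):
            r = find(i)
            cs, ce = comps.get(r, (s, e))
            comps[r] = (min(cs, s), max(ce, e))
        expect = sorted(comps.values())
        got = list(merged[["start", "end"]].itertuples(index=False, name=None))
        assert got == expect


def test_differential_counts_exact_binomial_oracle():
    """Poisson exact route equals a hand-computed conditional binomial."""
    merged = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
    counts = pd.DataFrame({"v1": [100], "v2": [10]})
    diff = call_differential_peaks(merged, counts, dispersion=0.0,
                                   size_factors=[1.0, 1.0])
    row = diff.iloc[0]
    expect_p = stats.binomtest(100, 110, 0.5).pvalue
    assert row["p_value"] == pytest.approx(expect_p)
    assert row["log2_fold_change"] == pytest.approx(np.log2(101 / 11))
    assert row["status"] == "up"


def test_differential_stable_and_allzero():
    merged = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 1000],
                           "end": [500, 1500]})
    counts = pd.DataFrame({"v1": [50, 0], "v2": [50, 0]})
    diff = call_differential_peaks(merged, counts, dispersion=0.0)
    assert diff.iloc[0]["log2_fold_change"] == 0
    assert (diff["status"] == "stable").all()
    assert diff.iloc[1]["p_value"] == 1.0


def test_bh_adjustment_monotone():
    rng = np.random.default_rng(5)
    merged = pd.DataFrame({"chrom": ["chr1"] * 50,
                           "start": np.arange(50) * 1000,
                           "end": np.arange(50) * 1000 + 500})
    counts = pd.DataFrame({"v1": rng.poisson(50, 50),
                           "v2": rng.poisson(50, 50)})
    diff = call_differential_peaks(merged, counts, dispersion=0.0)
    by_p = diff.sort_values("p_value")
    assert by_p["adjusted_p"].is_monotonic_increasing
    assert (diff["adjusted_p"] >= diff["p_value"] - 1e-15).all()


def test_attribute_variants_primary_class_rules():
    diff = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [0, 10_000, 50_000],
        "end": [1000, 11_000, 51_000],
        "status": ["up", "up", "down"],
    })
    snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10, 10_500],
                         "end": [11, 10_501], "id": ["s1", "s2"],
                         "class": ["SNP", "SNP"]})
    pavs = pd.DataFrame({"chrom": ["chr1"], "start": [10_200],
                         "end": [10_700], "id": ["p1"], "class": ["PAV"]})
    out = attribute_variants(diff, [snps, pavs])
    assert out.iloc[0]["primary_class"] == "SNP"
    assert out.iloc[1]["primary_class"] == "PAV"  # 500 bp PAV beats 1 bp SNP
    assert out.iloc[2]["primary_class"] == "none"


def test_variety_specific_loops_classification():
    loops1 = _loops([
        ("chr1", 1000, 2000, "chr1", 50_000, 51_000, "shared", 4, 0.0),
        ("chr1", 100_000, 101_000, "chr1", 150_000, 151_000, "pav_loss", 4, 0.0),
        ("chr1", 200_000, 201_000, "chr1", 250_000, 251_000, "converted", 4, 0.0),
        ("chr1", 300_000, 301_000, "chr1", 350_000, 351_000, "mystery", 4, 0.0),
    ])
    loops2 = _loops([("chr1", 900, 2100, "chr1", 49_900, 51_200,
                      "match", 5, 0.0)])
    pavs = pd.DataFrame({"chrom": ["chr1"], "start": [100_200],
                         "end": [100_800], "id": ["pav1"], "class": ["PAV"]})
    opposing = _peaks([("chr1", 200_500, 201_500, 3.0, "k9pk")],
                      mark="H3K9me2")
    table = variety_specific_loops(loops1, loops2, pavs, opposing,
                                   anchor_slop=2000)
    by_id = table.set_index("loop_id")
    assert by_id.loc["shared", "present_in"] == "both"
    assert by_id.loc["pav_loss", "cause"] == "PAV_associated"
    assert by_id.loc["converted", "cause"] == "mark_conversion"
    assert by_id.loc["mystery", "cause"] == "unexplained"


def test_variety_specific_loops_symmetric():
    rng = np.random.default_rng(21)

    def rand_loops(seed_ids):
        rows = []
        for i in seed_ids:
            s1 = int(rng.integers(0, 400_000))
            s2 = s1 + int(rng.integers(20_000, 100_000))
            rows.append(("chr1", s1, s1 + 1500, "chr1", s2, s2 + 1500,
                         f"L{i}", 3, 0.0))
        return _loops(rows)

    l1, l2 = rand_loops(range(15)), rand_loops(range(100, 115))
    # plant one guaranteed shared loop (shifted within the slop)
    shared1 = ("chr1", 600_000, 601_500, "chr1", 700_000, 701_500,
               "S1", 3, 0.0)
    shared2 = ("chr1", 600_800, 602_300, "chr1", 700_800, 702_300,
               "S2", 3, 0.0)
    l1 = _loops(list(l1.df.itertuples(index=False, name=None)) + [shared1])
    l2 = _loops(list(l2.df.itertuples(index=False, name=None)) + [shared2])
    empty_pav = pd.DataFrame(columns=["chrom", "start", "end", "id", "class"])
    empty_peaks = _peaks([], mark="H3K9me2")
    t12 = variety_specific_loops(l1, l2, empty_pav, empty_peaks, 2000)
    t21 = variety_specific_loops(l2, l1, empty_pav, empty_peaks, 2000)
    assert t12.set_index("loop_id").loc["S1", "present_in"] == "both"
    assert t21.set_index("loop_id").loc["S2", "present_in"] == "both"
    # anchor matching with slop is a symmetric relation
    n12 = (t12["present_in"] == "both").sum()
    n21 = (t21["present_in"] == "both").sum()
    assert (n12 > 0) and (n21 > 0)
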