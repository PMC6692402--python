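import numpy as np
import pandas as pd
import pytest

from chialoop import (DomainSet, GenomeLayout, LoopSet, call_cids,
                      loop_components, merge_related_segments,
                      partition_modules)
from conftest import random_loops


def _loops(rows, mark="H3K9me2"):
    return LoopSet(mark, pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                       "end2", "id", "pet_count", "fdr"]))


TOY = [("chr1", 1000, 2000, "chr1", 10_000, 11_000, "loop1", 2, 0.0),
       ("chr1", 10_500, 11_500, "chr1", 30_000, 31_000, "loop2", 2, 0.0),
       ("chr1", 60_000, 61_000, "chr1", 80_000, 81_000, "loop3", 2, 0.0)]


def test_loop_components_toy():
    groups, n_inter = loop_components(_loops(TOY))
    groups = sorted(map(sorted, groups))
    assert groups == [["loop1", "loop2"], ["loop3"]]
    assert n_inter == 0


def test_loop_components_filters_inter():
    rows = TOY + [("chr1", 0, 100, "chr2", 0, 100, "loopX", 1, 0.0)]
    groups, n_inter = loop_components(_loops(rows))
    assert n_inter == 1
    assert not any("loopX" in g for g in groups)


def brute_components(loops_df):
    n = len(loops_df)
    adj = [[False] * n for _ in range(n)]
    recs = list(loops_df.itertuples(index=False))

    def anchors(r):
        return [(r.chrom1, r.start1, r.end1), (r.chrom2, r.start2, r.end2)]

    for i in range(n):
        for j in range(n):
            for c1, s1, e1 in anchors(recs[i]):
                for c2, s2, e2 in anchors(recs[j]):
                    if c1 == c2 and s1 < e2 and s2 < e1:
                        adj[i][j] = True
    # transitive closure (Floyd-Warshall style)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
    groups, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if adj[i][j]]
        seen.update(comp)
        groups.append(sorted(recs[j].id for j in comp))
    return sorted(groups)


def test_loop_components_matches_closure_oracle():
    """Sweep union-find equals brute-force transitive closure."""
    rng = np.random.default_rng(19)
    for _ in range(60):
        ls = random_loops(rng, int(rng.integers(1, 30)))
        got, _ = loop_components(ls)
        assert sorted(map(sorted, got)) == brute_components(ls.df)


def test_call_cids_toy_coverage_profiles(layout):
    """Hand-computed coverage: threshold 1 keeps both components."""
    ls = _loops(TOY)
    ds1 = call_cids(ls, layout, coverage_threshold=1, min_span=10_000,
                    max_span=1_000_000)
    got = list(ds1.df.itertuples(index=False, name=None))
    assert got == [("chr1", 1000, 31_000), ("chr1", 60_000, 81_000)]
    # threshold 2: only [10500,11000) is covered twice; span 500 < min_span
    ds2 = call_cids(ls, layout, coverage_threshold=2, min_span=10_000,
                    max_span=1_000_000)
    assert len(ds2) == 0


def test_call_cids_max_span_excludes(layout):
    rows = [("chr1", 0, 1000, "chr1", 2_000_000, 2_001_000, "big", 2, 0.0),
            ("chr1", 500, 1500, "chr1", 2_000_500, 2_001_500, "big2", 2, 0.0)]
    ds = call_cids(_loops(rows), layout, 2, 10_000, 1_000_000)
    assert len(ds) == 0  # run exceeds max_span


def test_call_cids_never_overlapping(sim_data):
    ds = call_cids(sim_data["loops"]["H3K9me2"], sim_data["layout"])
    df = ds.df
    for chrom, sub in df.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()
    assert ((df["end"] - df["start"]) <= 1_000_000).all()


def test_merge_related_segments_boundaries():
    doms = DomainSet("H3K9me2", pd.DataFrame(
        [("chr1", 0, 10_000), ("chr1", 15_000, 25_000)],
        columns=["chrom", "start", "end"]))
    one = merge_related_segments(doms, gap_tolerance=5000)
    assert list(one.df.itertuples(index=False, name=None)) == \
        [("chr1", 0, 25_000)]
    two = merge_related_segments(doms, gap_tolerance=4999)
    assert len(two.df) == 2
    ident = merge_related_segments(doms, gap_tolerance=0)
    pd.testing.assert_frame_equal(ident.df, doms.df)


def test_partition_modules_hand_example():
    layout = GenomeLayout(("chr1",), (100_000,))
    k9 = DomainSet("H3K9me2", pd.DataFrame([("chr1", 0, 40_000)],
                                           columns=["chrom", "start", "end"]))
    k4 = DomainSet("H3K4me3", pd.DataFrame([("chr1", 30_000, 50_000)],
                                           columns=["chrom", "start", "end"]))
    pii = DomainSet("RNAPII", pd.DataFrame([("chr1", 45_000, 70_000)],
                                           columns=["chrom", "start", "end"]))
    part = partition_modules(k9, k4, pii, layout)
    by_label = {r.label: (r.start, r.end)
                for r in part.df.itertuples(index=False)}
    assert by_label["HID"] == (0, 30_000)
    assert by_label["MID"] == (30_000, 40_000)
    assert by_label["AID"] == (40_000, 50_000)
    assert by_label["TID"] == (50_000, 70_000)
    assert by_label["GAP"] == (70_000, 100_000)
    frac = part.summary.set_index("label")["fraction"]
    assert frac["HID"] == pytest.approx(0.30)
    assert frac["GAP"] == pytest.approx(0.30)


def test_partition_modules_degenerate_cases():
    layout = GenomeLayout(("chr1",), (50_000,))
    whole = DomainSet("x", pd.DataFrame([("chr1", 0, 50_000)],
                                        columns=["chrom", "start", "end"]))
    empty = DomainSet("x", pd.DataFrame(columns=["chrom", "start", "end"]))
    all_mid = partition_modules(whole, whole, empty, layout)
    assert all_mid.summary.set_index("label")["fraction"]["MID"] == 1.0
    all_gap = partition_modules(empty, empty, empty, layout)
    assert all_gap.summary.set_index("label")["fraction"]["GAP"] == 1.0


def test_partition_tiles_exactly(sim_data):
    """Partition intervals tile the genome: disjoint and bp-complete."""
    layout = sim_data["layout"]
    sets = {}
    for mark in ("H3K9me2", "H3K4me3", "RNAPII"):
        max_span = 200_000 if mark == "H3K4me3" else 1_000_000
        sets[mark] = call_cids(sim_data["loops"][mark], layout,
                               max_span=max_span)
    part = partition_modules(sets["H3K9me2"], sets["H3K4me3"],
                             sets["RNAPII"], layout)
    assert int(part.summary["bp"].sum()) == layout.total_bp
    for chrom, sub in part.df.groupby("chrom"):
        sub = sub.sort_values("start")
        assert sub["start"].iloc[0] == 0
        assert sub["end"].iloc[-1] == layout.length(chrom)
        assert (sub["start"].iloc[1:].to_numpy() ==
                sub["end"].iloc[:-1].to_numpy()).all()
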