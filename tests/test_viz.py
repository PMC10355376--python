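"""Visual-analysis tables: rainfall, binned frequency, flanking bases,
box summaries, hierarchical clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hgcube.genome import GenomeDef, GenomeError
from hgcube.hgsuite_format import HGSuiteError, parse_hgsuite
from hgcube.track_store import POINTS, SEGMENTS, IndexedTrack, Interval
from hgcube import viz

from helpers import random_point_track


def points(genome, positions, chrom="chr1", names=None):
    return IndexedTrack.from_intervals(
        genome, [Interval(chrom, p, p + 1, names[i] if names else None)
                 for i, p in enumerate(positions)], POINTS)


# -- rainfall --------------------------------------------------------------

def test_rainfall_distances(small_genome):
    t = points(small_genome, [10, 15, 115])
    table = viz.rainfall_table(t)
    assert list(table["pos"]) == [10, 15, 115]
    assert math.isnan(table["dist"].iloc[0])
    assert list(table["dist"].iloc[1:]) == [5, 100]


def test_rainfall_global_offsets_across_chromosomes():
    g = GenomeDef("two", (("chr1", 100), ("chr2", 100)))
    t = IndexedTrack.from_intervals(
        g, [Interval("chr1", 90, 91), Interval("chr2", 10, 11)], POINTS)
    table = viz.rainfall_table(t)
    assert list(table["global_pos"]) == [90, 110]
    assert table["dist"].iloc[1] == 20


def test_rainfall_single_chromosome_scope():
    g = GenomeDef("two", (("chr1", 100), ("chr2", 100)))
    t = IndexedTrack.from_intervals(
        g, [Interval("chr1", 90, 91), Interval("chr2", 10, 11)], POINTS)
    table = viz.rainfall_table(t, scope="chr2")
    assert len(table) == 1
    assert table["global_pos"].iloc[0] == 10
    assert math.isnan(table["dist"].iloc[0])


def test_rainfall_row_count_conserved_and_order_invariant(small_genome, rng):
    pos = list(rng.integers(0, 10_000, size=80))
    t1 = points(small_genome, pos)
    t2 = points(small_genome, list(reversed(pos)))
    a, b = viz.rainfall_table(t1), viz.rainfall_table(t2)
    assert len(a) == 80
    pd.testing.assert_frame_equal(a, b)
    # distances match a sort-and-diff oracle
    expect = np.diff(np.sort(pos))
    assert list(a["dist"].iloc[1:]) == list(expect)


def test_rainfall_per_type_distances(small_genome):
    t = points(small_genome, [10, 20, 30, 45], names=["C>T", "G>A", "C>T", "G>A"])
    table = viz.rainfall_table(t, per_type=True)
    ct = table[table["mtype"] == "C>T"]["dist"]
    assert math.isnan(ct.iloc[0]) and ct.iloc[1] == 20
    # G>A labels normalize but stay distinct from C>T
    assert set(table["mtype"]) == {"C>T", "G>A"}


def test_rainfall_rejects_segment_track(small_genome):
    t = IndexedTrack.from_intervals(small_genome,
                                    [Interval("chr1", 0, 50)], SEGMENTS)
    with pytest.raises(ValueError, match="point"):
        viz.rainfall_table(t)


# -- binned frequency ------------------------------------------------------

def test_frequency_counts_per_bin(small_genome):
    t = points(small_genome, [5, 20, 50, 99, 80])
    table = viz.frequency_table(t, small_genome, bin_size=100)
    assert table["mutations"].iloc[0] == 5
    assert table["mutations"].iloc[1:].sum() == 0
    assert len(table) == 100  # 10 kb / 100 bp


def test_frequency_layer_sums_are_conserved(small_genome, rng):
    t = random_point_track(rng, small_genome, 200)
    ov = random_point_track(rng, small_genome, 77)
    table = viz.frequency_table(t, small_genome, 100, {"cpg": ov})
    assert table["mutations"].sum() == 200
    assert table["cpg"].sum() == 77


def test_frequency_segment_spanning_boundary_counts_in_both_bins(small_genome):
    t = IndexedTrack.empty(small_genome, POINTS)
    seg = IndexedTrack.from_intervals(small_genome,
                                      [Interval("chr1", 90, 110)], SEGMENTS)
    table = viz.frequency_table(t, small_genome, 100, {"exon": seg})
    assert table["exon"].iloc[0] == 1 and table["exon"].iloc[1] == 1
    assert table["exon"].sum() == 2


def test_frequency_bins_tile_chromosomes(genome):
    t = IndexedTrack.empty(genome, POINTS)
    table = viz.frequency_table(t, genome, 3000)
    # ceil(10000/3000)+ceil(8000/3000)+ceil(5000/3000) = 4+3+2
    assert len(table) == 9


# -- flanking composition --------------------------------------------------

def test_flanking_single_mutation():
    g = GenomeDef("s", (("chr1", 10),))
    fasta = {"chr1": "AAAAACGAAA"}
    t = points(g, [5], names=["C>T"])
    table = viz.flanking_composition(t, fasta, k=1)
    rows = {(r.offset, r.base): r.count for r in table.itertuples()}
    assert rows == {(-1, "A"): 1, (1, "G"): 1}
    assert set(table["mtype"]) == {"C>T"}


def test_flanking_clips_at_chromosome_edge():
    g = GenomeDef("s", (("chr1", 10),))
    t = points(g, [0], names=["C>T"])
    table = viz.flanking_composition(t, {"chr1": "CGAAAAAAAA"}, k=1)
    assert list(table["offset"]) == [1]


def test_flanking_lowercase_and_ambiguous_bases():
    g = GenomeDef("s", (("chr1", 5),))
    t = points(g, [2], names=["C>T"])
    table = viz.flanking_composition(t, {"chr1": "ancNt"}, k=1)
    rows = {(r.offset, r.base): r.count for r in table.itertuples()}
    assert rows == {(-1, "N"): 1, (1, "N"): 1}


def test_flanking_matches_string_slicing_oracle(small_genome, rng):
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    pos = rng.integers(0, 10_000, size=100)
    names = [("C>T", "G>A", "T>G")[i % 3] for i in range(100)]
    t = points(small_genome, list(pos), names=names)
    k = 2
    table = viz.flanking_composition(t, {"chr1": seq}, k=k)
    expect: dict[tuple, int] = {}
    for p, n in zip(pos, names):
        for off in (-2, -1, 1, 2):
            q = p + off
            if 0 <= q < 10_000:
                key = (n, off, seq[q])
                expect[key] = expect.get(key, 0) + 1
    got = {(r.mtype, r.offset, r.base): r.count for r in table.itertuples()}
    assert got == expect
    # per (mtype, offset) totals equal the unclipped mutation counts
    for (mtype, off), sub in table.groupby(["mtype", "offset"])["count"]:
        n_unclipped = sum(1 for p, n in zip(pos, names)
                          if n == mtype and 0 <= p + off < 10_000)
        assert sub.sum() == n_unclipped


def test_flanking_length_mismatch_rejected(small_genome):
    t = points(small_genome, [5], names=["C>T"])
    with pytest.raises(GenomeError, match="mismatch"):
        viz.flanking_composition(t, {"chr1": "ACGT"}, k=1)


def test_flanking_from_fasta_file(tmp_path):
    g = GenomeDef("s", (("chr1", 10),))
    fa = tmp_path / "r.fa"
    fa.write_text(">chr1\nAAAAACGAAA\n")
    t = points(g, [5], names=["C>T"])
    table = viz.flanking_composition(t, fa, k=1)
    assert table["count"].sum() == 2


# -- box summaries ---------------------------------------------------------

def test_boxplot_five_number_summary():
    df = pd.DataFrame({"g": ["a"] * 5, "v": [1, 2, 3, 4, 5]})
    s = viz.boxplot_summary(df, "v", "g")
    row = s.loc["a"]
    assert (row["min"], row["q1"], row["median"], row["q3"], row["max"], row["n"]) == \
        (1, 2, 3, 4, 5, 5)


def test_boxplot_single_value_group():
    df = pd.DataFrame({"g": ["a"], "v": [7.0]})
    row = viz.boxplot_summary(df, "v", "g").loc["a"]
    assert set(row[["min", "q1", "median", "q3", "max"]]) == {7.0}


def test_boxplot_quantiles_match_numpy_oracle(rng):
    vals = rng.normal(size=101)
    df = pd.DataFrame({"g": ["x"] * 101, "v": vals})
    row = viz.boxplot_summary(df, "v", "g").loc["x"]
    assert row["q1"] == pytest.approx(np.percentile(vals, 25))
    assert row["median"] == pytest.approx(np.median(vals))
    assert row["q3"] == pytest.approx(np.percentile(vals, 75))


def test_boxplot_from_suite_names_bad_entry():
    suite = parse_hgsuite("###uri\ttitle\tscore\tgrp\n"
                          "a\tA\t1.5\tx\nb\tB\toops\tx\n")
    with pytest.raises(HGSuiteError, match="'B'"):
        viz.boxplot_summary(suite, "score", "grp")
    good = suite.with_entries(suite.entries[:1])
    assert viz.boxplot_summary(good, "score", "grp").loc["x", "median"] == 1.5


# -- hierarchical clustering ----------------------------------------------

def test_identical_rows_merge_at_height_zero():
    m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                     index=["a", "b", "c"])
    res = viz.hierarchical_clustering(m)
    assert res.merges[0][2] == 0.0
    assert set(res.leaf_order) == {"a", "b", "c"}


def test_near_duplicates_merge_first():
    m = pd.DataFrame([[0.0], [0.1], [5.0]], index=["a", "b", "c"])
    res = viz.hierarchical_clustering(m, linkage="single")
    assert set(res.merges[0][:2]) == {0, 1}


def test_merge_heights_match_bruteforce_average_linkage(rng):
    from scipy.spatial.distance import pdist, squareform

    X = rng.normal(size=(6, 3))
    res = viz.hierarchical_clustering(pd.DataFrame(X), linkage="average")

    # brute-force agglomerative average linkage over point indices
    D = squareform(pdist(X))
    clusters: dict[int, list[int]] = {i: [i] for i in range(6)}
    next_id = 6
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[p, q] for p in clusters[i] for q in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    got = [h for _, _, h in res.merges]
    assert got == pytest.approx(heights)


def test_clustering_requires_two_usable_rows():
    m = pd.DataFrame([[1.0, np.nan], [2.0, 1.0]], index=["a", "b"])
    with pytest.raises(ValueError, match="2 rows"):
        viz.hierarchical_clustering(m)


def test_newick_is_parseable_and_heights_add_up():
    m = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"])
    res = viz.hierarchical_clustering(m, linkage="single")
    import dendropy
    tree = dendropy.Tree.get(data=res.newick, schema="newick")
    assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}
    # root height equals the last merge height: leaf-to-root distance
    root_height = res.merges[-1][2]
    for leaf in tree.leaf_node_iter():
        assert pytest.approx(root_height) == leaf.distance_from_root()
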