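"""Data cube construction, OLAP operations, and their algebraic laws."""

import math

import numpy as np
import pandas as pd
import pytest

from hgcube import data_cube as dc
from hgcube.hgsuite_format import parse_hgsuite
from hgcube.metadata_ops import filter_by_metadata
from hgcube.track_store import TrackLoader, union
from hgcube.track_stats import count_stat, group_coverage, relation_stat


@pytest.fixture(scope="module")
def count_cube(mouse_suite, mouse_loader):
    return dc.build_cube(mouse_suite, "count", mouse_loader)


def test_mouse_cube_shape_and_dims(count_cube):
    assert count_cube.schema.dim_names == ("genotype", "mutation_type")
    assert count_cube.schema.shape == (4, 4)


def test_cube_cells_match_filter_oracle(count_cube, mouse_suite, mouse_loader):
    """Every cell equals the statistic recomputed on the filtered suite."""
    for geno in count_cube.schema.categories("genotype"):
        sub = filter_by_metadata(mouse_suite, "genotype", geno)
        for mt in count_cube.schema.categories("mutation_type"):
            cell_suite = filter_by_metadata(sub, "mutation_type", mt)
            expect = count_stat([mouse_loader(e) for e in cell_suite.entries])
            assert count_cube[(geno, mt)] == expect
            assert set(count_cube.cell_provenance((geno, mt))) == set(cell_suite.titles)


def test_single_track_cube_equals_bare_statistic(mouse_suite, mouse_loader):
    one = mouse_suite.with_entries(mouse_suite.entries[:1]).with_hierarchy(("genotype",))
    cube = dc.build_cube(one, "coverage_bp", mouse_loader)
    assert cube.schema.shape == (1,)
    assert cube.values[0] == mouse_loader(one.entries[0]).coverage_bp()


def test_empty_hierarchy_is_an_error(mouse_suite, mouse_loader):
    with pytest.raises(dc.CubeError, match="hierarchy"):
        dc.build_cube(mouse_suite.with_hierarchy(()), "count", mouse_loader)


def test_provenance_partitions_suite(count_cube, mouse_suite):
    titles = [t for idx in np.ndindex(*count_cube.schema.shape)
              for t in count_cube.provenance[idx]]
    assert sorted(titles) == sorted(mouse_suite.titles)


def test_obs_exp_cube_averages_to_one(mouse_suite, mouse_loader):
    cube = dc.build_cube(mouse_suite, "obs_exp_ratio", mouse_loader)
    vals = cube.values[~np.isnan(cube.values)]
    assert vals.mean() == pytest.approx(1.0, abs=1e-12)


# -- relation cube ---------------------------------------------------------

@pytest.fixture(scope="module")
def relation_cube(cancer_suite, region_suite, cancer_loaders):
    lp, lr = cancer_loaders
    return dc.build_relation_cube(cancer_suite, region_suite, "overlap_count",
                                  lp, lr)


def test_relation_cube_dims(relation_cube):
    assert relation_cube.schema.dim_names == ("cancer_type", "patientID", "region")
    assert relation_cube.schema.shape == (3, 30, 2)


def test_relation_cells_match_pairwise_oracle(relation_cube, cancer_suite,
                                              region_suite, cancer_loaders):
    lp, lr = cancer_loaders
    sch = relation_cube.schema
    for ct in sch.categories("cancer_type"):
        sub = filter_by_metadata(cancer_suite, "cancer_type", ct)
        for pid in sch.categories("patientID"):
            cell = filter_by_metadata(sub, "patientID", pid)
            for region in sch.categories("region"):
                got = relation_cube[(ct, pid, region)]
                regs = filter_by_metadata(region_suite, "region", region)
                if len(cell) == 0:
                    assert math.isnan(got)  # patient not of this tumor type
                    continue
                a = union([lp(e) for e in cell.entries])
                b = union([lr(e) for e in regs.entries])
                assert got == relation_stat("overlap_count", a, b)


def test_relation_cube_disjoint_cell_is_zero(cancer_suite, region_suite,
                                             cancer_loaders, genome):
    lp, lr = cancer_loaders
    cube = dc.build_relation_cube(cancer_suite, region_suite, "overlap_bp",
                                  lp, lr)
    # coding/noncoding partition the genome: the two overlaps sum to the
    # patient coverage, and a track disjoint from one side scores 0 there
    sch = cube.schema
    for ct in sch.categories("cancer_type"):
        for pid in sch.categories("patientID"):
            vals = [cube[(ct, pid, r)] for r in ("coding", "noncoding")]
            if math.isnan(vals[0]):
                continue
            cell = filter_by_metadata(
                filter_by_metadata(cancer_suite, "cancer_type", ct),
                "patientID", pid)
            cov = union([lp(e) for e in cell.entries]).coverage_bp()
            assert vals[0] + vals[1] == cov


# -- OLAP operations -------------------------------------------------------

def test_slice_drops_dimension(count_cube):
    s = dc.slice_cube(count_cube, "genotype", "UNG")
    assert s.schema.dim_names == ("mutation_type",)
    for mt in s.schema.categories("mutation_type"):
        assert s[(mt,)] == count_cube[("UNG", mt)]


def test_slice_unknown_category_lists_valid_ones(count_cube):
    with pytest.raises(dc.CubeError, match="WT"):
        dc.slice_cube(count_cube, "genotype", "XX")


def test_dice_with_all_categories_is_identity(count_cube):
    d = dc.dice(count_cube, "genotype", count_cube.schema.categories("genotype"))
    assert d.schema == count_cube.schema
    assert np.array_equal(d.values, count_cube.values)


def test_slices_commute_across_distinct_dims(count_cube):
    a = dc.slice_cube(dc.slice_cube(count_cube, "genotype", "WT"),
                      "mutation_type", "C>T")
    b = dc.slice_cube(dc.slice_cube(count_cube, "mutation_type", "C>T"),
                      "genotype", "WT")
    assert a.values == b.values


def test_slice_and_aggregate_commute(count_cube):
    a = dc.slice_cube(dc.aggregate(count_cube, "mutation_type", "sum"),
                      "genotype", "UNG")
    b = dc.aggregate(dc.slice_cube(count_cube, "genotype", "UNG"),
                     "mutation_type", "sum")
    assert a.values == b.values


def test_aggregate_mean_example():
    schema = dc.CubeSchema(dims=(("d", ("x", "y")),), statistic="count")
    cube = dc.DataCube(schema, np.array([3.0, 5.0]))
    out = dc.aggregate(cube, "d", "mean")
    assert out.rank == 0 and float(out.values) == 4.0


def test_aggregate_skips_na_by_default():
    schema = dc.CubeSchema(dims=(("d", ("x", "y", "z")),), statistic="count")
    cube = dc.DataCube(schema, np.array([3.0, np.nan, 5.0]))
    assert float(dc.aggregate(cube, "d", "mean").values) == 4.0
    assert float(dc.aggregate(cube, "d", "count").values) == 2.0
    assert math.isnan(float(dc.aggregate(cube, "d", "mean", strict_na=True).values))
    all_na = dc.DataCube(schema, np.array([np.nan] * 3))
    assert math.isnan(float(dc.aggregate(all_na, "d", "sum").values))


def test_sum_aggregation_equals_concatenated_counts(mouse_suite, mouse_loader,
                                                    count_cube):
    """Additivity: summing the count cube over mutation types equals
    counting the per-genotype union track."""
    agg = dc.aggregate(count_cube, "mutation_type", "sum")
    for geno in agg.schema.categories("genotype"):
        sub = filter_by_metadata(mouse_suite, "genotype", geno)
        merged = union([mouse_loader(e) for e in sub.entries])
        assert agg[(geno,)] == merged.count_elements()


def test_pivot_labels_and_values(count_cube):
    table = dc.pivot(count_cube)
    assert list(table.index) == list(count_cube.schema.categories("genotype"))
    assert list(table.columns) == list(count_cube.schema.categories("mutation_type"))
    for i, g in enumerate(table.index):
        for j, m in enumerate(table.columns):
            assert table.iloc[i, j] == count_cube[(g, m)]


def test_transpose_involution(count_cube):
    t = dc.pivot(count_cube)
    pd.testing.assert_frame_equal(dc.transpose(dc.transpose(t)), t)


def test_pivot_requires_rank_two(count_cube):
    with pytest.raises(dc.CubeError, match="rank"):
        dc.pivot(dc.aggregate(count_cube, "mutation_type", "sum"))


def test_to_table_round_trip(count_cube, tmp_path):
    path = tmp_path / "t.tsv"
    dc.to_table(count_cube, path, "tsv")
    back = pd.read_csv(path, sep="\t", index_col=0)
    expect = dc.pivot(count_cube)
    assert np.allclose(back.to_numpy(), expect.to_numpy())


def test_to_table_rank_limits(count_cube, relation_cube, tmp_path):
    one_cell = dc.dice(dc.aggregate(count_cube, "mutation_type", "sum"),
                       "genotype", ["WT"])
    path = tmp_path / "one.tsv"
    dc.to_table(one_cell, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 2 and str(one_cell[("WT",)]) in lines[1]
    with pytest.raises(dc.CubeError, match="rank-3"):
        dc.to_table(relation_cube, tmp_path / "x.tsv")


def test_save_load_round_trip(relation_cube, tmp_path):
    dc.save_cube(relation_cube, tmp_path / "c")
    back = dc.load_cube(tmp_path / "c")
    assert back.schema == relation_cube.schema
    assert np.array_equal(back.values, relation_cube.values, equal_nan=True)
    assert all(back.provenance[i] == relation_cube.provenance[i]
               for i in np.ndindex(*back.schema.shape))
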