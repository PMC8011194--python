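import math

import numpy as np
import pytest

import sgsd
from sgsd.genotype_io import (
    MISSING,
    GenotypeFormatError,
    GenotypeTable,
    detect_duplicates,
    filter_min_typed_loci,
    grid_subsample,
    pairwise_distances,
    read_genotypes,
    relationship_coefficient,
    write_genotypes,
    write_structure,
)
from conftest import make_table

CSV_FIXTURE = """sample_id,x,y,group,locA_1,locA_2,locB_1,locB_2
a,0.0,0.0,north,101,103,140,140
b,1.5,2.0,north,101,101,142,144
c,3.0,4.0,,103,105,,
"""


def test_read_csv_fixture(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(CSV_FIXTURE)
    t = read_genotypes(p, "csv")
    assert t.n_samples == 3
    assert t.loci == ["locA", "locB"]
    assert t.sample_ids == ["a", "b", "c"]
    assert tuple(t.genotypes[0, 0]) == (101, 103)
    assert tuple(t.genotypes[2, 1]) == (MISSING, MISSING)
    assert t.groups[2] is None


@pytest.mark.parametrize("fmt", ["csv", "spagedi"])
def test_round_trip(tmp_path, tiny_table, fmt):
    p = tmp_path / f"t.{fmt}"
    write_genotypes(tiny_table, p, fmt)
    back = read_genotypes(p, fmt)
    assert back.equals(tiny_table)


def test_round_trip_geographic(tmp_path, tiny_table):
    geo = GenotypeTable(
        sample_ids=tiny_table.sample_ids,
        x=np.array([10.5, 11.0, 12.25]),
        y=np.array([-1.0, 0.5, 2.0]),
        groups=tiny_table.groups,
        loci=tiny_table.loci,
        genotypes=tiny_table.genotypes,
        coord_system="geographic",
    )
    for fmt in ("csv", "spagedi"):
        p = tmp_path / f"g.{fmt}"
        write_genotypes(geo, p, fmt)
        back = read_genotypes(p, fmt)
        assert back.coord_system == "geographic"
        assert back.equals(geo)


def test_half_missing_genotype_errors(tmp_path):
    bad = CSV_FIXTURE.replace("103,105,,", "103,105,105,")
    p = tmp_path / "bad.csv"
    p.write_text(bad)
    with pytest.raises(GenotypeFormatError, match="line 4.*'c'"):
        read_genotypes(p, "csv")


def test_duplicate_sample_id_errors(tmp_path):
    bad = CSV_FIXTURE.replace("b,1.5", "a,1.5")
    p = tmp_path / "bad.csv"
    p.write_text(bad)
    with pytest.raises(GenotypeFormatError, match="duplicate sample_id"):
        read_genotypes(p, "csv")


def test_malformed_row_names_line(tmp_path):
    bad = CSV_FIXTURE + "d,5.0,5.0,north,101\n"
    p = tmp_path / "bad.csv"
    p.write_text(bad)
    with pytest.raises(GenotypeFormatError, match="line 5"):
        read_genotypes(p, "csv")


def test_odd_allele_columns_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("sample_id,x,y,group,locA_1,locA_2,locB_1\na,0,0,,1,2,3\n")
    with pytest.raises(GenotypeFormatError, match="odd"):
        read_genotypes(p, "csv")


def test_structure_export(tmp_path, tiny_table):
    p = tmp_path / "t.str"
    write_structure(tiny_table, p)
    lines = p.read_text().strip().split("\n")
    assert len(lines) == 1 + 2 * tiny_table.n_samples  # header + 2 rows each
    last = lines[-1].split("\t")
    assert last[-1] == "-9"  # missing locus of sample c


# ------------------------------------------------------------------ QC rules


def _typed_fraction_table(n_typed, n_loci=10):
    row = [(5, 7)] * n_typed + [(MISSING, MISSING)] * (n_loci - n_typed)
    full = [(5, 7)] * n_loci
    return make_table([row, full])


def test_min_typed_boundary_removed():
    t = _typed_fraction_table(5)
    out = filter_min_typed_loci(t, 0.6)
    assert out.sample_ids == ["s1"]


def test_min_typed_boundary_retained():
    t = _typed_fraction_table(6)
    out = filter_min_typed_loci(t, 0.6)
    assert out.sample_ids == ["s0", "s1"]


def test_min_typed_tiny_fraction_keeps_all():
    t = _typed_fraction_table(1)
    assert filter_min_typed_loci(t, 0.01).n_samples == 2


def test_min_typed_empty_result_warns():
    t = _typed_fraction_table(0, n_loci=4)
    t = t.subset([0])
    with pytest.warns(UserWarning, match="removed every sample"):
        out = filter_min_typed_loci(t, 0.5)
    assert out.n_samples == 0


def test_detect_duplicates_identical():
    g = [(1, 2)] * 10
    t = make_table([g, g, [(1, 3)] * 10])
    pairs = detect_duplicates(t)
    assert len(pairs) == 1
    assert {pairs[0].sample_1, pairs[0].sample_2} == {"s0", "s1"}
    assert pairs[0].coefficient == 1.0


def test_detect_duplicates_near_clone_not_identical():
    g1 = [(1, 2)] * 10
    g2 = [(1, 2)] * 9 + [(1, 3)]
    t = make_table([g1, g2])
    assert detect_duplicates(t) == []
    all_pairs = detect_duplicates(t, return_all=True)
    assert len(all_pairs) == 1
    assert all_pairs[0].coefficient < 1.0


def test_detect_duplicates_insufficient_overlap():
    g1 = [(1, 2)] * 3 + [(MISSING, MISSING)] * 7
    g2 = [(1, 2)] * 3 + [(MISSING, MISSING)] * 7
    t = make_table([g1, g2])
    assert detect_duplicates(t, min_shared_loci=5) == []


def test_relationship_coefficient_values():
    g1 = np.array([[1, 2], [3, 3], [5, 6]])
    g2 = np.array([[1, 2], [3, 4], [7, 8]])
    coeff, n = relationship_coefficient(g1, g2)
    assert n == 3
    assert coeff == pytest.approx((1.0 + 0.5 + 0.0) / 3)


# ------------------------------------------------------------- grid subsample


def _geo_cluster_table(n, cell=0.01):
    geno = [[(1, 2)]] * n
    # all inside one cell
    xs = np.linspace(0.001, 0.009, n)
    ys = np.full(n, 0.005)
    t = make_table(geno, x=xs, y=ys, coord_system="geographic")
    return t


def test_grid_subsample_caps_cell():
    t = _geo_cluster_table(5)
    out = grid_subsample(t, 0.01, 3, seed=1)
    assert out.n_samples == 3


def test_grid_subsample_identity_when_sparse():
    t = _geo_cluster_table(3)
    out = grid_subsample(t, 0.01, 3, seed=1)
    assert out.equals(t)


def test_grid_subsample_deterministic_and_idempotent():
    t = _geo_cluster_table(9)
    a = grid_subsample(t, 0.01, 3, seed=42)
    b = grid_subsample(t, 0.01, 3, seed=42)
    assert a.equals(b)
    again = grid_subsample(a, 0.01, 3, seed=42)
    assert again.equals(a)


def test_grid_subsample_planar_errors():
    t = _geo_cluster_table(5)
    t.coord_system = "planar"
    with pytest.raises(ValueError, match="planar"):
        grid_subsample(t, 0.01, 3, seed=1)


def test_grid_subsample_requires_seed():
    t = _geo_cluster_table(5)
    with pytest.raises(ValueError, match="seed"):
        grid_subsample(t, 0.01, 3, seed=None)


# -------------------------------------------------------- allele frequencies


def test_allele_frequencies_counting():
    t = make_table([[(1, 1)], [(1, 2)]])
    f = sgsd.allele_frequencies(t)
    assert f.freqs[0] == {1: 0.75, 2: 0.25}
    assert f.n_copies[0] == 4


def test_allele_frequencies_monomorphic():
    t = make_table([[(7, 7)], [(7, 7)]])
    f = sgsd.allele_frequencies(t)
    assert f.freqs[0] == {7: 1.0}


def test_allele_frequencies_empty_group_errors(tiny_table):
    with pytest.raises(ValueError, match="selects no samples"):
        sgsd.allele_frequencies(tiny_table, group="nope")


def test_allele_frequencies_untyped_locus_flagged():
    t = make_table([[(1, 2), (MISSING, MISSING)], [(1, 1), (MISSING, MISSING)]])
    with pytest.warns(UserWarning, match="zero typed copies"):
        f = sgsd.allele_frequencies(t)
    assert f.untyped_loci == ["L2"]
    assert f.freqs[1] == {}


def test_union_frequencies_are_weighted_average(demes_table):
    f_all = sgsd.allele_frequencies(demes_table)
    f0 = sgsd.allele_frequencies(demes_table, group="deme0")
    f1 = sgsd.allele_frequencies(demes_table, group="deme1")
    for l in range(demes_table.n_loci):
        n0, n1 = f0.n_copies[l], f1.n_copies[l]
        for a, p in f_all.freqs[l].items():
            expect = (f0.freqs[l].get(a, 0) * n0 + f1.freqs[l].get(a, 0) * n1) / (
                n0 + n1
            )
            assert p == pytest.approx(expect, abs=1e-12)


# ------------------------------------------------------------------ distances


def test_haversine_one_degree_equator():
    t = make_table([[(1, 2)], [(1, 2)]], x=[0.0, 1.0], y=[0.0, 0.0],
                   coord_system="geographic")
    d = pairwise_distances(t)
    # closed form: R * 1 degree in radians
    assert d[0, 1] == pytest.approx(6_371_000 * math.radians(1.0), rel=1e-9)


def test_identical_coordinates_zero():
    t = make_table([[(1, 2)], [(1, 2)]], x=[5.0, 5.0], y=[5.0, 5.0],
                   coord_system="geographic")
    assert pairwise_distances(t)[0, 1] == 0.0


def test_planar_3_4_5():
    t = make_table([[(1, 2)], [(1, 2)]], x=[0.0, 3.0], y=[0.0, 4.0])
    assert pairwise_distances(t)[0, 1] == pytest.approx(5.0)


def test_missing_coordinate_names_sample():
    t = make_table([[(1, 2)], [(1, 2)]], x=[0.0, np.nan], y=[0.0, 0.0])
    with pytest.raises(ValueError, match="s1"):
        pairwise_distances(t)


# ------------------------------------------------------------------ invariants


def test_table_invariant_half_missing():
    with pytest.raises(GenotypeFormatError, match="fully missing"):
        make_table([[(1, MISSING)]])


def test_table_invariant_positive_alleles():
    with pytest.raises(GenotypeFormatError, match="positive"):
        make_table([[(0, 2)]])


def test_table_invariant_unique_loci():
    with pytest.raises(GenotypeFormatError, match="unique"):
        make_table([[(1, 2), (1, 2)]], loci=["A", "A"])


def test_unordered_allele_pair_equality(tmp_path):
    a = make_table([[(1, 2)]])
    b = make_table([[(2, 1)]])
    assert a.equals(b)
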