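import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from assemblyscope.community_data import (
    AsvTable,
    Phylogeny,
    TaxonomyTable,
    aggregate_by_rank,
    align_to_tree,
    read_asv_table,
    subsample_to_min_depth,
    to_relative,
    write_asv_table,
)


class TestAsvTable:
    def test_duplicate_taxon_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate taxon"):
            AsvTable(["a", "a"], ["s1"], np.ones((2, 1)))

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample"):
            AsvTable(["a", "b"], ["s", "s"], np.ones((2, 2)))

    def test_negative_entry_names_cell(self):
        with pytest.raises(ValueError, match="'t2'.*'s1'"):
            AsvTable(["t1", "t2"], ["s1"], np.array([[1], [-3]]))

    def test_counts_must_be_integral(self):
        with pytest.raises(ValueError, match="not integral"):
            AsvTable(["t1"], ["s1"], np.array([[1.5]]))

    def test_relative_mode_column_sums_checked(self):
        with pytest.raises(ValueError, match="sums to"):
            AsvTable(["t1", "t2"], ["s1"], np.array([[0.5], [0.4]]),
                     mode="relative")


class TestReadWrite:
    def test_tsv_parse(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "taxon_id\ts1\ts2\nt1\t5\t0\nt2\t3\t2\nt3\t0\t4\n"
        )
        table = read_asv_table(path, format="tsv")
        assert table.taxon_ids == ["t1", "t2", "t3"]
        assert table.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(table.sample_totals(), [8, 6])

    def test_tsv_negative_entry_names_cell(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("taxon_id\ts1\nt1\t-1\n")
        with pytest.raises(ValueError, match="'t1'.*'s1'"):
            read_asv_table(path)

    def test_tsv_round_trip(self, tmp_path, random_table):
        path = tmp_path / "t.tsv"
        write_asv_table(random_table, path, format="tsv")
        back = read_asv_table(path, format="tsv")
        assert back.taxon_ids == random_table.taxon_ids
        assert back.sample_ids == random_table.sample_ids
        np.testing.assert_array_equal(back.counts, random_table.counts)

    def test_biom_round_trip(self, tmp_path, random_table):
        path = tmp_path / "t.biom"
        write_asv_table(random_table, path, format="biom")
        back = read_asv_table(path, format="biom")
        assert back.taxon_ids == random_table.taxon_ids
        assert back.sample_ids == random_table.sample_ids
        np.testing.assert_array_equal(back.counts, random_table.counts)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_asv_table("does-not-exist.tsv")

    def test_transpose(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tt1\tt2\ns1\t5\t3\ns2\t0\t2\n")
        table = read_asv_table(path, transpose=True)
        assert table.taxon_ids == ["t1", "t2"]
        np.testing.assert_array_equal(table.counts, [[5, 0], [3, 2]])


class TestToRelative:
    def test_arithmetic(self, small_table):
        rel = to_relative(small_table)
        np.testing.assert_allclose(rel.counts[:, 0], [0.625, 0.375, 0.0])

    def test_double_normalisation_rejected(self, small_table):
        rel = to_relative(small_table)
        with pytest.raises(ValueError, match="already"):
            to_relative(rel)

    def test_column_sums_one(self, random_table):
        rel = to_relative(random_table)
        np.testing.assert_allclose(rel.counts.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_pattern_preserved(self, random_table):
        rel = to_relative(random_table)
        np.testing.assert_array_equal(
            rel.counts == 0, random_table.counts == 0
        )

    def test_empty_sample_listed(self):
        table = AsvTable(["a", "b"], ["s1", "s2"],
                         np.array([[1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="s2"):
            to_relative(table)


class TestSubsample:
    def test_totals_equal_minimum(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(10, size=(20, 3)).astype(float)
        counts[:, 0] *= 2
        table = AsvTable([f"t{i}" for i in range(20)],
                         ["a", "b", "c"], counts)
        sub = subsample_to_min_depth(table, seed=1)
        depth = table.sample_totals().min()
        np.testing.assert_array_equal(sub.sample_totals(),
                                      [depth, depth, depth])

    def test_sample_at_min_depth_unchanged(self, small_table):
        sub = subsample_to_min_depth(small_table, seed=3)
        # s2 already holds the minimum total (6)
        np.testing.assert_array_equal(sub.counts[:, 1],
                                      small_table.counts[:, 1])

    def test_deterministic_given_seed(self, random_table):
        a = subsample_to_min_depth(random_table, seed=7)
        b = subsample_to_min_depth(random_table, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_support_never_grows(self, random_table):
        sub = subsample_to_min_depth(random_table, seed=5)
        assert not np.any((random_table.counts == 0) & (sub.counts > 0))

    def test_zero_depth_rejected(self):
        table = AsvTable(["a"], ["s1", "s2"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="zero"):
            subsample_to_min_depth(table, seed=0)


class TestAlignToTree:
    def test_intersection(self, quartet_tree):
        table = AsvTable(["A", "B", "X"], ["s1"],
                         np.array([[1], [2], [3]]))
        sub, pruned = align_to_tree(table, quartet_tree)
        assert sub.taxon_ids == ["A", "B"]
        assert sorted(pruned.leaf_labels) == ["A", "B"]

    def test_identity(self, quartet_tree):
        table = AsvTable(["A", "B", "C", "D"], ["s1"],
                         np.ones((4, 1)))
        sub, pruned = align_to_tree(table, quartet_tree)
        assert sub is table
        assert pruned is quartet_tree

    def test_disjoint_rejected(self, quartet_tree):
        table = AsvTable(["X", "Y"], ["s1"], np.ones((2, 1)))
        with pytest.raises(ValueError, match="share no"):
            align_to_tree(table, quartet_tree)


class TestAggregate:
    def test_genus_sum(self, simple_taxonomy):
        table = AsvTable(["t1", "t2"], ["s1", "s2"],
                         np.array([[1, 2], [3, 4]]))
        agg = aggregate_by_rank(table, simple_taxonomy, "genus")
        assert agg.taxon_ids == ["GenA"]
        np.testing.assert_array_equal(agg.counts, [[4, 6]])

    def test_totals_conserved(self, random_table, simple_taxonomy):
        # taxa beyond t1..t3 are unassigned and pool together
        agg = aggregate_by_rank(random_table, simple_taxonomy, "genus")
        np.testing.assert_array_equal(
            agg.sample_totals(), random_table.sample_totals()
        )
        assert "Unassigned" in agg.taxon_ids

    def test_all_unassigned(self):
        table = AsvTable(["x", "y"], ["s1"], np.array([[2], [3]]))
        taxonomy = TaxonomyTable(lineages={})
        agg = aggregate_by_rank(table, taxonomy, "genus")
        assert agg.taxon_ids == ["Unassigned"]
        np.testing.assert_array_equal(agg.counts, [[5]])

    def test_unknown_rank_rejected(self, small_table, simple_taxonomy):
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate_by_rank(small_table, simple_taxonomy, "tribe")


@settings(max_examples=25, deadline=None)
@given(
    arrays(
        np.int64, (6, 4),
        elements=st.integers(min_value=0, max_value=50),
    ).filter(lambda m: (m.sum(axis=0) > 0).all())
)
def test_round_trip_and_relative_properties(counts):
    table = AsvTable(
        [f"t{i}" for i in range(6)], [f"s{j}" for j in range(4)],
        counts.astype(float),
    )
    rel = to_relative(table)
    np.testing.assert_allclose(rel.counts.sum(axis=0), 1.0, atol=1e-9)


class TestTaxonomy:
    def test_prefix_stripping(self):
        tax = TaxonomyTable.from_lineage_strings(
            {"x": "k__Bacteria; p__Proteo; c__; o__Rhizobiales"}
        )
        assert tax.value("x", "kingdom") == "Bacteria"
        assert tax.value("x", "phylum") == "Proteo"
        assert tax.value("x", "class") == "Unassigned"
        assert tax.value("x", "order") == "Rhizobiales"
        assert tax.value("x", "genus") == "Unassigned"

    def test_unknown_taxon_unassigned(self, simple_taxonomy):
        assert simple_taxonomy.value("nope", "genus") == "Unassigned"

    def test_tsv_round_trip(self, tmp_path, simple_taxonomy):
        path = tmp_path / "tax.tsv"
        simple_taxonomy.write_tsv(path)
        back = TaxonomyTable.read_tsv(path)
        for t in ("t1", "t2", "t3"):
            for rank in ("phylum", "genus"):
                assert back.value(t, rank) == simple_taxonomy.value(t, rank)


class TestPhylogeny:
    def test_patristic_quartet(self, quartet_tree):
        d = quartet_tree.patristic_matrix(order=["A", "B", "C", "D"])
        assert d[0, 1] == pytest.approx(2.0)
        assert d[0, 2] == pytest.approx(4.0)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_patristic_triangle_inequality(self, quartet_tree):
        d = quartet_tree.patristic_matrix()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_prune(self, quartet_tree):
        pruned = quartet_tree.prune_to(["A", "C"])
        assert sorted(pruned.leaf_labels) == ["A", "C"]
        d = pruned.patristic_matrix(order=["A", "C"])
        assert d[0, 1] == pytest.approx(4.0)

    def test_newick_round_trip(self, quartet_tree, tmp_path):
        path = tmp_path / "t.nwk"
        quartet_tree.write(path)
        back = Phylogeny.read(path)
        assert sorted(back.leaf_labels) == ["A", "B", "C", "D"]
        np.testing.assert_allclose(
            back.patristic_matrix(order=["A", "B", "C", "D"]),
            quartet_tree.patristic_matrix(order=["A", "B", "C", "D"]),
        )
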