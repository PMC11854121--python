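import numpy as np
import pandas as pd
import pytest

from assemblyscope.community_data import AsvTable, Phylogeny
from assemblyscope.phylo_null import (
    beta_mntd,
    beta_nti,
    group_masks,
    niche_values,
    phylo_signal_correlogram,
)
from assemblyscope.synthetic_data import (
    evolve_optima,
    make_scenario,
    simulate_tree,
)


def brute_force_bmntd(rel, present, d):
    """Literal double-loop betaMNTD used as an independent oracle."""
    n_taxa, n_samples = rel.shape
    out = np.zeros((n_samples, n_samples))
    for j in range(n_samples):
        for k in range(j + 1, n_samples):
            total = 0.0
            for focal, other in ((j, k), (k, j)):
                for i in range(n_taxa):
                    if rel[i, focal] <= 0:
                        continue
                    best = min(
                        d[i, i2] for i2 in range(n_taxa) if present[i2, other]
                    )
                    total += rel[i, focal] * best
            out[j, k] = 0.5 * total
    return out + out.T


class TestBetaMntd:
    def test_hand_value_disjoint_clades(self, quartet_tree):
        t = AsvTable(["A", "C", "D"], ["j", "k"],
                     np.array([[1.0, 0.0], [0.0, 0.5], [0.0, 0.5]]),
                     mode="relative")
        d = beta_mntd(t, quartet_tree)
        assert d.values[0, 1] == pytest.approx(4.0, abs=1e-12)

    def test_hand_value_shared_taxon(self, quartet_tree):
        t = AsvTable(["A", "B"], ["j", "k"],
                     np.array([[1.0, 0.5], [0.0, 0.5]]),
                     mode="relative")
        d = beta_mntd(t, quartet_tree)
        assert d.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_self_comparison_zero(self, quartet_tree):
        t = AsvTable(["A", "B", "C"], ["j", "k"],
                     np.array([[2, 2], [1, 1], [3, 3]]))
        d = beta_mntd(t, quartet_tree)
        assert np.all(np.diag(d.values) == 0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        tree = simulate_tree(12, seed=1)
        counts = rng.poisson(5, size=(12, 6)).astype(float)
        counts[0, :] += 1
        table = AsvTable(tree.leaf_labels,
                         [f"s{j}" for j in range(6)], counts)
        fast = beta_mntd(table, tree).values
        rel = counts / counts.sum(axis=0)
        d = tree.patristic_matrix(order=tree.leaf_labels)
        slow = brute_force_bmntd(rel, counts > 0, d)
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestBetaNti:
    def test_null_equals_literal_tip_relabelling(self, quartet_tree):
        # permuting the cached patristic matrix must match physically
        # relabelling the tips
        counts = np.array([[4.0, 0], [1, 1], [0, 3], [2, 2]])
        table = AsvTable(["A", "B", "C", "D"], ["j", "k"], counts)
        d = quartet_tree.patristic_matrix(order=["A", "B", "C", "D"])
        perm = np.array([2, 0, 3, 1])
        via_matrix = beta_mntd(table, quartet_tree).values  # sanity baseline
        from assemblyscope.phylo_null import _bmntd_from_distance

        rel = counts / counts.sum(axis=0)
        shuffled = _bmntd_from_distance(
            rel, counts > 0, d[np.ix_(perm, perm)]
        )
        # under the permutation, taxon row i now sits on tip perm[i]
        relabel_table = AsvTable(
            [["A", "B", "C", "D"][i] for i in perm], ["j", "k"], counts
        )
        literal = beta_mntd(relabel_table, quartet_tree).values
        np.testing.assert_allclose(shuffled, literal, atol=1e-12)
        assert via_matrix.shape == shuffled.shape

    def test_zscore_definition_and_symmetry(self):
        sc = make_scenario("neutral", seed=0, n_taxa=40, n_samples=6, N=500)
        res = beta_nti(sc.communities, sc.tree, n_null=99, seed=1)
        off = ~np.eye(len(res.ids), dtype=bool)
        expected = (res.beta_mntd_obs - res.null_mean) / res.null_sd
        np.testing.assert_allclose(
            res.beta_nti[off], expected[off], atol=1e-12
        )
        np.testing.assert_allclose(res.beta_nti[off],
                                   res.beta_nti.T[off], atol=1e-12)
        assert np.all(np.isnan(np.diag(res.beta_nti)))

    def test_branch_length_scale_invariance(self):
        sc = make_scenario("neutral", seed=2, n_taxa=30, n_samples=5, N=500)
        res1 = beta_nti(sc.communities, sc.tree, n_null=99, seed=5)
        scaled = Phylogeny.from_newick(sc.tree.to_newick())
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 3.7
        res2 = beta_nti(sc.communities, scaled, n_null=99, seed=5)
        off = ~np.eye(len(res1.ids), dtype=bool)
        np.testing.assert_allclose(
            res1.beta_nti[off], res2.beta_nti[off], atol=1e-9
        )

    def test_sample_relabel_invariance(self):
        sc = make_scenario("neutral", seed=3, n_taxa=30, n_samples=5, N=500)
        res1 = beta_nti(sc.communities, sc.tree, n_null=99, seed=7)
        renamed = AsvTable(
            sc.communities.taxon_ids,
            [f"renamed_{s}" for s in sc.communities.sample_ids],
            sc.communities.counts,
        )
        res2 = beta_nti(renamed, sc.tree, n_null=99, seed=7)
        off = ~np.eye(len(res1.ids), dtype=bool)
        np.testing.assert_allclose(res1.beta_nti[off], res2.beta_nti[off])

    def test_identical_samples_nonpositive(self, quartet_tree):
        counts = np.array([[3.0, 3], [2, 2], [1, 1], [4, 4]])
        table = AsvTable(["A", "B", "C", "D"], ["j", "k"], counts)
        res = beta_nti(table, quartet_tree, n_null=199, seed=0)
        assert res.beta_mntd_obs[0, 1] == 0.0
        val = res.beta_nti[0, 1]
        assert np.isnan(val) or val <= 0

    def test_zero_abundance_taxa_are_exact_noops(self):
        sc = make_scenario("neutral", seed=4, n_taxa=40, n_samples=6, N=500)
        table = sc.communities
        padded = AsvTable(
            table.taxon_ids + ["ghost1", "ghost2"],
            table.sample_ids,
            np.vstack([table.counts, np.zeros((2, table.n_samples))]),
        )
        # graft ghost tips onto a copy of the tree
        ghost_tree = Phylogeny.from_newick(
            sc.tree.to_newick().rstrip(";\n")
            .replace("(", "((ghost1:0.1,ghost2:0.1):0.5,(", 1) + ");"
        )
        res1 = beta_nti(table, sc.tree, n_null=99, seed=9)
        res2 = beta_nti(padded, ghost_tree, n_null=99, seed=9)
        off = ~np.eye(len(res1.ids), dtype=bool)
        np.testing.assert_allclose(
            res1.beta_nti[off], res2.beta_nti[off], atol=1e-12
        )

    def test_small_null_count_warns(self, quartet_tree):
        counts = np.array([[3.0, 1], [2, 2], [1, 3], [4, 4]])
        table = AsvTable(["A", "B", "C", "D"], ["j", "k"], counts)
        with pytest.warns(UserWarning, match="small"):
            beta_nti(table, quartet_tree, n_null=9, seed=0)

    def test_group_masks(self):
        within, between = group_masks(["a", "b", "c", "d"],
                                      ["g1", "g1", "g2", "g2"])
        assert within[0, 1] and not within[0, 2]
        assert between[0, 2] and not between[0, 1]
        assert not within[0, 0]


class TestNicheValues:
    def _table(self, rel):
        rel = np.asarray(rel, dtype=float)
        return AsvTable(
            [f"t{i}" for i in range(rel.shape[0])],
            [f"s{j}" for j in range(rel.shape[1])],
            rel, mode="relative",
        )

    def test_point_mass(self):
        t = self._table([[1.0, 0.0], [0.0, 1.0]])
        niche = niche_values(t, np.array([2.0, 10.0]))
        assert niche["t0"] == pytest.approx(2.0)

    def test_midpoint(self):
        t = self._table([[0.5, 0.5], [0.5, 0.5]])
        niche = niche_values(t, np.array([2.0, 4.0]))
        assert niche["t0"] == pytest.approx(3.0)

    def test_weighted(self):
        t = self._table([[0.75, 0.25], [0.25, 0.75]])
        niche = niche_values(t, np.array([0.0, 4.0]))
        assert niche["t0"] == pytest.approx(1.0)

    def test_absent_taxon_missing(self):
        t = AsvTable(["a", "b"], ["s1", "s2"],
                     np.array([[2, 3], [0, 0]]))
        niche = niche_values(t, np.array([1.0, 2.0]))
        assert np.isnan(niche["b"])


class TestCorrelogram:
    def test_brownian_positive_control(self):
        hits = 0
        for seed in range(10):
            tree = simulate_tree(50, seed=seed)
            niche = evolve_optima(tree, sigma_bm=1.0, seed=seed + 100)
            corr = phylo_signal_correlogram(
                tree, niche, n_classes=3, n_perm=199, seed=seed
            )
            if corr.r[0] > 0 and corr.p[0] < 0.05:
                hits += 1
        assert hits >= 8

    def test_permuted_niche_null_calibration(self):
        rng = np.random.default_rng(0)
        pvals = []
        for seed in range(15):
            tree = simulate_tree(40, seed=seed + 50)
            niche = evolve_optima(tree, sigma_bm=1.0, seed=seed + 250)
            shuffled = pd.Series(
                rng.permutation(niche.to_numpy()), index=niche.index
            )
            corr = phylo_signal_correlogram(
                tree, shuffled, n_classes=3, n_perm=99, seed=seed
            )
            pvals.append(corr.p[0])
        assert 0.2 <= np.mean(pvals) <= 0.8

    def test_constant_niche_missing(self):
        tree = simulate_tree(25, seed=3)
        niche = pd.Series(1.0, index=tree.leaf_labels)
        corr = phylo_signal_correlogram(tree, niche, n_classes=2,
                                        n_perm=49, seed=0)
        assert np.all(np.isnan(corr.r))

    def test_too_few_taxa_rejected(self):
        tree = simulate_tree(10, seed=4)
        niche = pd.Series(np.arange(10.0), index=tree.leaf_labels)
        with pytest.raises(ValueError, match="20 taxa"):
            phylo_signal_correlogram(tree, niche, n_classes=2)

    def test_classes_partition_pairs(self):
        tree = simulate_tree(30, seed=5)
        niche = evolve_optima(tree, sigma_bm=1.0, seed=6)
        corr = phylo_signal_correlogram(tree, niche, n_classes=4,
                                        n_perm=49, seed=0)
        assert corr.n_pairs.sum() == 30 * 29 // 2
        assert np.all(corr.n_pairs > 0)
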