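"""Allele-sharing distance, neighbor joining, bootstrap support, PCA."""

import numpy as np
import pytest

from popscan.structure import (
    TreeNode, allele_sharing_distance, bootstrap_support, genotype_pca, nj_tree,
)

from conftest import build_gm


def random_additive_matrix(rng, n_taxa):
    """Distances induced by a random binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for nd in nodes:
        nd.length = rng.uniform(0.1, 1.0)
    pool = list(nodes)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), 2, replace=False))
        a, b = pool[j], pool[i]
        parent = TreeNode(length=rng.uniform(0.1, 1.0), children=[b, a])
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = TreeNode(children=pool)
    names, dm = root.tip_distances()
    order = np.argsort([int(nm[1:]) for nm in names])
    return [names[k] for k in order], dm[np.ix_(order, order)], root


class TestAlleleSharingDistance:
    def test_identical_samples_zero(self):
        dos = np.tile([0, 1, 2, 1], (2, 1))
        _, dm = allele_sharing_distance(build_gm(dos, ["P", "P"]))
        assert dm[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        dos = np.array([[0, 2, 0], [2, 0, 2]])
        _, dm = allele_sharing_distance(build_gm(dos, ["P", "P"]))
        assert dm[0, 1] == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(31)
        dos = rng.choice([0, 1, 2, -1], size=(5, 50), p=[0.3, 0.3, 0.3, 0.1])
        gm = build_gm(dos, ["P"] * 5)
        names, dm = allele_sharing_distance(gm)
        for i in range(5):
            for j in range(5):
                num, den = 0.0, 0
                for l in range(50):
                    if dos[i, l] >= 0 and dos[j, l] >= 0:
                        num += 1 - (2 - abs(dos[i, l] - dos[j, l])) / 2
                        den += 1
                assert dm[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_no_shared_loci_is_hard_error(self):
        dos = np.array([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="s0.*s1"):
            allele_sharing_distance(build_gm(dos, ["P", "P"]))


class TestNJTree:
    def test_three_taxa_closed_form(self):
        names = ["a", "b", "c"]
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(names, d)
        lengths = {ch.name: ch.length for ch in tree.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            n = int(rng.integers(5, 11))
            names, dm, _ = random_additive_matrix(rng, n)
            tree = nj_tree(names, dm)
            got_names, got = tree.tip_distances()
            order = [got_names.index(nm) for nm in names]
            assert np.allclose(got[np.ix_(order, order)], dm, atol=1e-9)

    def test_ultrametric_cherries_joined_first(self):
        # two clear cherries (a,b) and (c,d)
        d = np.array([
            [0.0, 0.2, 1.0, 1.0],
            [0.2, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.2],
            [1.0, 1.0, 0.2, 0.0],
        ])
        tree = nj_tree(["a", "b", "c", "d"], d)
        parts = tree.bipartitions()
        assert frozenset({"a", "b"}) in parts or frozenset({"c", "d"}) in parts

    def test_non_symmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.1, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(["a", "b", "c"], d)

    def test_matches_skbio_on_additive_matrix(self):
        # independent implementation cross-check
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(33)
        names, dm, _ = random_additive_matrix(rng, 8)
        ours = nj_tree(names, dm)
        theirs = skbio_nj(DistanceMatrix(dm, ids=names))
        ours_parts = ours.bipartitions()
        theirs_parts = set()
        all_names = frozenset(names)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            side = below if len(below) <= len(all_names - below) else all_names - below
            if 2 <= len(side) <= len(all_names) - 2:
                if len(side) * 2 == len(all_names):
                    side = min(side, all_names - side, key=lambda s: sorted(s))
                theirs_parts.add(side)
        assert ours_parts == theirs_parts

    def test_newick_round_trip_parses(self):
        rng = np.random.default_rng(34)
        names, dm, _ = random_additive_matrix(rng, 6)
        nwk = nj_tree(names, dm).newick()
        import io
        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(names)


class TestBootstrap:
    def make_structured_gm(self, seed=0, f=0.2):
        from popscan.sim import SimConfig, simulate_populations
        cfg = SimConfig(samples_per_pop=[6, 6], scaffolds=[("s1", 500_000)],
                        snp_density=1e-3, target_F=f, seed=seed)
        gm, _ = simulate_populations(cfg)
        return gm

    def test_population_split_strongly_supported(self):
        gm = self.make_structured_gm()
        tree = bootstrap_support(gm, n_reps=100, seed=1)
        pop1 = frozenset(s for s in gm.samples if gm.pops[s] == "pop1")
        support = {}

        def collect(node):
            if node is not tree and not node.is_leaf:
                below = frozenset(node.leaf_names())
                support[below] = node.support
            for ch in node.children:
                collect(ch)

        collect(tree)
        split = [v for k, v in support.items() if k == pop1 or
                 k == frozenset(gm.samples) - pop1]
        assert split and max(split) >= 95

    def test_single_replicate_support_binary(self):
        gm = self.make_structured_gm(seed=3)
        tree = bootstrap_support(gm, n_reps=1, seed=5)
        vals = []

        def collect(node):
            if node.support is not None:
                vals.append(node.support)
            for ch in node.children:
                collect(ch)

        collect(tree)
        assert vals and set(vals) <= {0.0, 100.0}

    def test_reproducible_given_seed(self):
        gm = self.make_structured_gm(seed=4)
        t1 = bootstrap_support(gm, n_reps=20, seed=9).newick()
        t2 = bootstrap_support(gm, n_reps=20, seed=9).newick()
        assert t1 == t2

    def test_invalid_rep_count(self):
        gm = self.make_structured_gm(seed=4)
        with pytest.raises(ValueError):
            bootstrap_support(gm, n_reps=0, seed=1)


class TestPCA:
    def test_two_samples_rank_one(self):
        rng = np.random.default_rng(41)
        dos = rng.integers(0, 3, size=(2, 60))
        res = genotype_pca(build_gm(dos, ["P", "Q"]), k=2)
        assert res.eigenvalues[0] > 1e-8
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(42)
        base = rng.integers(0, 3, size=(4, 80))
        dos = np.vstack([base, base])
        res = genotype_pca(build_gm(dos, ["P"] * 8), k=3)
        assert np.allclose(res.coords[:4], res.coords[4:], atol=1e-8)

    def test_eigenvalues_descending_and_variance_sums(self):
        rng = np.random.default_rng(43)
        dos = rng.integers(0, 3, size=(10, 200))
        gm = build_gm(dos, ["P"] * 10)
        res = genotype_pca(gm, k=9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)
        # total variance equals the sum of all eigenvalues of the normalised matrix
        D = dos.astype(float)
        p = D.sum(0) / (2 * 10)
        keep = (p > 0) & (p < 1)
        M = (D[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        total = np.linalg.norm(M) ** 2 / M.shape[1]
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_coordinates_centered(self):
        rng = np.random.default_rng(44)
        dos = rng.integers(0, 3, size=(12, 150))
        res = genotype_pca(build_gm(dos, ["P"] * 12), k=5)
        assert np.allclose(res.coords.sum(axis=0), 0.0, atol=1e-8)

    def test_k_truncated_with_warning(self, caplog):
        rng = np.random.default_rng(45)
        dos = rng.integers(0, 3, size=(4, 50))
        with caplog.at_level("WARNING"):
            res = genotype_pca(build_gm(dos, ["P"] * 4), k=10)
        assert res.coords.shape[1] == 3

    def test_pc1_separates_differentiated_populations(self):
        from popscan.sim import SimConfig, simulate_populations
        cfg = SimConfig(samples_per_pop=[10, 10], scaffolds=[("s1", 1_000_000)],
                        snp_density=1e-3, target_F=0.1, seed=6)
        gm, _ = simulate_populations(cfg)
        res = genotype_pca(gm, k=2)
        pc1 = res.coords[:, 0]
        g1 = pc1[:10]
        g2 = pc1[10:]
        within_sd = max(g1.std(), g2.std())
        assert abs(g1.mean() - g2.mean()) > 3 * within_sd
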