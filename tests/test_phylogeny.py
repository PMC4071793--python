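"""Poisson distances, neighbor-joining, bootstrap supports, Newick I/O."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from funcsite.conservation import Alignment
from funcsite.phylogeny import (DistanceMatrix, bootstrap_support,
                                neighbor_joining, pairwise_distance_matrix,
                                read_newick, write_newick)
from funcsite.synthetic import (random_additive_tree, simulate_msa,
                                tree_distance_matrix)


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson-Foulds via dendropy on a shared taxon namespace."""
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(tree_a), schema="newick",
                          taxon_namespace=ns)
    b = dendropy.Tree.get(data=write_newick(tree_b), schema="newick",
                          taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


class TestDistances:
    def test_identical_sequences(self):
        msa = Alignment(ids=list("abc"), rows={k: "ACDE" for k in "abc"})
        dm = pairwise_distance_matrix(msa)
        assert np.allclose(dm.d, 0.0)

    def test_poisson_closed_form_half(self):
        msa = Alignment(ids=list("abc"),
                        rows={"a": "AAAA", "b": "AACC", "c": "AAAA"})
        dm = pairwise_distance_matrix(msa)
        assert dm.d[0, 1] == pytest.approx(-np.log(0.5), abs=1e-4)

    def test_pairwise_deletion_hand_example(self):
        msa = Alignment(ids=list("abc"),
                        rows={"a": "ACDX", "b": "ACEY", "c": "ACDF"})
        dm = pairwise_distance_matrix(msa, deletion="pairwise")
        # a vs b: X ambiguous -> 3 usable, 1 mismatch, d = -ln(2/3)
        assert dm.d[0, 1] == pytest.approx(0.4055, abs=1e-4)

    def test_complete_deletion_drops_column_for_all(self):
        msa = Alignment(ids=list("abc"),
                        rows={"a": "ACDX", "b": "ACEY", "c": "ACDF"})
        dm = pairwise_distance_matrix(msa, deletion="complete")
        # column 4 ambiguous in a -> removed for every pair: b vs c usable 3
        assert dm.d[1, 2] == pytest.approx(-np.log(2 / 3), abs=1e-6)

    def test_saturated_pair_errors(self):
        msa = Alignment(ids=list("abc"),
                        rows={"a": "AAAA", "b": "CCCC", "c": "AAAA"})
        with pytest.raises(ValueError, match="Poisson"):
            pairwise_distance_matrix(msa)

    def test_no_usable_sites_errors(self):
        msa = Alignment(ids=list("abc"),
                        rows={"a": "XX", "b": "AA", "c": "AA"})
        with pytest.raises(ValueError, match="usable"):
            pairwise_distance_matrix(msa)

    def test_poisson_correction_properties(self):
        # d >= p, strictly increasing and convex in p
        ps = np.linspace(0.05, 0.9, 30)
        ds = -np.log(1 - ps)
        assert np.all(ds >= ps)
        assert np.all(np.diff(ds) > 0)
        assert np.all(np.diff(ds, 2) > 0)


def _lsq_tree_fit_oracle(ids, d):
    """Brute force: best least-squares additive fit over the 3 unrooted
    4-taxon topologies, via the four-point condition branch solve."""
    best = None
    for (i, j, k, l) in [(0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)]:
        # internal branch from the four-point condition
        internal = 0.5 * (0.5 * (d[i, k] + d[i, l] + d[j, k] + d[j, l])
                          - d[i, j] - d[k, l])
        if best is None or internal > best[0]:
            best = (internal, frozenset({ids[i], ids[j]}))
    return best[1]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        # oracle: best-fitting quartet topology by the four-point condition
        assert _lsq_tree_fit_oracle(ids, d) == frozenset({"A", "B"})
        newick = write_newick(tree)
        assert ("(A:" in newick and "B:" in newick)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for x, y in itertools.combinations(ids, 2):
            assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(
                d[ids.index(x), ids.index(y)], abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_random_additive_topology(self, seed):
        n = 5 + seed % 6  # 5..10 taxa
        tree = random_additive_tree(n, seed=seed)
        ids, d = tree_distance_matrix(tree)
        recovered = neighbor_joining(DistanceMatrix(ids, d))
        assert rf_distance(tree, recovered) == 0

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        tree = random_additive_tree(7, seed=42)
        ids, d = tree_distance_matrix(tree)
        # perturb away from additivity so the test is not trivially exact
        rng = np.random.default_rng(1)
        noise = rng.normal(scale=0.01, size=d.shape)
        noise = np.triu(noise, 1)
        d_noisy = d + noise + noise.T
        ours = neighbor_joining(DistanceMatrix(ids, d_noisy))
        ref = skbio_nj(skbio.DistanceMatrix(d_noisy, ids))
        ref_tree = dendropy.Tree.get(data=str(ref), schema="newick")
        assert rf_distance(ours, ref_tree) == 0

    def test_nonnegative_branch_lengths(self):
        rng = np.random.default_rng(9)
        n = 6
        d = rng.uniform(0.2, 1.5, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = neighbor_joining(DistanceMatrix([f"T{i}" for i in range(n)], d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d)


class TestBootstrap:
    def _two_block_alignment(self):
        # identical rows within each block: every variable column supports
        # the a|b split; the shared GGGG suffix keeps cross-block p below 1
        rows = {"a1": "AAAAAAAAAAGGGG", "a2": "AAAAAAAAAAGGGG",
                "b1": "WWWWWWWWWWGGGG", "b2": "WWWWWWWWWWGGGG"}
        return Alignment(ids=sorted(rows), rows=rows)

    def test_fully_supported_split(self):
        aln = self._two_block_alignment()
        tree = bootstrap_support(aln, n_reps=50, seed=0)
        supports = [float(n.label) for n in tree.preorder_node_iter()
                    if n.label is not None]
        assert supports and max(supports) == pytest.approx(1.0)

    def test_seed_determinism(self):
        aln = self._two_block_alignment()
        t1 = write_newick(bootstrap_support(aln, n_reps=30, seed=7))
        t2 = write_newick(bootstrap_support(aln, n_reps=30, seed=7))
        assert t1 == t2

    def test_taxon_order_invariance(self):
        tree = random_additive_tree(6, seed=11)
        aln, _ = simulate_msa(tree, 400, rate=1.0, seed=11)
        perm_ids = list(reversed(aln.ids))
        aln_perm = Alignment(ids=perm_ids, rows=dict(aln.rows))
        s1 = _support_map(bootstrap_support(aln, n_reps=40, seed=3))
        s2 = _support_map(bootstrap_support(aln_perm, n_reps=40, seed=3))
        assert set(s1) == set(s2)

    def test_planted_long_branch_support(self):
        tree = random_additive_tree(6, seed=2, min_internal=0.5)
        aln, _ = simulate_msa(tree, 500, rate=1.0, seed=2)
        bt = bootstrap_support(aln, n_reps=100, seed=5)
        supports = [float(n.label) for n in bt.preorder_node_iter()
                    if n.label is not None]
        assert max(supports) >= 0.95

    def test_bad_rep_count(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._two_block_alignment(), n_reps=0)


def _support_map(tree):
    out = {}
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    for node in tree.preorder_node_iter():
        if node.label is None or node.is_leaf():
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = min(leaves, all_taxa - leaves, key=lambda s: (len(s), sorted(s)))
        out[side] = float(node.label)
    return out


class TestNewick:
    def test_three_taxon_shape(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        text = write_newick(neighbor_joining(DistanceMatrix(["A", "B", "C"], d)))
        assert text.startswith("(") and text.rstrip().endswith(";")
        assert "A:1" in text

    def test_round_trip_topology_and_lengths(self):
        tree = random_additive_tree(8, seed=4)
        ids, d = tree_distance_matrix(tree)
        nj = neighbor_joining(DistanceMatrix(ids, d))
        back = read_newick(write_newick(nj))
        assert rf_distance(nj, back) == 0
        orig = sorted(e.length for e in nj.preorder_edge_iter()
                      if e.length is not None)
        rt = sorted(e.length for e in back.preorder_edge_iter()
                    if e.length is not None)
        assert np.allclose(orig, rt, rtol=1e-5)

    def test_supports_appear_after_parens(self):
        rows = {"a1": "AAAAAAAACCGGGG", "a2": "AAAAAAAADDGGGG",
                "b1": "WWWWWWWWEEGGGG", "b2": "WWWWWWWWFFGGGG"}
        aln = Alignment(ids=sorted(rows), rows=rows)
        text = write_newick(bootstrap_support(aln, n_reps=20, seed=1))
        assert ")1.000:" in text or ")0." in text
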