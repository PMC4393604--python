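"""p-distance, neighbor joining (with exhaustive oracle), bootstrap."""

import itertools

import dendropy
import numpy as np
import pytest

from bzipkit import phylogeny as phy
from bzipkit.io import write_newick


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_unrooted_topologies(leaves):
    """All unrooted binary topologies, as edge lists over leaf/internal names."""
    topologies = [[("i0", leaves[0]), ("i0", leaves[1]), ("i0", leaves[2])]]
    for idx, leaf in enumerate(leaves[3:], start=1):
        new = []
        for edges in topologies:
            for k in range(len(edges)):
                u, v = edges[k]
                w = f"i{idx}_{k}"
                grown = edges[:k] + edges[k + 1 :] + [(u, w), (w, v), (w, leaf)]
                new.append(grown)
        topologies = new
    return topologies


def topology_bipartitions(edges, leaves):
    """Non-trivial leaf bipartitions (frozensets of the smaller side)."""
    import networkx as nx

    g = nx.Graph(edges)
    splits = set()
    for u, v in edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(h, u) if n in set(leaves)}
        if 2 <= len(side) <= len(leaves) - 2:
            other = set(leaves) - side
            splits.add(frozenset(min(side, other, key=sorted)))
    return splits


def ols_fit(edges, leaves, dist):
    """Least-squares branch lengths for a fixed topology; returns residual."""
    import networkx as nx

    g = nx.Graph()
    for k, (u, v) in enumerate(edges):
        g.add_edge(u, v, index=k)
    rows, targets = [], []
    for i, j in itertools.combinations(range(len(leaves)), 2):
        path = nx.shortest_path(g, leaves[i], leaves[j])
        row = np.zeros(len(edges))
        for u, v in zip(path, path[1:]):
            row[g[u][v]["index"]] = 1.0
        rows.append(row)
        targets.append(dist[i, j])
    A = np.array(rows)
    x, *_ = np.linalg.lstsq(A, np.array(targets), rcond=None)
    residual = float(np.linalg.norm(A @ x - targets))
    return residual, float(x.sum())


def random_additive_matrix(leaves, rng):
    """Distance matrix generated from a random tree with known topology."""
    topologies = enumerate_unrooted_topologies(leaves)
    edges = topologies[int(rng.integers(0, len(topologies)))]
    import networkx as nx

    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=float(rng.uniform(0.05, 1.0)))
    n = len(leaves)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(
            g, leaves[i], leaves[j], weight="weight"
        )
    return d, topology_bipartitions(edges, leaves)


def tree_bipartitions(tree, leaves):
    out = set()
    tree.encode_bipartitions()
    leafset = set(leaves)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        side = {
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        }
        if 2 <= len(side) <= len(leafset) - 2:
            other = leafset - side
            out.add(frozenset(min(side, other, key=sorted)))
    return out


def tree_path_distances(tree, leaves):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaves)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(taxa[leaves[i]], taxa[leaves[j]])
    return d


# ---------------------------------------------------------------------------
# p-distance


class TestPDistance:
    def test_single_mismatch_quarter(self):
        d = phy.p_distance(phy.Alignment(["a", "b"], ["AAAA", "AATA"]))
        assert d.matrix[0, 1] == 0.25

    def test_pairwise_deletion_of_gaps(self):
        d = phy.p_distance(phy.Alignment(["a", "b"], ["A-AA", "AGAA"]))
        assert d.matrix[0, 1] == 0.0

    def test_x_sites_excluded(self):
        d = phy.p_distance(phy.Alignment(["a", "b"], ["AXTA", "AGAA"]))
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_identical_rows_zero(self):
        d = phy.p_distance(phy.Alignment(["a", "b"], ["MKNL", "MKNL"]))
        assert d.matrix[0, 1] == 0.0

    def test_incomparable_pair_names_both(self):
        with pytest.raises(phy.IncomparablePairError, match="'a'.*'b'"):
            phy.p_distance(phy.Alignment(["a", "b"], ["A---", "-GGG"]))


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = phy.nj_tree(phy.DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_exact_recovery(self, rng):
        leaves = ["A", "B", "C", "D"]
        for _ in range(10):
            d, true_splits = random_additive_matrix(leaves, rng)
            tree = phy.nj_tree(phy.DistanceMatrix(leaves, d))
            assert tree_bipartitions(tree, leaves) == true_splits
            assert np.allclose(tree_path_distances(tree, leaves), d, atol=1e-9)

    def test_five_taxon_matches_exhaustive_oracle(self, rng):
        leaves = list("ABCDE")
        topologies = enumerate_unrooted_topologies(leaves)
        assert len(topologies) == 15
        for _ in range(5):
            d, true_splits = random_additive_matrix(leaves, rng)
            # oracle: the unique zero-residual OLS topology of the 15
            fits = [
                (ols_fit(edges, leaves, d), topology_bipartitions(edges, leaves))
                for edges in topologies
            ]
            best = min(fits, key=lambda t: (round(t[0][0], 9), t[0][1]))
            assert best[1] == true_splits  # oracle agrees with the generator
            tree = phy.nj_tree(phy.DistanceMatrix(leaves, d))
            assert tree_bipartitions(tree, leaves) == best[1]
            assert np.allclose(tree_path_distances(tree, leaves), d, atol=1e-9)

    def test_bipartition_count_n_minus_3(self, rng):
        for n in (4, 6, 9):
            leaves = [f"t{i}" for i in range(n)]
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = phy.nj_tree(phy.DistanceMatrix(leaves, m))
            assert len(tree_bipartitions(tree, leaves)) == n - 3

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            phy.DistanceMatrix(["a", "b", "c"], m)

    def test_matches_scikit_bio_topology(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        leaves = list("ABCDEFG")
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        mine = phy.nj_tree(phy.DistanceMatrix(leaves, m))
        sk = dendropy.Tree.get(
            data=str(sknj(SkDM(m, leaves))),
            schema="newick",
            taxon_namespace=mine.taxon_namespace,
        )
        assert tree_bipartitions(mine, leaves) == tree_bipartitions(sk, leaves)


# ---------------------------------------------------------------------------
# bootstrap


def _block_alignment():
    """Alignment whose duplicated blocks force one overwhelming split."""
    ids = [f"t{i}" for i in range(6)]
    block_a = "AAAAAAAAAA"
    block_b = "CCCCCCCCCC"
    noise = ["MK", "MR", "MN", "MQ", "MS", "MT"]
    rows = [
        (block_a if i < 3 else block_b) * 4 + noise[i] for i in range(6)
    ]
    return phy.Alignment(ids, rows)


class TestBootstrap:
    def test_forced_split_support_100(self):
        tree, used = phy.bootstrap(_block_alignment(), replicates=50, seed=3)
        assert used == 50
        supports = [
            e.bootstrap_support
            for e in tree.preorder_edge_iter()
            if hasattr(e, "bootstrap_support")
        ]
        assert max(supports) == 100.0

    def test_single_replicate_supports_binary(self):
        tree, used = phy.bootstrap(_block_alignment(), replicates=1, seed=4)
        supports = {
            e.bootstrap_support
            for e in tree.preorder_edge_iter()
            if hasattr(e, "bootstrap_support")
        }
        assert supports <= {0.0, 100.0}

    def test_determinism_byte_identical_newick(self):
        a = write_newick(phy.bootstrap(_block_alignment(), replicates=20, seed=5)[0])
        b = write_newick(phy.bootstrap(_block_alignment(), replicates=20, seed=5)[0])
        assert a == b

    def test_support_stability_across_seeds(self, rng):
        # 10-taxon synthetic alignment: supports agree within 5 points
        # between two seeds at 1000 replicates
        ids = [f"t{i}" for i in range(10)]
        archetype = rng.integers(0, 4, size=80)
        rows = []
        for i in range(10):
            chars = archetype.copy()
            flip = rng.random(80) < 0.15 * (1 + i % 3)
            chars[flip] = (chars[flip] + 1 + rng.integers(0, 3, flip.sum())) % 20
            rows.append("".join("ACDEFGHIKLMNPQRSTVWY"[c] for c in chars))
        aln = phy.Alignment(ids, rows)
        t1, _ = phy.bootstrap(aln, replicates=1000, seed=11)
        t2, _ = phy.bootstrap(aln, replicates=1000, seed=12)
        s1 = sorted(
            e.bootstrap_support for e in t1.preorder_edge_iter()
            if hasattr(e, "bootstrap_support")
        )
        s2 = sorted(
            e.bootstrap_support for e in t2.preorder_edge_iter()
            if hasattr(e, "bootstrap_support")
        )
        assert len(s1) == len(s2)
        assert all(abs(x - y) <= 5 for x, y in zip(s1, s2))
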