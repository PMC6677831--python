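"""Poisson distances, Neighbor-Joining, Newick round trips."""

from itertools import combinations

import numpy as np
import pytest
import dendropy

from oligodeer.phylo import (
    AlignedSequences,
    complete_deletion,
    distance_matrix,
    neighbor_joining,
    poisson_distance,
    read_newick,
    total_branch_length,
    tree_path_distances,
    write_newick,
)
from oligodeer.synthetic_data import random_additive_tree


def additive_matrix(tree):
    """Path-length matrix and leaf order from a dendropy tree."""
    names = sorted(t.label for t in tree.taxon_namespace)
    dists = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dists.patristic_distance(taxa[names[i]], taxa[names[j]])
    return d, names


def rf_distance(t1, t2):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestCompleteDeletion:
    def test_gap_column_removed(self):
        aln = AlignedSequences(["a", "b"], ["ACGT-", "ACGA-"])
        out = complete_deletion(aln)
        assert out.n_columns == 4
        assert out.rows == ["ACGT", "ACGA"]

    def test_gap_free_unchanged(self):
        aln = AlignedSequences(["a", "b"], ["ACDE", "ACDF"])
        assert complete_deletion(aln).rows == aln.rows

    def test_missing_data_column_removed(self):
        aln = AlignedSequences(["a", "b"], ["AXDE", "ACDF"])
        assert complete_deletion(aln).n_columns == 3

    def test_all_columns_gone_rejected(self):
        aln = AlignedSequences(["a", "b"], ["-A", "A-"])
        with pytest.raises(ValueError):
            complete_deletion(aln)


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        assert poisson_distance("ACDEF", "ACDEF") == 0.0

    def test_closed_forms(self):
        # p = 0.5 -> ln 2; p = 0.25 -> -ln 0.75
        assert poisson_distance("AAAA", "AAGG") == pytest.approx(0.6931, abs=1e-4)
        assert poisson_distance("AAAA", "AAAG") == pytest.approx(0.2877, abs=1e-4)

    def test_saturated_rows_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            poisson_distance("AAAA", "GGGG")

    def test_monotone_in_proportion_differing(self):
        base = "A" * 20
        prev = -1.0
        for k in range(0, 20):
            other = "G" * k + "A" * (20 - k)
            d = poisson_distance(base, other)
            assert d > prev
            prev = d

    def test_corrected_distance_at_least_observed(self):
        rng = np.random.default_rng(8)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            a = "".join(rng.choice(aas, 50))
            b = "".join(rng.choice(aas, 50))
            p = sum(x != y for x, y in zip(a, b)) / 50
            if p < 1:
                assert poisson_distance(a, b) >= p


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): pairwise paths below, total length 11
        names = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        d[2, 3] = d[3, 2] = 7.0
        tree = neighbor_joining(d, names)
        paths = tree_path_distances(tree)
        for (i, j) in combinations(range(4), 2):
            key = tuple(sorted((names[i], names[j])))
            assert paths[key] == pytest.approx(d[i, j], abs=1e-9)
        assert total_branch_length(tree) == pytest.approx(11.0, abs=1e-9)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(d, ["x", "y", "z"])
        paths = tree_path_distances(tree)
        assert paths[("x", "y")] == pytest.approx(4.0, abs=1e-9)
        assert paths[("x", "z")] == pytest.approx(6.0, abs=1e-9)
        assert paths[("y", "z")] == pytest.approx(8.0, abs=1e-9)

    def test_ultrametric_topology_vs_least_squares_oracle(self):
        # 5-taxon ultrametric tree: ((A,B),(C,D)),E with clock-like depths
        names = list("ABCDE")
        d = np.array([
            [0.0, 0.2, 0.6, 0.6, 1.0],
            [0.2, 0.0, 0.6, 0.6, 1.0],
            [0.6, 0.6, 0.0, 0.3, 1.0],
            [0.6, 0.6, 0.3, 0.0, 1.0],
            [1.0, 1.0, 1.0, 1.0, 0.0],
        ])
        tree = neighbor_joining(d, names)
        nj_splits = _nontrivial_splits(tree, names)
        oracle_splits = _least_squares_best_topology(d, names)
        assert nj_splits == oracle_splits

    def test_random_additive_trees_recovered_exactly(self):
        for seed in range(50):
            n = 4 + seed % 5  # 4..8 leaves
            true = random_additive_tree(n, seed=seed)
            d, names = additive_matrix(true)
            tree = neighbor_joining(d, names)
            assert rf_distance(true, tree) == 0
            paths = tree_path_distances(tree)
            for i, j in combinations(range(n), 2):
                key = tuple(sorted((names[i], names[j])))
                assert paths[key] == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_scikit_bio_on_non_additive_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        n = 6
        base = rng.uniform(0.2, 1.5, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        names = [f"t{i}" for i in range(n)]
        import io

        ours = neighbor_joining(d, names)
        buf = io.StringIO()
        skbio_nj(SkbioDM(d, ids=names)).write(buf, format="newick")
        theirs = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
        assert rf_distance(ours, theirs) == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, list("abc"))

    def test_edge_count(self):
        true = random_additive_tree(7, seed=3)
        d, names = additive_matrix(true)
        tree = neighbor_joining(d, names)
        n_edges = sum(
            1 for e in tree.edges()
            if e.head_node is not tree.seed_node and e.length is not None
        )
        assert n_edges == 2 * 7 - 3


def _nontrivial_splits(tree, names):
    """Leaf bipartitions induced by internal edges, as frozensets."""
    all_names = frozenset(names)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if 1 < len(below) < len(names) - 1:
            splits.add(min(below, frozenset(all_names - below), key=sorted))
    return splits


def _least_squares_best_topology(d, names):
    """Exhaustive 15-topology OLS oracle for 5 taxa.

    Every unrooted binary 5-leaf tree is two cherries and a middle leaf;
    branch lengths are fit by least squares on the 10 pairwise distances
    and the lowest-SSE topology's splits are returned.
    """
    n = 5
    pairs = list(combinations(range(n), 2))
    best = (np.inf, None)
    seen = set()
    for cherry1 in combinations(range(n), 2):
        rest = [i for i in range(n) if i not in cherry1]
        for cherry2 in combinations(rest, 2):
            key = frozenset((frozenset(cherry1), frozenset(cherry2)))
            if key in seen:
                continue
            seen.add(key)
            middle = next(i for i in rest if i not in cherry2)
            # edges: 5 pendant + internal u-w and w-v
            # leaf cherry1 -> u, cherry2 -> v, middle -> w
            def path_edges(i, j):
                e = [i, j]  # pendant edges by leaf index
                def side(x):
                    if x in cherry1:
                        return "u"
                    if x in cherry2:
                        return "v"
                    return "w"
                si, sj = side(i), side(j)
                if {si, sj} == {"u", "v"}:
                    e += [5, 6]
                elif {si, sj} == {"u", "w"}:
                    e += [5]
                elif {si, sj} == {"v", "w"}:
                    e += [6]
                elif si == sj == "u" or si == sj == "v":
                    pass
                return e

            a = np.zeros((len(pairs), 7))
            y = np.array([d[i, j] for i, j in pairs])
            for row, (i, j) in enumerate(pairs):
                for e in path_edges(i, j):
                    a[row, e] = 1.0
            x, res, *_ = np.linalg.lstsq(a, y, rcond=None)
            sse = float(np.sum((a @ x - y) ** 2))
            split1 = frozenset(names[i] for i in cherry1)
            split2 = frozenset(names[i] for i in cherry2)
            if sse < best[0] - 1e-12:
                best = (sse, {_canon(split1, names), _canon(split2, names)})
    return best[1]


def _canon(split, names):
    other = frozenset(names) - split
    return min(split, other, key=sorted)


class TestTotalBranchLength:
    def test_uniform_four_leaf_tree(self):
        t = dendropy.Tree.get(
            data="((a:1,b:1):1,c:1,d:1);", schema="newick"
        )
        assert total_branch_length(t) == pytest.approx(5.0)

    def test_zero_star(self):
        t = dendropy.Tree.get(data="(a:0,b:0,c:0);", schema="newick")
        assert total_branch_length(t) == 0.0


class TestNewickRoundTrip:
    def test_write_read_preserves_topology_and_lengths(self, tmp_path):
        true = random_additive_tree(6, seed=9)
        d, names = additive_matrix(true)
        tree = neighbor_joining(d, names)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        again = read_newick(path)
        assert rf_distance(tree, again) == 0
        assert total_branch_length(again) == pytest.approx(
            total_branch_length(tree), abs=1e-9
        )


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self):
        aln = AlignedSequences(
            ["a", "b", "c"], ["ACDEFGHIKL", "ACDEFGHIKV", "ACDEYGHIKV"]
        )
        d = distance_matrix(aln)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d[0, 1] == pytest.approx(-np.log(0.9), abs=1e-12)


class TestTopologyRecoveryFromEvolvedFamilies:
    def test_nj_recovers_generating_topology(self, nj_topology_recovery):
        assert nj_topology_recovery >= 18
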