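"""Chord distance and UPGMA dendrogram."""

import math

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from mitoscreen import CSE_MAX, cse_distance, to_newick, upgma, write_newick


def _matrix(rows, genomes):
    return pd.DataFrame(rows, columns=genomes, dtype=bool)


class TestCseDistance:
    def test_identical_profiles_distance_zero(self):
        m = _matrix([[1, 1], [0, 0], [1, 1]], ["a", "b"])
        assert cse_distance(m).loc["a", "b"] == 0.0

    def test_complete_disagreement_closed_form(self):
        for L in (1, 5, 20):
            m = _matrix([[1, 0]] * L, ["a", "b"])
            d = cse_distance(m).loc["a", "b"]
            assert d == pytest.approx(2 * math.sqrt(2) / math.pi, abs=1e-12)
            assert d == pytest.approx(0.9003, abs=1e-4)

    def test_partial_disagreement(self):
        rows = [[1, 0]] * 3 + [[1, 1]] * 7
        d = cse_distance(_matrix(rows, ["a", "b"])).loc["a", "b"]
        assert d == pytest.approx(0.3 * CSE_MAX, abs=1e-12)
        assert d == pytest.approx(0.2701, abs=1e-4)

    def test_metric_properties(self, rng):
        m = _matrix(rng.integers(0, 2, size=(12, 4)).astype(bool),
                    list("abcd"))
        dm = cse_distance(m).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)
        n = dm.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-12

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError):
            cse_distance(pd.DataFrame(columns=["a", "b"], dtype=bool))


class TestUpgma:
    def test_hand_computed_three_taxa(self):
        dm = pd.DataFrame([[0, .2, .6], [.2, 0, .6], [.6, .6, 0]],
                          index=list("ABC"), columns=list("ABC"))
        assert to_newick(upgma(dm)) == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_equal_distances_deterministic(self):
        dm = pd.DataFrame(0.4 * (1 - np.eye(4)), index=list("DBCA"),
                          columns=list("DBCA"))
        n1 = to_newick(upgma(dm))
        n2 = to_newick(upgma(dm.loc[list("ABCD"), list("ABCD")]))
        assert n1 == n2  # tie rule depends on labels, not input order

    def test_matches_scipy_average_linkage(self, rng):
        """Topology and node heights equal an independent O(n^3) UPGMA on
        random 5-taxon matrices."""
        labels = [f"G{i}" for i in range(5)]
        for _ in range(10):
            m = np.zeros((5, 5))
            iu = np.triu_indices(5, 1)
            m[iu] = rng.uniform(0.05, 1.0, len(iu[0]))
            m += m.T
            mine = upgma(pd.DataFrame(m, index=labels, columns=labels))
            root = to_tree(linkage(squareform(m), method="average"))

            def scipy_sets(node, acc):
                if node.is_leaf():
                    return frozenset([labels[node.id]])
                s = scipy_sets(node.left, acc) | scipy_sets(node.right, acc)
                acc[s] = node.dist / 2
                return s

            def my_sets(node, acc):
                if node.is_leaf:
                    return frozenset([node.name])
                s = frozenset()
                for c in node.children:
                    s |= my_sets(c, acc)
                acc[s] = node.height
                return s

            ref, got = {}, {}
            scipy_sets(root, ref)
            my_sets(mine, got)
            assert set(ref) == set(got)
            for k in ref:
                assert got[k] == pytest.approx(ref[k], abs=1e-9)

    def test_ultrametric(self, rng):
        labels = [f"G{i}" for i in range(6)]
        m = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        m[iu] = rng.uniform(0.05, 1.0, len(iu[0]))
        m += m.T
        tree = upgma(pd.DataFrame(m, index=labels, columns=labels))

        def depths(node, acc_h):
            if node.is_leaf:
                return [acc_h]
            out = []
            for c in node.children:
                out += depths(c, acc_h + (node.height - c.height))
            return out

        ds = depths(tree, 0.0)
        assert max(ds) - min(ds) < 1e-9

    def test_recovers_planted_nested_topology(self):
        """Private-insertion profiles with a ladder of divergences yield the
        planted nested clades."""
        genomes = ["query", "sisterA", "sisterB", "cousin", "outgroup"]
        n_private = {"query": 1, "sisterA": 1, "sisterB": 3, "cousin": 6,
                     "outgroup": 10}
        rows = []
        for gi, g in enumerate(genomes):
            for _ in range(n_private[g]):
                rows.append([i == gi for i in range(len(genomes))])
        tree = upgma(cse_distance(_matrix(rows, genomes)))
        clades = set()

        def collect(node):
            if node.is_leaf:
                return frozenset([node.name])
            s = frozenset()
            for c in node.children:
                s |= collect(c)
            clades.add(s)
            return s

        collect(tree)
        assert frozenset({"query", "sisterA"}) in clades
        assert frozenset({"query", "sisterA", "sisterB"}) in clades
        assert frozenset({"query", "sisterA", "sisterB", "cousin"}) in clades


class TestNewick:
    def test_single_cherry(self):
        dm = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["A", "B"],
                          columns=["A", "B"])
        assert to_newick(upgma(dm)) == "(A:0.5,B:0.5);"

    def test_roundtrip_via_skbio(self, rng, tmp_path):
        labels = [f"G{i}" for i in range(5)]
        m = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        m[iu] = rng.uniform(0.1, 1.0, len(iu[0]))
        m += m.T
        tree = upgma(pd.DataFrame(m, index=labels, columns=labels))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        assert sorted(t.name for t in parsed.tips()) == labels
        # total tip depth preserved
        assert parsed.find("G0").distance(parsed.find("G1")) > 0

    def test_labels_with_spaces_quoted(self):
        dm = pd.DataFrame([[0, .4], [.4, 0]], index=["tax one", "B"],
                          columns=["tax one", "B"])
        nwk = to_newick(upgma(dm))
        assert "'tax one'" in nwk and nwk.endswith(";")
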