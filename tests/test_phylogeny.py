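"""NJ reconstruction, bootstrap support, and group assignment."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from ervscape import assign_group, bootstrap_support, distance_matrix, nj_tree
from ervscape import mutate_sequence
from ervscape.phylogeny import tree_splits


def _random_seq(length, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _additive_matrix(tree_splits_spec, names, internal=0.6, leaf_lengths=None):
    """Distances from a tree given as a set of splits with branch lengths."""
    leaf_lengths = leaf_lengths or {n: 1.0 + 0.1 * i for i, n in enumerate(names)}
    n = len(names)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = leaf_lengths[names[i]] + leaf_lengths[names[j]]
        for split in tree_splits_spec:
            if (names[i] in split) != (names[j] in split):
                d += internal
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, names)


class TestDistanceMatrix:
    def test_identical_taxa_all_zero(self):
        aln = {n: "ACGTACGT" for n in "abc"}
        assert np.allclose(distance_matrix(aln).data, 0.0)

    def test_jc_closed_form(self):
        # p = 0.25 -> JC distance -(3/4) ln(2/3)
        aln = {"a": "AAAA" * 25, "b": ("AAAC" * 25), "c": "AAAA" * 25}
        dm = distance_matrix(aln, model="JC")
        assert dm["a", "b"] == pytest.approx(-0.75 * np.log(2 / 3), abs=1e-12)

    def test_saturated_pair_named_in_error(self):
        aln = {"a": "A" * 100, "b": "C" * 76 + "A" * 24, "c": "A" * 100}
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            distance_matrix(aln, model="JC")

    def test_k2p_reduces_toward_jc_for_even_changes(self):
        # equal transition/transversion proportions: K2P ~ JC
        aln = {
            "a": "A" * 100,
            "b": "G" * 10 + "C" * 5 + "T" * 5 + "A" * 80,
            "c": "A" * 100,
        }
        dm_k = distance_matrix(aln, model="K2P")
        dm_j = distance_matrix(aln, model="JC")
        assert dm_k["a", "b"] == pytest.approx(dm_j["a", "b"], rel=0.05)


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 6], [4, 6, 0]], ["a", "b", "c"])
        tree = nj_tree(dm)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 4.0}

    def test_four_taxon_topology_recovery(self):
        # additive matrix from ((a,b),(c,d)): the ab|cd split must come back
        dm = _additive_matrix([{"a", "b"}], ["a", "b", "c", "d"])
        assert tree_splits(nj_tree(dm)) == {frozenset({"a", "b"})}

    @pytest.mark.parametrize("pair", [("a", "b"), ("a", "c"), ("a", "d")])
    def test_all_four_taxon_shapes(self, pair):
        names = ["a", "b", "c", "d"]
        dm = _additive_matrix([set(pair)], names)
        assert tree_splits(nj_tree(dm)) == {frozenset(pair)}

    def test_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]]))

    def test_matches_independent_nj_implementation(self):
        # same additive matrix through scikit-bio's own NJ: same splits
        from skbio.tree import nj as skbio_nj

        names = list("abcde")
        dm = _additive_matrix([{"a", "b"}, {"a", "b", "c"}], names)
        ours = tree_splits(nj_tree(dm))
        theirs = tree_splits(skbio_nj(dm))
        assert ours == theirs == {frozenset({"a", "b"}), frozenset({"d", "e"})}


class TestBootstrap:
    def _two_clade_alignment(self, seed=0, length=2000, intra=0.01, inter=0.30):
        ancestor = _random_seq(length, seed)
        other = mutate_sequence(ancestor, inter, seed=seed + 1)
        aln = {}
        for i in range(5):
            aln[f"x{i}"] = mutate_sequence(ancestor, intra, seed=100 + i)
            aln[f"y{i}"] = mutate_sequence(other, intra, seed=200 + i)
        return aln

    def test_well_separated_clades_strongly_supported(self):
        aln = self._two_clade_alignment()
        _, supports = bootstrap_support(aln, reps=100, seed=5)
        clade = frozenset(f"x{i}" for i in range(5))
        assert supports[clade] >= 95.0

    def test_single_replicate_supports_binary(self):
        aln = self._two_clade_alignment(length=300)
        _, supports = bootstrap_support(aln, reps=1, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproducible(self):
        aln = self._two_clade_alignment(length=500)
        _, s1 = bootstrap_support(aln, reps=50, seed=9)
        _, s2 = bootstrap_support(aln, reps=50, seed=9)
        assert s1 == s2

    def test_supports_invariant_to_taxon_order(self):
        aln = self._two_clade_alignment(length=500)
        reordered = dict(reversed(list(aln.items())))
        _, s1 = bootstrap_support(aln, reps=50, seed=4)
        _, s2 = bootstrap_support(reordered, reps=50, seed=4)
        clade = frozenset(f"x{i}" for i in range(5))
        assert s1[clade] == s2[clade]

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "A", "b": "A", "c": "A"}, reps=2, seed=0)

    def test_two_gag_subclusters_both_supported(self):
        """Two intra-tight, inter-divergent sub-lineages form two supported
        clusters (the 'type a / type b' pattern)."""
        ancestor = _random_seq(2000, 42)
        type_a = mutate_sequence(ancestor, 0.075, seed=1)   # inter ~0.15
        type_b = mutate_sequence(ancestor, 0.075, seed=2)
        aln = {}
        for i in range(4):
            aln[f"a{i}"] = mutate_sequence(type_a, 0.03, seed=300 + i)
            aln[f"b{i}"] = mutate_sequence(type_b, 0.03, seed=400 + i)
        _, supports = bootstrap_support(aln, reps=100, seed=7)
        cluster_a = frozenset(f"a{i}" for i in range(4))
        cluster_b = frozenset(f"b{i}" for i in range(4))
        assert supports[cluster_a] >= 95.0 or supports[cluster_b] >= 95.0
        assert cluster_a in supports or cluster_b in supports


class TestAssignGroup:
    def _panel(self, seed=0, length=1500, n_groups=6):
        panel = {}
        for g in range(n_groups):
            panel[f"ref{g}"] = (_random_seq(length, 1000 + g), f"HML-{g + 1}")
        return panel

    def test_mutated_copy_assigned_to_its_group(self):
        panel = self._panel()
        query = mutate_sequence(panel["ref3"][0], 0.05, seed=77)
        labels = assign_group({"q1": query}, panel, reps=50, seed=2)
        assert labels == {"q1": "HML-4"}

    def test_query_equal_to_reference(self):
        panel = self._panel()
        labels = assign_group({"q1": panel["ref0"][0]}, panel, reps=50, seed=2)
        assert labels == {"q1": "HML-1"}

    def test_unrelated_query_unassigned(self):
        panel = self._panel()
        labels = assign_group({"q1": _random_seq(1500, 999_999)}, panel,
                              reps=50, seed=2)
        assert labels == {"q1": "unassigned"}

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_group({"q": "ACGT"}, {})
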