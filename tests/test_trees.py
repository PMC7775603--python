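import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from pcmphylo.distances import DistanceMatrix, distance_matrix
from pcmphylo.matrix import ParameterMatrix
from pcmphylo.trees import (
    CladeGroup,
    bootstrap_support,
    clade_recovered,
    clade_sets,
    gold_standard_score,
    is_ultrametric,
    leaf_set,
    load_gold_standard,
    majority_rule_consensus,
    newick_read,
    newick_write,
    robinson_foulds,
    upgma,
)
from helpers import average_linkage_oracle, random_ultrametric, tree_cophenetic


def dm(labels, condensed_or_square):
    arr = np.asarray(condensed_or_square, dtype=float)
    if arr.ndim == 1:
        arr = squareform(arr)
    return DistanceMatrix(list(labels), arr, "test")


class TestUpgma:
    def test_single_merge(self):
        tree = upgma(dm("AB", [0.4]))
        labels, M = tree_cophenetic(tree)
        assert M[0, 1] == pytest.approx(0.4)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.2)

    def test_three_taxon_hand_agglomeration(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6 -> ((A:0.1,B:0.1):0.2,C:0.3)
        tree = upgma(dm("ABC", [0.2, 0.6, 0.6]))
        by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
        assert by_label["A"].edge.length == pytest.approx(0.1)
        assert by_label["C"].edge.length == pytest.approx(0.3)
        inner = by_label["A"].parent_node
        assert inner.edge.length == pytest.approx(0.2)
        assert leaf_set(inner) == frozenset("AB")

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_matches_exhaustive_average_linkage_oracle(self, rng, n):
        """Cophenetic matrices and clade sets agree with brute-force UPGMA."""
        labels = [f"t{i}" for i in range(n)]
        for _ in range(10):
            vals = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
            tree = upgma(dm(labels, vals))
            coph_oracle, clades_oracle = average_linkage_oracle(labels, vals)
            got_labels, coph = tree_cophenetic(tree)
            order = [labels.index(l) for l in got_labels]
            assert np.allclose(coph, coph_oracle[np.ix_(order, order)], atol=1e-9)
            assert clade_sets(tree, include_trivial=True) >= clades_oracle

    def test_matches_scipy_average_linkage(self, rng):
        """Cross-check against scipy's independent implementation."""
        n = 8
        condensed = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
        labels = [f"t{i}" for i in range(n)]
        tree = upgma(dm(labels, condensed))
        got_labels, coph = tree_cophenetic(tree)
        scipy_coph = squareform(cophenet(linkage(condensed, method="average")))
        order = [labels.index(l) for l in got_labels]
        assert np.allclose(coph, scipy_coph[np.ix_(order, order)], atol=1e-9)

    def test_recovers_random_ultrametric_trees_exactly(self, rng):
        """UPGMA on an exactly ultrametric matrix rebuilds topology and heights."""
        for n in (5, 8, 12):
            labels = [f"t{i}" for i in range(n)]
            D, clades = random_ultrametric(labels, rng)
            tree = upgma(D)
            assert is_ultrametric(tree, tol=1e-9)
            got_labels, coph = tree_cophenetic(tree)
            order = [labels.index(l) for l in got_labels]
            assert np.allclose(coph, D.values[np.ix_(order, order)], atol=1e-9)
            assert clade_sets(tree, include_trivial=True) == clades

    def test_output_is_ultrametric_and_order_invariant(self, rng):
        n = 6
        labels = [f"t{i}" for i in range(n)]
        vals = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        tree = upgma(dm(labels, vals))
        assert is_ultrametric(tree)
        perm = rng.permutation(n)
        tree_p = upgma(dm([labels[i] for i in perm], vals[np.ix_(perm, perm)]))
        assert clade_sets(tree, include_trivial=True) == clade_sets(tree_p, include_trivial=True)

    def test_undefined_distances_rejected(self):
        V = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            upgma(DistanceMatrix(["A", "B"], V, "test"))


class TestClades:
    t = None

    def setup_method(self):
        self.balanced = newick_read("((A:1,B:1):1,(C:1,D:1):1);")
        self.ladder = newick_read("((A:2,(B:1,C:1):1):1,D:3);")

    def test_exact_clade_membership(self):
        assert clade_recovered(self.balanced, CladeGroup.of("x", "AB"))
        assert not clade_recovered(self.balanced, CladeGroup.of("x", "BC"))
        assert clade_recovered(self.ladder, CladeGroup.of("x", "ABC"))

    def test_member_not_in_tree(self):
        with pytest.raises(ValueError, match="not in tree"):
            clade_recovered(self.balanced, CladeGroup.of("x", {"A", "Z"}))

    def test_score_table_and_fraction(self):
        groups = [CladeGroup.of("good", "AB"), CladeGroup.of("bad", "BC"),
                  CladeGroup.of("also", "CD")]
        table, frac = gold_standard_score(self.balanced, groups)
        assert list(table["recovered"]) == [True, False, True]
        assert frac == pytest.approx(2 / 3)
        table2, frac2 = gold_standard_score(self.balanced, groups, exclude={"bad"})
        assert frac2 == 1.0

    def test_empty_group_list_vacuous(self):
        table, frac = gold_standard_score(self.balanced, [])
        assert len(table) == 0 and np.isnan(frac)

    def test_packaged_gold_standard_groups(self):
        groups = load_gold_standard()
        assert len(groups) == 23
        with_altaic = load_gold_standard(include_altaic=True)
        assert len(with_altaic) == 24
        names = {g.name for g in with_altaic}
        assert {"IE", "Romance", "Balto-Finnic", "Altaic", "Kipchak"} <= names
        ie = next(g for g in with_altaic if g.name == "IE")
        assert len(ie.members) == 39


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t1 = newick_read("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = newick_read("((C:1,D:1):1,(A:1,B:1):1);")
        assert robinson_foulds(t1, t2) == (0, 0.0)

    def test_conflicting_quartets(self):
        t1 = newick_read("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = newick_read("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == (2, 1.0)

    def test_leaf_set_mismatch(self):
        t1 = newick_read("((A:1,B:1):1,C:2);")
        t2 = newick_read("((A:1,B:1):1,D:2);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(t1, t2)

    def test_agrees_with_dendropy(self, rng):
        for _ in range(5):
            labels = [f"t{i}" for i in range(8)]
            D1, _ = random_ultrametric(labels, rng)
            D2, _ = random_ultrametric(labels, rng)
            t1, t2 = upgma(D1), upgma(D2)
            count, _ = robinson_foulds(t1, t2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=newick_write(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=newick_write(t2), schema="newick",
                                   taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert count == expected


class TestNewick:
    def test_round_trip_preserves_everything(self, rng):
        labels = [f"t{i}" for i in range(7)]
        D, _ = random_ultrametric(labels, rng)
        tree = upgma(D)
        for node in tree.preorder_internal_node_iter():
            node.label = "97"
        back = newick_read(newick_write(tree))
        assert leaf_set(back.seed_node) == leaf_set(tree.seed_node)
        assert clade_sets(back) == clade_sets(tree)
        _, M1 = tree_cophenetic(tree)
        _, M2 = tree_cophenetic(back)
        assert np.allclose(M1, M2, atol=1e-9)
        assert all(n.label == "97" for n in back.preorder_internal_node_iter()
                   if n.parent_node is not None)

    def test_labels_with_spaces_quoted(self):
        tree = upgma(dm(["lang one", "lang two"], [0.4]))
        text = newick_write(tree)
        assert "'lang one'" in text
        back = newick_read(text)
        assert leaf_set(back.seed_node) == {"lang one", "lang two"}


class TestBootstrap:
    def test_perfect_split_full_support(self, split_matrix):
        res = bootstrap_support(split_matrix, n_reps=50, seed=1)
        assert res.n_retained + res.n_discarded == 50 and res.n_retained > 0
        assert res.support[frozenset("AB")] == 100.0
        assert res.support[frozenset("CD")] == 100.0

    def test_determinism(self, split_matrix):
        a = bootstrap_support(split_matrix, n_reps=30, seed=7)
        b = bootstrap_support(split_matrix, n_reps=30, seed=7)
        assert a.support_table().to_csv() == b.support_table().to_csv()
        assert newick_write(a.tree) == newick_write(b.tree)

    def test_support_matches_exhaustive_enumeration(self):
        """At P=3 columns all 27 ordered resamples can be enumerated exactly."""
        data = pd.DataFrame(
            [list("++-"), list("+--"), list("-+-"), list("--+"), list("--+")],
            index=list("ABCDE"), columns=["p1", "p2", "p3"],
        )
        m = ParameterMatrix(data)
        # exact clade frequencies over all 3^3 equally likely column draws
        exact: dict = {}
        usable = 0
        for combo in itertools.product(range(3), repeat=3):
            boot = ParameterMatrix(
                data.iloc[:, list(combo)].set_axis(["b0", "b1", "b2"], axis=1))
            D = distance_matrix(boot, "jaccard", undefined_policy="flag")
            if D.has_undefined():
                continue
            usable += 1
            for c in clade_sets(upgma(D)):
                exact[c] = exact.get(c, 0) + 1
        assert usable > 0
        res = bootstrap_support(m, n_reps=600, seed=11)
        for clade, pct in res.support.items():
            expected = 100.0 * exact.get(clade, 0) / usable
            assert abs(pct - expected) <= 5.0, (clade, pct, expected)

    def test_majority_rule_consensus_structure(self, split_matrix):
        res = bootstrap_support(split_matrix, n_reps=40, seed=3)
        cons = majority_rule_consensus(res.clade_counts, res.n_retained,
                                       split_matrix.languages)
        assert frozenset("AB") in clade_sets(cons)
        assert frozenset("CD") in clade_sets(cons)
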