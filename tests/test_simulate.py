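import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from pcmphylo.distances import compare_pair, jaccard_distance
from pcmphylo.matrix import validate_dependencies
from pcmphylo.simulate import (
    SimulationConfig,
    apply_borrowing,
    generate_yule_tree,
    recovery_experiment,
    simulate_dataset,
)
from pcmphylo.trees import is_ultrametric, newick_write, robinson_foulds, upgma
from helpers import tree_cophenetic


class TestYuleTree:
    def test_two_taxa_single_cherry(self):
        tree = generate_yule_tree(2, seed=5)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 2
        assert leaves[0].parent_node is leaves[1].parent_node is tree.seed_node

    def test_seed_determinism(self):
        a = newick_write(generate_yule_tree(12, seed=99))
        b = newick_write(generate_yule_tree(12, seed=99))
        assert a == b

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_tip_count_and_ultrametricity_over_seeds(self, n):
        for seed in range(60):
            tree = generate_yule_tree(n, birth_rate=2.0, seed=seed)
            assert len(tree.leaf_nodes()) == n
            assert is_ultrametric(tree, tol=1e-9)

    def test_height_rescaling(self):
        tree = generate_yule_tree(8, seed=3, tree_height=1.0)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert np.allclose(depths, 1.0, atol=1e-9)


class TestEvolveParameters:
    def test_frozen_process_stays_default(self):
        cfg = SimulationConfig(n_taxa=6, n_params=20, gain_rate=0.0, loss_rate=0.0,
                               root_plus_prob=0.0, dependency_fraction=0.0, seed=1)
        ds = simulate_dataset(cfg)
        assert (ds.matrix.data.to_numpy() == "-").all()
        assert ds.events == []

    def test_condition_never_met_gives_null_column(self):
        # controller frozen at '-' -> dependent parameter never defined
        cfg = SimulationConfig(n_taxa=5, n_params=2, gain_rate=0.0, loss_rate=0.0,
                               root_plus_prob=0.0, dependency_fraction=1.0, seed=2)
        ds = simulate_dataset(cfg)
        assert ds.dependencies[1] == (0, "+")
        assert (ds.matrix.data["p1"] == "-").all()
        assert (ds.matrix.data["p2"] == "0").all()

    def test_stationary_plus_frequency_on_long_branches(self):
        """Leaf '+' share approaches gain/(gain+loss) for deep trees."""
        gain, loss = 0.6, 0.3
        cfg = SimulationConfig(n_taxa=2, n_params=3000, gain_rate=gain,
                               loss_rate=loss, root_plus_prob=0.0,
                               dependency_fraction=0.0, tree_height=40.0, seed=7)
        ds = simulate_dataset(cfg)
        row = ds.matrix.data.iloc[0]
        n_plus = int((row == "+").sum())
        p = gain / (gain + loss)
        lo, hi = binom.ppf([0.0005, 0.9995], 3000, p)
        assert lo <= n_plus <= hi

    def test_no_dependencies_no_nulls(self, rng):
        cfg = SimulationConfig(n_taxa=8, n_params=40, dependency_fraction=0.0, seed=4)
        ds = simulate_dataset(cfg)
        assert not (ds.matrix.data.to_numpy() == "0").any()

    @pytest.mark.parametrize("seed", [0, 11, 23])
    def test_every_null_certified_by_unmet_condition(self, seed):
        """The evolved null pattern is exactly the declared implicational one."""
        cfg = SimulationConfig(n_taxa=10, n_params=60, dependency_fraction=0.6,
                               seed=seed)
        ds = simulate_dataset(cfg)
        assert (ds.matrix.data.to_numpy() == "0").any()  # non-vacuous
        assert validate_dependencies(ds.matrix, ds.definitions()) == []

    def test_full_dataset_determinism(self):
        cfg = SimulationConfig(n_taxa=9, n_params=30, seed=13,
                               borrowing=(("T1", "T2", 5),))
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert a.matrix.data.equals(b.matrix.data)
        assert newick_write(a.true_tree) == newick_write(b.true_tree)
        assert a.events == b.events
        assert a.dependencies == b.dependencies


class TestBorrowing:
    def make_dataset(self, seed=5):
        cfg = SimulationConfig(n_taxa=8, n_params=50, dependency_fraction=0.4,
                               seed=seed)
        return simulate_dataset(cfg)

    def test_zero_copies_is_identity(self):
        ds = self.make_dataset()
        ds2 = apply_borrowing(ds, "T1", "T2", 0, seed=0)
        assert ds2.matrix.data.equals(ds.matrix.data)

    def test_copy_all_defined_transfers_profile(self):
        ds = self.make_dataset()
        donor_row = ds.matrix.data.loc["T1"]
        defined = [p for p in ds.matrix.parameters if donor_row[p] != "0"]
        ds2 = apply_borrowing(ds, "T1", "T2", len(defined), seed=1)
        assert (ds2.matrix.data.loc["T2", defined] == donor_row[defined]).all()
        # implicational consistency restored on the recipient
        assert validate_dependencies(ds2.matrix, ds2.definitions()) == []

    def test_too_many_copies_rejected(self):
        ds = self.make_dataset()
        with pytest.raises(ValueError, match="cannot copy"):
            apply_borrowing(ds, "T1", "T2", 51, seed=0)

    def test_borrowing_shrinks_pair_distance_in_expectation(self):
        """Jaccard(donor, recipient) decreases with the number of copies."""
        dist_low, dist_high = [], []
        for seed in range(25):
            ds = self.make_dataset(seed=100 + seed)
            row = ds.matrix.data.loc["T1"]
            n_def = int((row != "0").sum())
            for n_copied, acc in ((max(1, n_def // 10), dist_low),
                                  (n_def, dist_high)):
                ds2 = apply_borrowing(ds, "T1", "T2", n_copied, seed=seed)
                c = compare_pair(ds2.matrix.row_codes("T1"),
                                 ds2.matrix.row_codes("T2"))
                d = jaccard_distance(c)
                if not np.isnan(d):
                    acc.append(d)
        assert np.mean(dist_high) < np.mean(dist_low)

    def test_events_logged(self):
        ds = self.make_dataset()
        ds2 = apply_borrowing(ds, "T1", "T2", 10, seed=2)
        borrows = [e for e in ds2.events if e.kind == "borrow"]
        assert len(borrows) == 10
        assert all(e.branch == "T2" and e.detail == "from T1" for e in borrows)


class TestRecovery:
    def test_true_tree_path_metric_recovered_exactly(self, rng):
        """UPGMA is exact on ultrametric input: RF = 0 from the true path metric."""
        from pcmphylo.distances import DistanceMatrix

        for seed in range(5):
            tree = generate_yule_tree(12, seed=seed)
            labels, M = tree_cophenetic(tree)
            est = upgma(DistanceMatrix(labels, M, "path"))
            count, norm = robinson_foulds(tree, est)
            assert count == 0 and norm == 0.0

    def test_recovery_table_shape_and_determinism(self):
        cfg = SimulationConfig(n_taxa=8, n_params=60, dependency_fraction=0.0, seed=6)
        t1 = recovery_experiment(cfg, 5)
        t2 = recovery_experiment(cfg, 5)
        assert list(t1.columns) == ["rep", "seed", "rf_count", "rf_normalized",
                                    "undefined_pairs"]
        pd.testing.assert_frame_equal(t1, t2)
        ok = t1[~t1["undefined_pairs"]]
        assert ((ok["rf_normalized"] >= 0) & (ok["rf_normalized"] <= 1)).all()
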