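"""Birth-death-migration simulator: elementary draws, trees, datasets."""

import numpy as np
import pytest

from phylostruct import (DemeParameters, SimulationConfig, SimulationError,
                         SimulatorState, baseline_design, count_cherries,
                         dataset2_design, newick_string, prune_extinct_lineages,
                         simulate_dataset, simulate_structured_tree,
                         simulate_unstructured_tree)
from phylostruct.simulate import draw_waiting_time, select_deme, select_event
from phylostruct.trees import Node, Phylogeny


def make_state(counts, rates):
    return SimulatorState(list(counts), 0.0, list(rates))


class TestElementaryDraws:
    def test_waiting_time_requires_active_deme(self, rng):
        state = make_state([0, 5], [2.0, 2.0])
        with pytest.raises(SimulationError):
            draw_waiting_time(state, 0, rng)

    def test_waiting_time_positive_and_exponential_mean(self, rng):
        # N*T = 2.0 -> mean 0.5; Monte-Carlo within 3 standard errors
        state = make_state([2, 0], [1.0, 1.0])
        draws = np.array([draw_waiting_time(state, 0, rng)
                          for _ in range(100_000)])
        assert (draws > 0).all()
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_select_deme_threshold(self):
        state = make_state([3, 3], [1.0, 1.0])
        assert select_deme(state, 0.25) == 0
        assert select_deme(state, 0.75) == 1

    def test_select_deme_skips_empty_deme(self):
        state = make_state([0, 3], [5.0, 1.0])
        assert select_deme(state, 0.01) == 1

    def test_select_deme_extinct(self):
        with pytest.raises(SimulationError):
            select_deme(make_state([0, 0], [1.0, 1.0]), 0.5)

    def test_select_deme_empirical_frequency(self, rng):
        state = make_state([1, 1], [3.0, 1.0])
        n = 100_000
        hits = sum(select_deme(state, u) == 0 for u in rng.random(n))
        p = 0.75
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_select_event_boundaries(self):
        params = DemeParameters(3.0, 1.0, 1.0)  # T = 5
        assert select_event(params, 0.0) == "birth"
        assert select_event(params, 1.0) == "death"
        assert select_event(params, 0.7) == "migration"  # 0.6 < 0.7 <= 0.8
        with pytest.raises(ValueError):
            select_event(params, 1.5)


class TestStructuredSimulation:
    PARAMS = (DemeParameters(1.0, 0.05, 0.3), DemeParameters(1.4, 0.1, 0.2))

    def test_no_migration_means_one_deme(self, rng):
        p = DemeParameters(1.0, 0.1, 0.0)
        tree = simulate_structured_tree(
            (p, p), SimulationConfig(n_tips=(20, 0)), rng)
        assert tree.n_migration_nodes == 0
        assert {n.deme for n in tree.iter_preorder()} == {1}

    @pytest.mark.parametrize("n_tips", [(10, 5), (25, 25)])
    def test_tip_count_matches_target(self, rng, n_tips):
        tree = simulate_structured_tree(
            self.PARAMS, SimulationConfig(n_tips=n_tips), rng)
        assert tree.n_tips == sum(n_tips)
        tree.validate()

    def test_pure_birth_node_counts(self, rng):
        params = (DemeParameters(1.0, 0.0, 0.3), DemeParameters(1.4, 0.0, 0.2))
        tree = simulate_structured_tree(
            params, SimulationConfig(n_tips=(20, 15)), rng)
        bifurcations = sum(1 for n in tree.iter_preorder()
                           if len(n.children) == 2)
        assert bifurcations == tree.n_tips - 1
        assert tree.n_migration_nodes >= 0

    def test_joint_termination_meets_quotas(self, rng):
        cfg = SimulationConfig(n_tips=(10, 8), termination="joint")
        tree = simulate_structured_tree(self.PARAMS, cfg, rng)
        leaves_by_deme = {1: 0, 2: 0}
        for leaf in tree.leaves():
            leaves_by_deme[leaf.deme] += 1
        assert leaves_by_deme[1] >= 10 and leaves_by_deme[2] >= 8
        assert tree.metadata["termination"] == "joint"

    def test_population_weighted_option(self, rng):
        cfg = SimulationConfig(n_tips=(15, 10), deme_weighting="population")
        tree = simulate_structured_tree(self.PARAMS, cfg, rng)
        assert tree.n_tips == 25

    def test_subcritical_warns(self, rng):
        params = (DemeParameters(0.1, 0.5, 0.3), DemeParameters(0.1, 0.5, 0.3))
        cfg = SimulationConfig(n_tips=(5, 0), max_retries=2)
        with pytest.warns(UserWarning):
            with pytest.raises(SimulationError):
                simulate_structured_tree(params, cfg, rng)


class TestUnstructuredSimulation:
    def test_two_tip_tree(self, rng):
        tree = simulate_unstructured_tree(1.0, 0.0, 2, rng)
        assert tree.n_tips == 2
        assert len(tree.internal_nodes()) == 1

    def test_binary_invariants(self, rng):
        tree = simulate_unstructured_tree(1.0, 0.4, 40, rng)
        assert tree.n_tips == 40
        assert len(tree.internal_nodes()) == 39
        assert tree.n_migration_nodes == 0
        tree.validate()

    def test_yule_cherry_expectation(self):
        """Mean cherry count of Yule trees is n/3 (within 3 standard errors)."""
        rng = np.random.default_rng(77)
        counts = [count_cherries(simulate_unstructured_tree(1.0, 0.0, 100, rng))
                  for _ in range(200)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 100 / 3) < 3 * se


class TestPruning:
    def test_identity_without_deaths(self, rng):
        tree = simulate_unstructured_tree(1.0, 0.0, 15, rng)
        before = newick_string(tree)
        assert newick_string(prune_extinct_lineages(tree)) == before

    def test_three_tip_forced_topology(self):
        # ((a,b)x,dead)root -> pruning suppresses root, x becomes the root
        root = Node(label="root")
        x = root.add_child(Node(label="x", edge_length=1.0))
        dead = root.add_child(Node(label="dead", edge_length=1.0))
        dead.alive = False
        x.add_child(Node(label="a", edge_length=1.0))
        x.add_child(Node(label="b", edge_length=1.0))
        tree = prune_extinct_lineages(Phylogeny(root))
        assert tree.root.label == "x"
        assert [c.label for c in tree.root.children] == ["a", "b"]

    @pytest.mark.parametrize("seed", range(5))
    def test_extant_tip_set_preserved(self, seed):
        """Pruning keeps exactly the extant tips (set-equality oracle)."""
        params = (DemeParameters(1.0, 0.6, 0.3), DemeParameters(1.2, 0.5, 0.2))
        rng = np.random.default_rng(seed)
        tree = simulate_structured_tree(
            params, SimulationConfig(n_tips=(12, 8)), rng)
        leaves = tree.leaves()
        assert all(leaf.alive for leaf in leaves)
        assert len(leaves) == 20
        tree.validate()

    def test_all_dead_raises(self):
        root = Node()
        for _ in range(2):
            child = root.add_child(Node(edge_length=1.0))
            child.alive = False
        with pytest.raises(SimulationError):
            prune_extinct_lineages(Phylogeny(root))


class TestDatasets:
    def test_baseline_design_shape(self):
        design = baseline_design(3, n_unstructured=500, n_structured=500)
        unstr = design[design.label == "non-structured"]
        assert len(unstr) == 500 and len(design) == 1000
        assert (unstr.n_tips_1 == 350).all()
        assert unstr.lambda_1.iloc[0] == pytest.approx(0.0699, abs=5e-5)
        struct = design[design.label == "structured"]
        assert (struct.n_tips_1 == 350).all() and (struct.n_tips_2 == 200).all()
        assert struct.lambda_1.iloc[0] == pytest.approx(3.0639, abs=5e-5)
        assert struct.lambda_2.iloc[0] == pytest.approx(4.0178, abs=5e-5)

    def test_dataset2_tip_intervals(self):
        design = dataset2_design(3, 30, 30)
        unstr = design[design.label == "non-structured"]
        assert unstr.n_tips_1.between(300, 400).all()
        struct = design[design.label == "structured"]
        assert struct.n_tips_2.between(150, 250).all()

    def test_event_bookkeeping_conservation(self):
        """Births +1, deaths -1, migrations 0: final extant total is the
        target, so tips = target regardless of event mix."""
        design = baseline_design(5, 2, 2)
        design[["n_tips_1"]] = 30
        design.loc[design.label == "structured", "n_tips_2"] = 20
        data = simulate_dataset(design)
        for tree, label in zip(data.trees, data.labels):
            assert tree.n_tips == (30 if label == "non-structured" else 50)

    def test_seeded_determinism(self):
        design = baseline_design(11, 2, 2)
        design["n_tips_1"] = 20
        design.loc[design.label == "structured", "n_tips_2"] = 10
        first = [newick_string(t) for t in simulate_dataset(design).trees]
        second = [newick_string(t) for t in simulate_dataset(design).trees]
        assert first == second
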