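import itertools
import math

import numpy as np
import pandas as pd
import pytest

from frugisim import (
    ExtinctionTrajectory,
    SimulationConfig,
    TraitTable,
    aggregate_random,
    downsizing_sequence,
    random_sequences,
    remove_birds,
    run_extinction,
    run_random_scenario,
    simulate_network_kernel,
    structural_state,
)
from frugisim.extinction_sim import (
    _ldd_profile_cached,
    _ldd_profile_masked,
    _order_positions,
    _structural_profiles,
)

CFG = SimulationConfig(multiplier=10, n_random_sequences=20)


class TestSequences:
    def test_downsizing_sorts_largest_first(self):
        traits = TraitTable(body_mass={"A": 1.2, "B": 0.1, "C": 0.5})
        assert downsizing_sequence(["A", "B", "C"], traits) == ["A", "C", "B"]

    def test_tie_broken_lexicographically(self):
        traits = TraitTable(body_mass={"B": 0.5, "A": 0.5})
        assert downsizing_sequence(["B", "A"], traits) == ["A", "B"]

    def test_single_bird(self):
        assert downsizing_sequence(["A"], TraitTable(body_mass={"A": 1.0})) == ["A"]

    def test_random_sequences_reproducible(self):
        a = random_sequences(np.random.default_rng(3), ["x", "y", "z"], 10)
        b = random_sequences(np.random.default_rng(3), ["x", "y", "z"], 10)
        assert a == b

    def test_random_sequences_uniform_over_orders(self):
        n_iter = 1000
        seqs = random_sequences(np.random.default_rng(0), ["a", "b", "c"], n_iter)
        freq = pd.Series([tuple(s) for s in seqs]).value_counts()
        assert len(freq) == 6
        p = 1 / 6
        sigma = math.sqrt(n_iter * p * (1 - p))
        assert np.all(np.abs(freq.to_numpy() - n_iter * p) < 3 * sigma)

    def test_single_bird_orders_identical(self):
        seqs = random_sequences(np.random.default_rng(1), ["a"], 5)
        assert seqs == [["a"]] * 5


class TestRemoveBirds:
    def test_remove_none_is_identity_remove_all_zeroes_counts(self, toy_network):
        assert remove_birds(toy_network, []).equals(toy_network)
        empty = remove_birds(toy_network, toy_network.birds)
        assert empty.total_events == 0
        assert empty.plants == toy_network.plants  # rows retained for coextinction counts

    def test_remove_one_conserves_remaining_counts(self, toy_network):
        sub = remove_birds(toy_network, ["C"])
        col = list(toy_network.birds).index("C")
        assert sub.total_events == toy_network.total_events - toy_network.counts[:, col].sum()

    def test_unknown_bird_rejected(self, toy_network):
        with pytest.raises(ValueError, match="ghost"):
            remove_birds(toy_network, ["ghost"])


class TestStructuralState:
    def test_interaction_loss_arithmetic(self, toy_network):
        sub = remove_birds(toy_network, ["C"])  # C holds 5 of 11 events
        lost, _ = structural_state(sub, toy_network)
        assert lost == pytest.approx(100 * 5 / 11)

    def test_plant_with_sole_partner_removed_counts_extinct(self, toy_network):
        sub = remove_birds(toy_network, ["B"])  # p2 interacts only with B
        _, extinct = structural_state(sub, toy_network)
        assert extinct == pytest.approx(100 / 3)

    def test_identity_subnetwork_scores_zero(self, toy_network):
        assert structural_state(toy_network, toy_network) == (0.0, 0.0)


class TestRunExtinction:
    def test_boundary_steps(self, toy_network, toy_traits):
        order = downsizing_sequence(toy_network.birds, toy_traits)
        traj = run_extinction(toy_network, toy_traits, order, CFG,
                              np.random.SeedSequence(0), scenario="downsizing")
        first, last = traj.steps.iloc[0], traj.steps.iloc[-1]
        assert (first[["pct_interactions_lost", "pct_plants_extinct",
                       "pct_ldd_change"]] == 0).all()
        assert last["pct_interactions_lost"] == 100
        assert last["pct_plants_extinct"] == 100
        assert last["pct_ldd_change"] == -100

    def test_matches_stepwise_removal_oracle(self, toy_network, toy_traits):
        """Vectorized profiles equal brute-force removal plus direct scoring."""
        for order in itertools.permutations(toy_network.birds):
            traj = run_extinction(toy_network, toy_traits, list(order), CFG,
                                  np.random.SeedSequence(1))
            for m in range(len(order) + 1):
                sub = remove_birds(toy_network, order[:m])
                lost, extinct = structural_state(sub, toy_network)
                row = traj.steps.iloc[m]
                assert row["pct_interactions_lost"] == pytest.approx(lost)
                assert row["pct_plants_extinct"] == pytest.approx(extinct)

    def test_structural_metrics_monotone_along_any_order(self, small_community):
        net, traits = small_community
        for order in random_sequences(np.random.default_rng(0), net.birds, 5):
            pct_lost, pct_extinct = _structural_profiles(net, _order_positions(net, order))
            assert np.all(np.diff(pct_lost) >= 0)
            assert np.all(np.diff(pct_extinct) >= 0)

    def test_cached_profile_agrees_with_masked_reference(self, small_community):
        net, traits = small_community
        kernel = simulate_network_kernel(net, traits, CFG, np.random.default_rng(0))
        for order in random_sequences(np.random.default_rng(1), net.birds, 5):
            pos = _order_positions(net, order)
            fast = _ldd_profile_cached(kernel, pos, 0.95)
            ref = _ldd_profile_masked(kernel, pos, 0.95)
            np.testing.assert_allclose(fast, ref, rtol=1e-12)

    def test_order_must_be_permutation(self, toy_network, toy_traits):
        with pytest.raises(ValueError, match="permutation"):
            run_extinction(toy_network, toy_traits, ["A", "B"], CFG,
                           np.random.SeedSequence(0))


class TestRandomScenario:
    def test_mean_interaction_loss_is_linear_in_removals(self, small_community):
        """E[% events lost after m of n removals] = 100 m/n under uniform orders."""
        net, traits = small_community
        n = net.n_birds
        cfg = SimulationConfig(multiplier=2, n_random_sequences=1000)
        kernel = simulate_network_kernel(net, traits, cfg, np.random.default_rng(0))
        orders = random_sequences(np.random.default_rng(3), net.birds, cfg.n_random_sequences)
        per_iter = np.array([
            _structural_profiles(net, _order_positions(net, order))[0] for order in orders
        ])
        mean = per_iter.mean(axis=0)
        se = per_iter.std(axis=0, ddof=1) / np.sqrt(len(orders))
        expected = 100.0 * np.arange(n + 1) / n
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)

    def test_full_enumeration_mean_is_exact(self, toy_network, toy_traits):
        """Averaging over all n! orders reproduces 100 m/n exactly."""
        trajs = [
            run_extinction(toy_network, toy_traits, list(order),
                           SimulationConfig(multiplier=2), np.random.SeedSequence(0),
                           ldd_mode="cached")
            for order in itertools.permutations(toy_network.birds)
        ]
        mean = aggregate_random(trajs)
        n = toy_network.n_birds
        np.testing.assert_allclose(
            mean.steps["pct_interactions_lost"], 100.0 * np.arange(n + 1) / n, atol=1e-9)

    def test_fast_scenario_equals_aggregated_per_order_runs(self, toy_network, toy_traits):
        cfg = SimulationConfig(multiplier=5, n_random_sequences=8)
        seq = np.random.SeedSequence(11)
        mean_fast = run_random_scenario(toy_network, toy_traits, cfg, seq)

        kernel_seed, orders_seed = np.random.SeedSequence(11).spawn(2)
        kernel = simulate_network_kernel(toy_network, toy_traits, cfg,
                                         np.random.default_rng(kernel_seed))
        orders = random_sequences(np.random.default_rng(orders_seed), toy_network.birds, 8)
        trajs = [run_extinction(toy_network, toy_traits, order, cfg,
                                np.random.SeedSequence(0), ldd_mode="cached", kernel=kernel)
                 for order in orders]
        mean_slow = aggregate_random(trajs)
        pd.testing.assert_frame_equal(mean_fast.steps, mean_slow.steps)

    def test_endpoints_coincide_across_scenarios(self, small_community):
        net, traits = small_community
        cfg = SimulationConfig(multiplier=2, n_random_sequences=10)
        down = run_extinction(net, traits, downsizing_sequence(net.birds, traits), cfg,
                              np.random.SeedSequence(0), ldd_mode="cached")
        rand = run_random_scenario(net, traits, cfg, np.random.SeedSequence(1))
        for col in ("pct_interactions_lost", "pct_plants_extinct"):
            assert down.steps[col].iloc[0] == rand.steps[col].iloc[0] == 0
            assert down.steps[col].iloc[-1] == rand.steps[col].iloc[-1] == 100


class TestAggregateRandom:
    def test_single_trajectory_is_identity(self, toy_network, toy_traits):
        traj = run_extinction(toy_network, toy_traits, list(toy_network.birds), CFG,
                              np.random.SeedSequence(0), ldd_mode="cached")
        agg = aggregate_random([traj])
        pd.testing.assert_frame_equal(
            agg.steps, traj.steps.assign(), check_exact=True)

    def test_means_bounded_by_iteration_extremes(self, small_community):
        net, traits = small_community
        cfg = SimulationConfig(multiplier=2, n_random_sequences=6)
        _, iters = run_random_scenario(net, traits, cfg, np.random.SeedSequence(2),
                                       return_iterations=True)
        agg = aggregate_random(iters)
        stack = np.stack([t.steps["pct_plants_extinct"].to_numpy() for t in iters])
        assert np.all(agg.steps["pct_plants_extinct"] <= stack.max(axis=0) + 1e-12)
        assert np.all(agg.steps["pct_plants_extinct"] >= stack.min(axis=0) - 1e-12)

    def test_mismatched_networks_rejected(self, toy_network, toy_traits):
        t1 = run_extinction(toy_network, toy_traits, list(toy_network.birds), CFG,
                            np.random.SeedSequence(0), ldd_mode="cached")
        t2 = ExtinctionTrajectory("other", "random", t1.steps)
        with pytest.raises(ValueError, match="different networks"):
            aggregate_random([t1, t2])
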