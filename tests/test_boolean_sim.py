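import numpy as np
import pytest

from togglesim import (
    SimulationConfig,
    enumerate_fixed_points,
    find_steady_states,
    ising_update,
    k_frequencies,
    make_toggle,
)
from togglesim.boolean_sim import (
    build_state_transition_graph,
    hamming_perturbation,
    theorem_k_values,
)
from togglesim.network import SignedNetwork


class TestIsingUpdate:
    def test_toggle2_high_high_resolves(self):
        net = make_toggle(2)
        out = ising_update(net, np.array([1, 1]), 1)
        assert out.tolist() == [1, -1]

    def test_toggle3_majority_input_holds_node_high(self):
        net = make_toggle(3)
        out = ising_update(net, np.array([1, -1, -1]), 0)
        assert out.tolist() == [1, -1, -1]

    def test_zero_input_sum_holds_current_value(self):
        # one inhibition removed: node 1 has no regulators, sum is 0
        net = SignedNetwork(["A", "B"], np.array([[0.0, -1.0], [0.0, 0.0]]))
        out = ising_update(net, np.array([1, 1]), 0)
        assert out.tolist() == [1, 1]

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            ising_update(make_toggle(2), np.array([1, 1]), 5)


class TestEnumerateFixedPoints:
    def test_toggle4_exactly_the_two_high_states(self):
        fps = enumerate_fixed_points(make_toggle(4))
        assert len(fps) == 6
        assert ((fps > 0).sum(axis=1) == 2).all()

    def test_toggle2_self_activation_gains_corner_states(self):
        fps = enumerate_fixed_points(make_toggle(2, "activation"))
        ks = sorted((fps > 0).sum(axis=1).tolist())
        assert ks == [0, 1, 1, 2]

    def test_all_activation_network_has_only_corners(self):
        net = make_toggle(3)
        net.adjacency = np.abs(net.adjacency)
        fps = enumerate_fixed_points(net)
        ks = sorted((fps > 0).sum(axis=1).tolist())
        assert ks == [0, 3]

    @pytest.mark.parametrize("n", range(2, 9))
    def test_half_high_theorem_exhaustive(self, n):
        """Every fixed point of toggle-n has n/2 (even) or (n±1)/2 (odd)
        high nodes, and all such states are fixed."""
        fps = enumerate_fixed_points(make_toggle(n))
        ks = set((fps > 0).sum(axis=1).tolist())
        assert ks == theorem_k_values(n)
        from math import comb

        expected_count = sum(comb(n, k) for k in theorem_k_values(n))
        assert len(fps) == expected_count

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_odd_self_inhibition_has_no_fixed_points(self, n):
        assert len(enumerate_fixed_points(make_toggle(n, "inhibition"))) == 0


class TestFindSteadyStates:
    def test_toggle2_both_single_positive_states(self, replicate_config):
        dist = find_steady_states(make_toggle(2), replicate_config)
        assert dist.n_states == 2
        assert set(map(tuple, dist.states.tolist())) == {(1, -1), (-1, 1)}
        assert dist.k_frequencies()[1] == pytest.approx(1.0)
        assert np.allclose(dist.mean_freqs(), 0.5, atol=0.03)
        assert (dist.converged_fraction == 1).all()

    def test_toggle5_mass_split_between_2_and_3_high(self, replicate_config):
        dist = find_steady_states(make_toggle(5), replicate_config)
        fk = dist.k_frequencies()
        assert fk[2] == pytest.approx(0.5, abs=0.03)
        assert fk[3] == pytest.approx(0.5, abs=0.03)

    def test_toggle3_self_inhibition_never_converges(self, fast_config):
        dist = find_steady_states(make_toggle(3, "inhibition"), fast_config)
        assert dist.n_states == 0
        assert (dist.converged_fraction == 0).all()
        assert (dist.k_frequencies() == 0).all()

    def test_seed_reproducibility(self, fast_config):
        a = find_steady_states(make_toggle(4), fast_config)
        b = find_steady_states(make_toggle(4), fast_config)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.freqs, b.freqs)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_fk_symmetry_under_high_low_exchange(self, n, replicate_config):
        """Pure toggles are symmetric under global high/low relabelling,
        so F(k) = F(n-k) up to Monte-Carlo noise."""
        fk = find_steady_states(make_toggle(n), replicate_config).k_frequencies()
        for k in range(n + 1):
            assert fk[k] == pytest.approx(fk[n - k], abs=0.04)

    def test_monte_carlo_support_matches_oracle(self, fast_config):
        for net in (make_toggle(4), make_toggle(5), make_toggle(6, "activation")):
            dist = find_steady_states(net, fast_config)
            mc = set(map(tuple, dist.states.tolist()))
            oracle = set(map(tuple, enumerate_fixed_points(net).tolist()))
            assert mc == oracle


class TestStateTransitionGraph:
    def test_toggle2_fixed_points_have_no_outgoing_edges(self):
        g = build_state_transition_graph(make_toggle(2))
        assert g.out_degree((1, -1)) == 0
        assert g.out_degree((-1, 1)) == 0
        assert g.nodes[(1, -1)]["stable"]

    def test_toggle3_self_inhibition_all_intermediate_states_leak(self):
        g = build_state_transition_graph(make_toggle(3, "inhibition"))
        for u, data in g.nodes(data=True):
            k = sum(1 for x in u if x > 0)
            if k in (1, 2):
                assert g.out_degree(u) >= 1
                assert not data["stable"]
                assert data["metastable"]

    def test_toggle4_self_inhibition_half_states_remain_stable(self):
        g = build_state_transition_graph(make_toggle(4, "inhibition"))
        for u, data in g.nodes(data=True):
            k = sum(1 for x in u if x > 0)
            assert data["stable"] == (k == 2)


class TestHammingPerturbation:
    def test_toggle2_flip_reaches_both_fixed_points(self):
        out = hamming_perturbation(
            make_toggle(2), SimulationConfig(n_initial_conditions=400, seed=7)
        )
        reached = {r for r, _, _ in out[((1, -1), 1)]}
        assert reached == {(1, -1), (-1, 1)}

    def test_toggle4_return_is_a_modal_outcome(self):
        """Perturbed even toggles relax back to the origin state at least
        as often as to any single alternative fixed point."""
        out = hamming_perturbation(
            make_toggle(4), SimulationConfig(n_initial_conditions=1500, seed=7)
        )
        for (origin, _flip), results in out.items():
            probs = dict(((r, p) for r, p, _ in results))
            assert probs.get(origin, 0.0) >= max(probs.values()) - 0.08

    def test_toggle5_settles_at_hamming_distance_one(self):
        out = hamming_perturbation(
            make_toggle(5), SimulationConfig(n_initial_conditions=400, seed=7)
        )
        assert any(
            d == 1 for results in out.values() for _, _, d in results
        )


class TestKFrequencies:
    def test_toggle6_all_mass_at_half(self, fast_config):
        fk = k_frequencies(find_steady_states(make_toggle(6), fast_config))
        assert fk[3] == pytest.approx(1.0)
        assert fk.sum() == pytest.approx(1.0)

    def test_single_positive_frequency_by_node(self, fast_config):
        dist = find_steady_states(make_toggle(2), fast_config)
        fk, fa1 = k_frequencies(dist, focal_node="N1")
        assert fk[1] == pytest.approx(1.0)
        assert fa1 == pytest.approx(0.5, abs=0.05)
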