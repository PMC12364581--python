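import numpy as np
import pytest

from togglesim import (
    MultiLevelState,
    SimulationConfig,
    discretize_profile,
    find_multilevel_steady_states,
    find_steady_states,
    make_team_network,
    multilevel_update,
)
from togglesim.boolean_sim import ising_update
from togglesim.multilevel import enumerate_multilevel_fixed_points
from togglesim.netgen import TeamSpec
from togglesim.network import SignedNetwork


class TestMultilevelUpdate:
    @pytest.mark.parametrize("seed", range(8))
    def test_l1_coincides_with_ising_update(self, seed):
        """With a single level per sign the bracket rule collapses onto the
        Boolean sign rule for every state and node."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        adj = rng.choice([-1.0, 0.0, 1.0], size=(n, n))
        net = SignedNetwork([f"G{i}" for i in range(n)], adj)
        values = rng.choice([-1.0, 1.0], size=n)
        state = MultiLevelState(values=tuple(values), l=1)
        for j in range(n):
            if np.count_nonzero(adj[:, j]) == 0:
                continue
            ml = multilevel_update(net, state, j)
            boolean = ising_update(net, values.astype(np.int8), j)
            assert np.allclose(ml.values, boolean)

    def test_four_level_bracket_example(self):
        # 2 teams x 2 members, all nodes at +0.5: every node's normalized
        # input is (0.5 - 1.0)/3 = -1/6, landing in the first negative
        # bracket, so the updated node moves to -0.5
        net = make_team_network(TeamSpec(sizes=(2, 2)))
        state = MultiLevelState(values=(0.5, 0.5, 0.5, 0.5), l=2)
        for j in range(4):
            out = multilevel_update(net, state, j)
            assert out.values[j] == -0.5

    def test_zero_input_holds(self):
        adj = np.array([[0.0, 1.0, -1.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        net = SignedNetwork(["A", "B", "C"], adj.T)
        # node A receives +B -C; with B = C the sum is exactly zero
        state = MultiLevelState(values=(0.5, 1.0, 1.0), l=2)
        out = multilevel_update(net, state, 0)
        assert out.values[0] == 0.5

    def test_isolated_node_warns_and_holds(self):
        net = SignedNetwork(["A", "B"], np.array([[0.0, -1.0], [0.0, 0.0]]))
        state = MultiLevelState(values=(1.0, 1.0), l=1)
        with pytest.warns(UserWarning, match="no regulators"):
            out = multilevel_update(net, state, 0)
        assert out.values == state.values

    def test_invalid_level_values_rejected(self):
        with pytest.raises(ValueError):
            MultiLevelState(values=(0.3,), l=2)
        with pytest.raises(ValueError):
            MultiLevelState(values=(0.0,), l=2)


class TestTeamSteadyStates:
    def test_l1_distribution_matches_boolean_engine(self, fast_config):
        net = make_team_network(TeamSpec(sizes=(2, 2)))
        ml = find_multilevel_steady_states(net, 1, fast_config)
        boolean = find_steady_states(net, fast_config)
        ml_support = set(map(tuple, ml.levels.tolist()))
        bool_support = set(map(tuple, boolean.states.tolist()))
        assert ml_support == bool_support
        ml_freqs = {tuple(s): f for s, f in zip(ml.levels.tolist(), ml.mean_freqs())}
        for s, f in zip(boolean.states.tolist(), boolean.mean_freqs()):
            assert ml_freqs[tuple(s)] == pytest.approx(f, abs=0.05)

    def test_within_team_coherence_of_fixed_points(self):
        for sizes in [(2, 2), (2, 2, 2), (3, 3)]:
            net = make_team_network(TeamSpec(sizes=sizes))
            fps = enumerate_multilevel_fixed_points(net, 2)
            start = 0
            for size in sizes:
                block = fps[:, start : start + size]
                assert (block == block[:, :1]).all()
                start += size

    def test_two_team_four_level_profiles_match_boolean(self, fast_config):
        net = make_team_network(TeamSpec(sizes=(2, 2)))
        ml = find_multilevel_steady_states(net, 2, fast_config)
        assert set(ml.profile_frequencies()) == {"20"}

    def test_three_team_four_level_partial_expression(self):
        """Every four-level fixed point of the three-team network keeps at
        least two teams away from full ±1 expression."""
        net = make_team_network(TeamSpec(sizes=(2, 2, 2)))
        fps = enumerate_multilevel_fixed_points(net, 2)
        assert len(fps)
        values = fps / 2.0
        for row in values:
            teams = row.reshape(3, 2).mean(axis=1)
            partial = np.abs(teams) < 1.0
            assert partial.sum() >= 2

    def test_five_team_mass_in_polarized_profiles(self):
        net = make_team_network(TeamSpec(sizes=(2,) * 5))
        dist = find_multilevel_steady_states(
            net, 2, SimulationConfig(n_initial_conditions=4000, seed=5)
        )
        profiles = dist.profile_frequencies()
        mass = sum(
            f for p, f in profiles.items() if sorted(p) in (
                sorted("22000"), sorted("22200"))
        )
        assert mass >= 0.99


class TestDiscretization:
    def test_extreme_and_partial_symbols(self):
        net = make_team_network(TeamSpec(sizes=(2, 2)))
        full = MultiLevelState(values=(1.0, 1.0, -1.0, -1.0), l=2)
        assert discretize_profile(full, net) == "20"
        # one team at +0.5 while the other sits at the state's maximum
        mixed = MultiLevelState(values=(0.5, 0.5, -1.0, -1.0), l=2)
        assert discretize_profile(mixed, net, max_expression=1.0) == "10"

    def test_scaled_state_normalizes_to_full_profile(self):
        net = make_team_network(TeamSpec(sizes=(2, 2)))
        half = MultiLevelState(values=(0.5, 0.5, -0.5, -0.5), l=2)
        assert discretize_profile(half, net) == "20"

    def test_run_normalization_option(self, fast_config):
        net = make_team_network(TeamSpec(sizes=(2, 2)))
        dist = find_multilevel_steady_states(net, 2, fast_config)
        by_run = dist.profile_frequencies(normalization="run")
        assert abs(sum(by_run.values()) - 1.0) < 1e-9
        with pytest.raises(ValueError):
            dist.profile_frequencies(normalization="banana")
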