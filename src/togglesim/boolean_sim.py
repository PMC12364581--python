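"""Asynchronous Boolean simulation in the Ising formalism.

States live in {-1, +1}^n.  One *time step* updates a single node chosen
uniformly at random: the node's next value is the sign of the weighted sum
of its regulators' states (the corresponding column of the adjacency
matrix), and the node holds its current value when the sum is exactly
zero.  Trajectories run until they reach a fixed point (no single-node
update changes the state) or a step cap; non-converged trajectories are
discarded from the frequency statistics.

The module provides a Monte-Carlo driver (:func:`find_steady_states`), an
exhaustive fixed-point oracle (:func:`enumerate_fixed_points`), the full
state-transition graph for small networks, and single-bit (Hamming)
perturbation analysis of fixed points.

Cytokine-tagged nodes are clamped at +1 throughout: they are forced high
in every initial condition and are never drawn for update.  Because a
cytokine has no incoming regulation, its input sum is zero and the clamp
coincides with the hold rule; clamping simply makes the constitutive
activation explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import SignedNetwork

_ENUM_MAX_NODES = 22  # 2^22 states; beyond this exhaustive enumeration refuses


@dataclass(frozen=True)
class AsymmetricWeight:
    """State-dependent inhibition strength from one focal node.

    While the focal node is high, its outgoing (off-diagonal) edge weights
    are scaled by ``weight``; while it is low they keep their baseline
    values.  ``weight == 1`` is the identity.
    """

    focal_index: int
    weight: float

    def delta_row(self, adjacency: np.ndarray) -> np.ndarray:
        """Additive input correction per target while the focal node is high."""
        delta = (self.weight - 1.0) * adjacency[self.focal_index]
        delta = delta.copy()
        delta[self.focal_index] = 0.0  # the focal node's own inputs unchanged
        return delta


@dataclass
class SimulationConfig:
    """Monte-Carlo simulation settings.

    ``n_initial_conditions`` random starting states per replicate,
    ``max_steps`` single-node updates per trajectory before it is declared
    non-converged, ``n_replicates`` independent replicates whose mean and
    95% CI are reported, and a root ``seed`` from which all replicate
    streams derive.
    """

    n_initial_conditions: int = 100_000
    max_steps: int = 1000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_initial_conditions, self.max_steps, self.n_replicates) < 1:
            raise ValueError("all simulation sizes must be positive")


@dataclass
class SteadyStateDistribution:
    """Converged fixed points and their per-replicate relative frequencies.

    ``states`` holds one verified fixed point per row (full ±1 vector over
    all nodes); ``freqs[s, r]`` is the relative frequency of state ``s``
    among the converged trajectories of replicate ``r``.  ``k`` counts the
    high *core* nodes of each state.
    """

    states: np.ndarray            # (S, n) int8 in {-1, +1}
    freqs: np.ndarray             # (S, R)
    converged_fraction: np.ndarray  # (R,)
    node_names: list[str]
    core_mask: np.ndarray

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def k(self) -> np.ndarray:
        if self.n_states == 0:
            return np.zeros(0, dtype=int)
        return (self.states[:, self.core_mask] > 0).sum(axis=1)

    def mean_freqs(self) -> np.ndarray:
        return self.freqs.mean(axis=1) if self.n_states else np.zeros(0)

    def ci95(self) -> np.ndarray:
        """Half-width of the normal-approximation 95% CI across replicates."""
        r = self.freqs.shape[1] if self.n_states else 1
        if r < 2 or self.n_states == 0:
            return np.zeros(self.n_states)
        return 1.96 * self.freqs.std(axis=1, ddof=1) / np.sqrt(r)

    def k_frequencies(self) -> np.ndarray:
        """F(k) for k = 0..n_core, averaged over replicates."""
        n_core = int(self.core_mask.sum())
        out = np.zeros(n_core + 1)
        np.add.at(out, self.k, self.mean_freqs())
        return out

    def single_positive_frequency(self, node_name: str) -> float:
        """F_A(1): frequency of the state with only the named core node high."""
        idx = self.node_names.index(node_name)
        total = 0.0
        freqs = self.mean_freqs()
        core_idx = np.flatnonzero(self.core_mask)
        for s in range(self.n_states):
            high = np.flatnonzero(self.states[s, core_idx] > 0)
            if len(high) == 1 and core_idx[high[0]] == idx:
                total += freqs[s]
        return float(total)


def _updatable_indices(network: SignedNetwork) -> np.ndarray:
    return np.flatnonzero(~network.cytokine_mask)


def _full_inputs(
    adjacency: np.ndarray, states: np.ndarray, asym: AsymmetricWeight | None
) -> np.ndarray:
    """Input sums for every node of every state (rows of ``states``)."""
    inputs = states @ adjacency
    if asym is not None and asym.weight != 1.0:
        high = states[:, asym.focal_index] > 0
        inputs[high] += asym.delta_row(adjacency)
    return inputs


def _is_fixed(
    adjacency: np.ndarray,
    states: np.ndarray,
    updatable: np.ndarray,
    asym: AsymmetricWeight | None,
) -> np.ndarray:
    """Boolean mask: which rows of ``states`` are fixed points."""
    inputs = _full_inputs(adjacency, states, asym)
    cond = states[:, updatable] * inputs[:, updatable] >= 0
    return cond.all(axis=1)


def _relax(
    network: SignedNetwork,
    states: np.ndarray,
    max_steps: int,
    rng: np.random.Generator,
    asym: AsymmetricWeight | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run asynchronous updates on each row of ``states`` until fixed.

    Returns ``(final_states, converged)``.  Rows are updated in place on a
    copy; the fixed-point test is evaluated every ``n_updatable`` steps
    (it is exact, so the cadence only affects when the early exit fires).
    """
    adjacency = network.adjacency
    updatable = _updatable_indices(network)
    n_upd = len(updatable)
    n_traj = states.shape[0]
    final = states.copy()
    converged = np.zeros(n_traj, dtype=bool)

    S = states.astype(float)
    ids = np.arange(n_traj)
    steps_done = 0
    focal = asym.focal_index if asym is not None else -1
    delta = asym.delta_row(adjacency) if asym is not None else None

    while len(ids):
        fixed = _is_fixed(adjacency, S, updatable, asym)
        if fixed.any():
            done = ids[fixed]
            final[done] = S[fixed].astype(np.int8)
            converged[done] = True
            keep = ~fixed
            S, ids = S[keep], ids[keep]
        if not len(ids) or steps_done >= max_steps:
            break
        burst = min(n_upd, max_steps - steps_done)
        t_idx = np.arange(len(ids))
        for _ in range(burst):
            nodes = updatable[rng.integers(0, n_upd, len(ids))]
            inp = np.einsum("ti,it->t", S, adjacency[:, nodes])
            if delta is not None:
                inp += np.where(
                    (S[:, focal] > 0) & (nodes != focal), delta[nodes], 0.0
                )
            cur = S[t_idx, nodes]
            S[t_idx, nodes] = np.where(inp > 0, 1.0, np.where(inp < 0, -1.0, cur))
        steps_done += burst

    # non-converged rows keep their last state but are flagged unconverged
    if len(ids):
        final[ids] = S.astype(np.int8)
    return final, converged


def _random_states(
    network: SignedNetwork, n: int, rng: np.random.Generator
) -> np.ndarray:
    states = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n, network.n_nodes))
    states[:, network.cytokine_mask] = 1
    return states


def ising_update(
    network: SignedNetwork,
    state: np.ndarray,
    node_index: int,
    asym: AsymmetricWeight | None = None,
) -> np.ndarray:
    """Apply one asynchronous Ising update to ``node_index``.

    Returns a new state with that node set to the sign of its weighted
    input sum, holding its current value on an exact zero.
    """
    state = np.asarray(state, dtype=np.int8)
    if not 0 <= node_index < network.n_nodes:
        raise IndexError(f"node index {node_index} out of range")
    if network.cytokine_mask[node_index]:
        raise ValueError("cytokine nodes are clamped and cannot be updated")
    inputs = _full_inputs(network.adjacency, state[None, :].astype(float), asym)
    s = inputs[0, node_index]
    out = state.copy()
    if s > 0:
        out[node_index] = 1
    elif s < 0:
        out[node_index] = -1
    return out


def find_steady_states(
    network: SignedNetwork,
    config: SimulationConfig,
    asym: AsymmetricWeight | None = None,
) -> SteadyStateDistribution:
    """Monte-Carlo steady-state distribution of ``network``.

    Per replicate: draw ``n_initial_conditions`` states uniformly over
    {-1, +1}^n (cytokines forced +1, sampling with replacement), relax each
    under random asynchronous updates, discard trajectories that have not
    reached a fixed point within ``max_steps`` single-node updates, and
    tabulate relative frequencies over the converged remainder.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    per_rep: list[dict[bytes, int]] = []
    conv_frac = np.zeros(config.n_replicates)
    state_index: dict[bytes, int] = {}
    state_rows: list[np.ndarray] = []

    for r, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        init = _random_states(network, config.n_initial_conditions, rng)
        final, converged = _relax(network, init, config.max_steps, rng, asym)
        conv_frac[r] = converged.mean()
        counts: dict[bytes, int] = {}
        if converged.any():
            uniq, cnt = np.unique(final[converged], axis=0, return_counts=True)
            for row, c in zip(uniq, cnt):
                key = row.tobytes()
                counts[key] = int(c)
                if key not in state_index:
                    state_index[key] = len(state_rows)
                    state_rows.append(row)
        per_rep.append(counts)

    n_states = len(state_rows)
    freqs = np.zeros((n_states, config.n_replicates))
    for r, counts in enumerate(per_rep):
        total = sum(counts.values())
        if total:
            for key, c in counts.items():
                freqs[state_index[key], r] = c / total

    states = (
        np.stack(state_rows)
        if state_rows
        else np.zeros((0, network.n_nodes), dtype=np.int8)
    )
    return SteadyStateDistribution(
        states=states,
        freqs=freqs,
        converged_fraction=conv_frac,
        node_names=list(network.node_names),
        core_mask=network.core_mask,
    )


def _all_states(network: SignedNetwork, chunk: int = 1 << 16):
    """Yield chunks of the full ±1 state space (cytokines clamped +1)."""
    free = np.flatnonzero(~network.cytokine_mask)
    m = len(free)
    if m > _ENUM_MAX_NODES:
        raise ValueError(
            f"{m} free nodes is too many for exhaustive 2^n enumeration"
        )
    n = network.n_nodes
    total = 1 << m
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        bits = (codes[:, None] >> np.arange(m)) & 1
        states = np.ones((len(codes), n), dtype=np.int8)
        states[:, free] = (2 * bits - 1).astype(np.int8)
        yield states


def enumerate_fixed_points(
    network: SignedNetwork, asym: AsymmetricWeight | None = None
) -> np.ndarray:
    """All fixed points of the asynchronous dynamics, by 2^n enumeration.

    Serves as the exact oracle against which the Monte-Carlo support is
    checked.  Returns an array of ±1 rows (possibly empty).
    """
    updatable = _updatable_indices(network)
    found = []
    for states in _all_states(network):
        mask = _is_fixed(network.adjacency, states.astype(float), updatable, asym)
        if mask.any():
            found.append(states[mask])
    if not found:
        return np.zeros((0, network.n_nodes), dtype=np.int8)
    return np.concatenate(found, axis=0)


def build_state_transition_graph(
    network: SignedNetwork, asym: AsymmetricWeight | None = None
) -> nx.DiGraph:
    """Directed graph over the full state space under single-node updates.

    Vertices are ±1 state tuples.  An edge u -> v exists when some single
    asynchronous update maps u to v with v != u.  Each vertex carries:

    ``self_consistent``
        per-node tuple, True where updating that node leaves u unchanged;
    ``stable``
        True when u has no outgoing edge (a fixed point);
    ``metastable``
        True when u is not stable but would be a fixed point with its
        self-regulation contributions removed — i.e. the inter-node
        regulation sustains the pattern while a self-edge drives it away.
    """
    updatable = _updatable_indices(network)
    adjacency = network.adjacency
    noself = adjacency.copy()
    np.fill_diagonal(noself, 0.0)
    g = nx.DiGraph()
    for states in _all_states(network, chunk=1 << 12):
        inputs = _full_inputs(adjacency, states.astype(float), asym)
        inputs_noself = _full_inputs(noself, states.astype(float), asym)
        for row, inp, inp_ns in zip(states, inputs, inputs_noself):
            u = tuple(int(x) for x in row)
            cons = row * inp >= 0
            cons[network.cytokine_mask] = True
            stable = bool(cons[updatable].all())
            cons_ns = row * inp_ns >= 0
            metastable = (not stable) and bool(cons_ns[updatable].all())
            g.add_node(
                u,
                self_consistent=tuple(bool(c) for c in cons),
                stable=stable,
                metastable=metastable,
            )
            for j in updatable:
                if not cons[j]:
                    v = list(u)
                    v[j] = 1 if inp[j] > 0 else -1
                    g.add_edge(u, tuple(v))
    return g


def hamming_perturbation(
    network: SignedNetwork,
    config: SimulationConfig,
    asym: AsymmetricWeight | None = None,
) -> dict[tuple[tuple[int, ...], int], list[tuple[tuple[int, ...], float, int]]]:
    """Relaxation outcomes of single-bit flips of every fixed point.

    For each enumerated fixed point and each flippable node, the flipped
    state is relaxed ``n_initial_conditions`` times under independent
    asynchronous schedules.  The result maps ``(fixed_point, flipped_node)``
    to a list of ``(reached_state, probability, hamming_distance_from_
    origin)`` tuples over converged relaxations.
    """
    fps = enumerate_fixed_points(network, asym)
    rng = np.random.default_rng(config.seed)
    out: dict = {}
    for fp in fps:
        origin = tuple(int(x) for x in fp)
        for j in _updatable_indices(network):
            start = fp.copy()
            start[j] = -start[j]
            batch = np.tile(start, (config.n_initial_conditions, 1))
            final, converged = _relax(network, batch, config.max_steps, rng, asym)
            results: list[tuple[tuple[int, ...], float, int]] = []
            if converged.any():
                uniq, cnt = np.unique(final[converged], axis=0, return_counts=True)
                total = cnt.sum()
                for row, c in zip(uniq, cnt):
                    reached = tuple(int(x) for x in row)
                    dist = int(np.sum(row != fp))
                    results.append((reached, c / total, dist))
            out[(origin, int(j))] = sorted(results, key=lambda t: -t[1])
    return out


def k_frequencies(
    dist: SteadyStateDistribution, focal_node: str | None = None
) -> np.ndarray | tuple[np.ndarray, float]:
    """F(k) over core nodes; optionally also F_A(1) for a named node.

    With ``focal_node`` given, returns ``(F, F_A(1))``; otherwise just the
    F(k) array (index k = 0..n_core).  An empty distribution yields an
    all-zero F.
    """
    fk = dist.k_frequencies()
    if focal_node is None:
        return fk
    return fk, dist.single_positive_frequency(focal_node)


def theorem_k_values(n: int) -> set[int]:
    """Admissible high-node counts of toggle-n fixed points.

    n/2 for even n; (n-1)/2 and (n+1)/2 for odd n.  Used by the exhaustive
    verification of the convergence theorem.
    """
    if n % 2 == 0:
        return {n // 2}
    return {(n - 1) // 2, (n + 1) // 2}


def fixed_point_k_counts(states: np.ndarray, core_mask: np.ndarray) -> np.ndarray:
    """High-core-node count of each fixed point row."""
    if states.shape[0] == 0:
        return np.zeros(0, dtype=int)
    return (states[:, core_mask] > 0).sum(axis=1)
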