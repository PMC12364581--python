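"""Multi-level extension of the Ising update for team networks.

Each node takes one of 2l values {-1, ..., -1/l, +1/l, ..., +1} (zero is
excluded; l = 1 recovers the Boolean +/-1 space, l = 2 the "four-level"
model with values {-1, -0.5, +0.5, +1}).  The update of node j computes
the in-degree-normalized input

    s = sum_i Adj_ij * x_i / d_j,

where d_j counts the nonzero incoming weights of j (self-edges included),
and maps s onto the level ladder: |s| in ((k-1)/l, k/l] yields level k/l
with the sign of s, and s = 0 holds the current value.  Nodes with no
regulators hold their value.

Internally states are stored as *integer levels* in {-l..-1, 1..l} so all
bracket comparisons are exact integer arithmetic (the input sum times l
equals an integer over d_j for sign-valued adjacencies), never floating-
point boundary tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boolean_sim import SimulationConfig
from .network import SignedNetwork


@dataclass(frozen=True)
class MultiLevelState:
    """A multi-level expression state: per-node values in {±k/l : k=1..l}."""

    values: tuple[float, ...]
    l: int

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("l must be >= 1")
        for v in self.values:
            k = round(abs(v) * self.l)
            if k < 1 or k > self.l or abs(abs(v) - k / self.l) > 1e-12:
                raise ValueError(
                    f"value {v} is not a multiple ±k/{self.l} with 1<=k<={self.l}"
                )

    def levels(self) -> np.ndarray:
        return np.array(
            [int(round(v * self.l)) for v in self.values], dtype=np.int64
        )

    @classmethod
    def from_levels(cls, levels: np.ndarray, l: int) -> "MultiLevelState":
        return cls(values=tuple(float(k) / l for k in levels), l=l)


def _integer_adjacency(network: SignedNetwork) -> np.ndarray:
    adj = network.adjacency
    adj_int = np.rint(adj).astype(np.int64)
    if not np.allclose(adj, adj_int):
        raise ValueError(
            "multi-level updates require integer-valued edge weights"
        )
    return adj_int


def _in_degrees(adj_int: np.ndarray) -> np.ndarray:
    return np.count_nonzero(adj_int, axis=0)


def _next_levels(
    levels: np.ndarray, adj_int: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Updated level of every node of every state row (hold rules applied)."""
    N = levels @ adj_int  # N[t, j] = l * d_j * s_j, an integer
    d_safe = np.maximum(d, 1)
    mag = -(-np.abs(N) // d_safe)  # ceil(|N| / d)
    new = np.sign(N) * mag
    hold = (N == 0) | (d == 0)
    return np.where(hold, levels, new)


def multilevel_update(
    network: SignedNetwork, state: MultiLevelState, node_index: int
) -> MultiLevelState:
    """One asynchronous multi-level update of a single node."""
    adj_int = _integer_adjacency(network)
    d = _in_degrees(adj_int)
    levels = state.levels()
    if not 0 <= node_index < network.n_nodes:
        raise IndexError(f"node index {node_index} out of range")
    if d[node_index] == 0:
        warnings.warn(
            f"node {network.node_names[node_index]!r} has no regulators; "
            "holding its value",
            stacklevel=2,
        )
        return state
    new = _next_levels(levels[None, :], adj_int, d)[0]
    out = levels.copy()
    out[node_index] = new[node_index]
    return MultiLevelState.from_levels(out, state.l)


@dataclass
class MultiLevelDistribution:
    """Fixed points of the multi-level dynamics with frequencies.

    ``levels`` holds integer-level rows; values are ``levels / l``.
    """

    levels: np.ndarray             # (S, n) int
    l: int
    freqs: np.ndarray              # (S, R)
    converged_fraction: np.ndarray
    node_names: list[str]
    core_mask: np.ndarray
    teams: dict[str, list[str]] | None

    @property
    def n_states(self) -> int:
        return self.levels.shape[0]

    def values(self) -> np.ndarray:
        return self.levels / self.l

    def mean_freqs(self) -> np.ndarray:
        return self.freqs.mean(axis=1) if self.n_states else np.zeros(0)

    def max_expression(self) -> float:
        """Largest |value| attained in any fixed point of the run."""
        if self.n_states == 0:
            return 1.0
        return float(np.abs(self.values()).max())

    def team_scores(self) -> np.ndarray:
        """Per-state per-team mean expression (states x teams)."""
        if self.teams is None:
            raise ValueError("network has no team annotation")
        vals = self.values()
        cols = []
        for members in self.teams.values():
            idx = [self.node_names.index(m) for m in members]
            cols.append(vals[:, idx].mean(axis=1))
        return np.stack(cols, axis=1) if cols else np.zeros((self.n_states, 0))

    def profile_frequencies(self, normalization: str = "state") -> dict[str, float]:
        """Total frequency of each discretized team-score profile.

        Team scores are normalized by the maximum |expression| attained
        either within each state (``normalization="state"``, the default)
        or across all fixed points of the run (``"run"``), then mapped to
        symbols 2 / 0 / 1 for exactly +1 / exactly -1 / strictly between.
        Profiles are symbol multisets sorted descending (e.g. ``"22000"``).
        """
        if normalization not in ("state", "run"):
            raise ValueError("normalization must be 'state' or 'run'")
        if self.n_states == 0:
            return {}
        scores = self.team_scores()
        freqs = self.mean_freqs()
        run_max = self.max_expression()
        vals = self.values()
        out: dict[str, float] = {}
        for s in range(self.n_states):
            max_expr = (
                run_max
                if normalization == "run"
                else float(np.abs(vals[s]).max())
            )
            prof = _profile_string(scores[s], max_expr)
            out[prof] = out.get(prof, 0.0) + float(freqs[s])
        return dict(sorted(out.items(), key=lambda kv: -kv[1]))


def _profile_string(scores: np.ndarray, max_expr: float, tol: float = 1e-9) -> str:
    symbols = []
    for s in scores:
        norm = s / max_expr if max_expr else 0.0
        if norm >= 1.0 - tol:
            symbols.append("2")
        elif norm <= -1.0 + tol:
            symbols.append("0")
        else:
            symbols.append("1")
    return "".join(sorted(symbols, reverse=True))


def discretize_profile(
    state: MultiLevelState,
    network: SignedNetwork,
    max_expression: float | None = None,
) -> str:
    """Discretized team-score profile string of a single state.

    Scores are normalized by ``max_expression`` (default: the largest
    |value| within the state itself) and mapped to 2 / 1 / 0; the profile
    lists the symbols sorted descending, matching labels like ``22000``.
    """
    teams = network.team_indices()
    vals = np.array(state.values)
    if max_expression is None:
        max_expression = float(np.abs(vals).max())
    scores = np.array([vals[idx].mean() for idx in teams.values()])
    return _profile_string(scores, max_expression)


def _is_fixed_ml(
    levels: np.ndarray, adj_int: np.ndarray, d: np.ndarray, updatable: np.ndarray
) -> np.ndarray:
    new = _next_levels(levels, adj_int, d)
    return (new[:, updatable] == levels[:, updatable]).all(axis=1)


def find_multilevel_steady_states(
    network: SignedNetwork,
    l: int,
    config: SimulationConfig,
) -> MultiLevelDistribution:
    """Monte-Carlo fixed-point distribution under the 2l-level dynamics.

    Mirrors the Boolean driver: per replicate, initial conditions are
    drawn uniformly over the 2l levels per node, relaxed by asynchronous
    single-node updates until fixed or ``max_steps`` is exhausted, and
    frequencies are tabulated over converged trajectories.  With l = 1
    this reduces exactly to the Boolean Ising dynamics.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    adj_int = _integer_adjacency(network)
    d = _in_degrees(adj_int)
    updatable = np.flatnonzero(~network.cytokine_mask)
    n = network.n_nodes
    level_choices = np.concatenate(
        [np.arange(-l, 0), np.arange(1, l + 1)]
    ).astype(np.int64)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    per_rep: list[dict[bytes, int]] = []
    conv_frac = np.zeros(config.n_replicates)
    state_index: dict[bytes, int] = {}
    state_rows: list[np.ndarray] = []

    for r, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        S = rng.choice(level_choices, size=(config.n_initial_conditions, n))
        S[:, network.cytokine_mask] = l
        ids = np.arange(config.n_initial_conditions)
        final = S.copy()
        converged = np.zeros(config.n_initial_conditions, dtype=bool)
        steps_done = 0
        n_upd = len(updatable)
        while len(ids):
            fixed = _is_fixed_ml(S, adj_int, d, updatable)
            if fixed.any():
                done = ids[fixed]
                final[done] = S[fixed]
                converged[done] = True
                keep = ~fixed
                S, ids = S[keep], ids[keep]
            if not len(ids) or steps_done >= config.max_steps:
                break
            burst = min(n_upd, config.max_steps - steps_done)
            t_idx = np.arange(len(ids))
            for _ in range(burst):
                nodes = updatable[rng.integers(0, n_upd, len(ids))]
                N = np.einsum("ti,it->t", S, adj_int[:, nodes])
                dn = d[nodes]
                ok = (N != 0) & (dn > 0)
                mag = -(-np.abs(N) // np.maximum(dn, 1))
                new = np.sign(N) * mag
                cur = S[t_idx, nodes]
                S[t_idx, nodes] = np.where(ok, new, cur)
            steps_done += burst

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

    levels = (
        np.stack(state_rows) if state_rows else np.zeros((0, n), dtype=np.int64)
    )
    return MultiLevelDistribution(
        levels=levels,
        l=l,
        freqs=freqs,
        converged_fraction=conv_frac,
        node_names=list(network.node_names),
        core_mask=network.core_mask,
        teams=network.teams,
    )


def enumerate_multilevel_fixed_points(
    network: SignedNetwork, l: int
) -> np.ndarray:
    """All multi-level fixed points by exhaustive (2l)^n enumeration.

    Exact oracle for small networks; returns integer-level rows.
    """
    adj_int = _integer_adjacency(network)
    d = _in_degrees(adj_int)
    updatable = np.flatnonzero(~network.cytokine_mask)
    n = network.n_nodes
    level_choices = np.concatenate([np.arange(-l, 0), np.arange(1, l + 1)])
    total = (2 * l) ** n
    if total > 4_000_000:
        raise ValueError("state space too large for exhaustive enumeration")
    grids = np.meshgrid(*([level_choices] * n), indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    if network.cytokine_mask.any():
        keep = (states[:, network.cytokine_mask] == l).all(axis=1)
        states = states[keep]
    mask = _is_fixed_ml(states, adj_int, d, updatable)
    return states[mask]
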