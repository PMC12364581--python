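"""Generators for the network families under study.

* toggle-n: fully connected mutual-inhibition networks, optionally with
  self-activation or self-inhibition on every node;
* impurity variants: toggle-n with a chosen number of inhibitions flipped
  to activations, filtered down to pairwise non-isomorphic topologies;
* team networks: intra-team activation, inter-team inhibition, with equal
  or randomly unequal team sizes;
* embeddings: a toggle placed inside a random directed host graph with
  random signed cross-regulation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import ROLE_CORE, ROLE_EMBEDDING, SignedNetwork

SELF_NONE = "none"
SELF_ACTIVATION = "activation"
SELF_INHIBITION = "inhibition"

# non-isomorphic variant caps used in the impurity analysis
_IMPURITY_CAPS = {2: 100, 3: 100, 4: 100, 5: 100, 6: 50}


@dataclass(frozen=True)
class TeamSpec:
    """Team partition of a fully connected team network.

    ``sizes[i]`` is the member count of team ``i``; all sizes must be >= 1.
    """

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) < 1:
            raise ValueError("need at least one team")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every team needs at least one member")

    @property
    def n_teams(self) -> int:
        return len(self.sizes)

    @property
    def n_nodes(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Random host graph parameters for embedding experiments.

    ``embedding_size`` host nodes, ``embedding_density`` average edges per
    host node (so ``size * density`` directed host edges), and
    ``n_replicates`` independent random hosts.
    """

    embedding_size: int = 10
    embedding_density: int = 2
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if self.embedding_size < 1:
            raise ValueError("embedding_size must be >= 1")
        n, m = self.embedding_size, self.n_edges
        if m > n * (n - 1):
            raise ValueError(
                f"{m} edges exceed the simple-digraph maximum "
                f"{n * (n - 1)} for {n} nodes"
            )

    @property
    def n_edges(self) -> int:
        return self.embedding_size * self.embedding_density


def _node_names(n: int) -> list[str]:
    return [f"N{i + 1}" for i in range(n)]


def make_toggle(n: int, self_regulation: str = SELF_NONE) -> SignedNetwork:
    """Toggle-n: every ordered pair of distinct nodes joined by inhibition.

    The diagonal is 0, +1 or -1 for no self-regulation, self-activation or
    self-inhibition respectively.
    """
    if n < 2:
        raise ValueError("a toggle network needs at least 2 nodes")
    diag = {SELF_NONE: 0.0, SELF_ACTIVATION: 1.0, SELF_INHIBITION: -1.0}
    if self_regulation not in diag:
        raise ValueError(f"unknown self_regulation {self_regulation!r}")
    adj = -np.ones((n, n)) + (diag[self_regulation] + 1.0) * np.eye(n)
    return SignedNetwork(node_names=_node_names(n), adjacency=adj)


def _activation_digraph(network: SignedNetwork) -> nx.DiGraph:
    """Reduce a signed network to the unweighted digraph of its activations.

    All nodes are kept so that isomorphism compares like with like even
    when no activations are present.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(network.n_nodes))
    rows, cols = np.nonzero(network.adjacency > 0)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return g


def make_impurity_variants(
    n: int, n_imp: int, max_variants: int | None = None, seed: int = 0
) -> list[SignedNetwork]:
    """Toggle-n variants with exactly ``n_imp`` inhibitions flipped to +1.

    Returns pairwise non-isomorphic variants, where isomorphism is judged
    on the activation-only unweighted digraph.  When the number of flip
    combinations is enumerable (< ~200k) every combination is tested and
    the result capped afterwards; otherwise combinations are sampled
    uniformly without replacement before filtering.  Default caps: 100
    variants for n <= 5, 50 for n = 6; n > 6 is unsupported (the
    combination count explodes).
    """
    if n > 6:
        raise ValueError(
            "impurity analysis is unsupported for n > 6: the number of "
            "edge combinations is combinatorially infeasible"
        )
    if n < 2:
        raise ValueError("need n >= 2")
    n_edges = n * (n - 1)
    if not 0 <= n_imp <= n_edges:
        raise ValueError(f"n_imp must be in [0, {n_edges}]")
    if max_variants is None:
        max_variants = _IMPURITY_CAPS[n]

    base = make_toggle(n)
    offdiag = [(i, j) for i in range(n) for j in range(n) if i != j]
    n_comb = math.comb(n_edges, n_imp)

    def variant(combo: tuple[int, ...]) -> SignedNetwork:
        net = base.copy()
        for idx in combo:
            i, j = offdiag[idx]
            net.adjacency[i, j] = 1.0
        return net

    if n_comb <= 200_000:
        combos = itertools.combinations(range(n_edges), n_imp)
    else:  # sample-then-filter
        rng = np.random.default_rng(seed)
        picked: set[tuple[int, ...]] = set()
        budget = 50 * max_variants
        while len(picked) < budget:
            picked.add(tuple(sorted(rng.choice(n_edges, n_imp, replace=False))))
        combos = iter(sorted(picked))

    kept: list[SignedNetwork] = []
    kept_graphs: list[nx.DiGraph] = []
    for combo in combos:
        net = variant(tuple(combo))
        g = _activation_digraph(net)
        if any(nx.is_isomorphic(g, h) for h in kept_graphs):
            continue
        kept.append(net)
        kept_graphs.append(g)
        if len(kept) >= max_variants:
            break
    return kept


def make_team_network(spec: TeamSpec) -> SignedNetwork:
    """Fully connected team network: +1 within teams, -1 across, 0 diagonal.

    Team membership is recorded on the returned network (labels ``T1``,
    ``T2``, ...).  A single team yields an all-activation clique, which is
    a degenerate but legal input.
    """
    n = spec.n_nodes
    team_of = np.repeat(np.arange(spec.n_teams), spec.sizes)
    adj = np.where(team_of[:, None] == team_of[None, :], 1.0, -1.0)
    np.fill_diagonal(adj, 0.0)
    names = _node_names(n)
    teams = {
        f"T{t + 1}": [names[i] for i in np.flatnonzero(team_of == t)]
        for t in range(spec.n_teams)
    }
    return SignedNetwork(node_names=names, adjacency=adj, teams=teams)


def sample_unequal_teams(
    n_teams: int, mean_size: int, n_networks: int, seed: int = 0
) -> list[TeamSpec]:
    """Random unequal team splits with a fixed total of members.

    Sizes are drawn from a multinomial with ``mean_size * n_teams`` trials
    and equal cell probabilities, rejecting draws in which any team is
    empty or any team has exactly the mean size (so every sampled split is
    strictly unequal).
    """
    if n_teams < 2:
        raise ValueError("need at least 2 teams")
    total = n_teams * mean_size
    if mean_size < 2:
        # with mean 1 every nonempty team of a size-n total must hit the
        # mean somewhere: total n over n teams, all >=1 and != 1 impossible
        raise ValueError(
            "mean_size < 2 leaves no split with all teams nonempty and "
            "none at the mean size"
        )
    rng = np.random.default_rng(seed)
    specs: list[TeamSpec] = []
    max_draws = 10_000 * max(n_networks, 1)
    draws = 0
    while len(specs) < n_networks:
        if draws >= max_draws:
            raise RuntimeError(
                "rejection sampling failed to find enough valid splits"
            )
        sizes = rng.multinomial(total, np.full(n_teams, 1.0 / n_teams))
        draws += 1
        if (sizes == 0).any() or (sizes == mean_size).any():
            continue
        specs.append(TeamSpec(sizes=tuple(int(s) for s in sizes)))
    return specs


def embed_in_random(
    network: SignedNetwork, spec: EmbeddingSpec, seed: int = 0
) -> list[SignedNetwork]:
    """Embed ``network`` into random directed host graphs.

    Each replicate keeps the toggle adjacency intact (roles ``core``),
    adds ``embedding_size`` host nodes (roles ``embedding``) wired as a
    uniform random simple digraph with ``size * density`` edges and edge
    weights drawn uniformly from {-1, +1}, and assigns every ordered
    (core, host) and (host, core) pair a weight drawn uniformly from
    {-1, 0, +1}.
    """
    seeds = np.random.SeedSequence(seed).spawn(spec.n_replicates)
    out = []
    n_core = network.n_nodes
    n_host = spec.embedding_size
    host_names = [f"R{i + 1}" for i in range(n_host)]
    for child in seeds:
        rng = np.random.default_rng(child)
        host = nx.gnm_random_graph(
            n_host, spec.n_edges, directed=True,
            seed=int(rng.integers(2**31)),
        )
        n = n_core + n_host
        adj = np.zeros((n, n))
        adj[:n_core, :n_core] = network.adjacency
        for u, v in host.edges:
            adj[n_core + u, n_core + v] = rng.choice((-1.0, 1.0))
        cross = rng.choice((-1.0, 0.0, 1.0), size=(n_core, n_host))
        adj[:n_core, n_core:] = cross
        adj[n_core:, :n_core] = rng.choice((-1.0, 0.0, 1.0), size=(n_host, n_core))
        out.append(
            SignedNetwork(
                node_names=list(network.node_names) + host_names,
                adjacency=adj,
                roles=[ROLE_CORE] * n_core + [ROLE_EMBEDDING] * n_host,
            )
        )
    return out
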