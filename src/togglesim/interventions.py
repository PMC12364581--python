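"""Perturbations that drive directed differentiation.

Three interventions are modelled:

* random edge weights — every regulatory link's magnitude is scaled by an
  independent U(0,1) draw (biological noise in interaction strength);
* asymmetric weight W — the inhibitions *from* one focal node onto the
  rest are strengthened to W, but only while that node is high (an
  epigenetic-reprogramming abstraction);
* cytokine signalling — an external, constitutively high input of
  strength W_C that activates the focal node and, optionally, inhibits
  every other core node.

:func:`threshold_scan` measures the frequency of the focal-node-only-high
state, F_A(1), over an integer (W, W_C) grid and extracts the minimal
weight and signalling strength at which complete differentiation
(F_A(1) = 1) becomes attainable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boolean_sim import (
    AsymmetricWeight,
    SimulationConfig,
    find_steady_states,
)
from .network import ROLE_CYTOKINE, SignedNetwork

MODE_ACTIVATE_ONLY = "activate_only"
MODE_ACTIVATE_AND_INHIBIT = "activate_and_inhibit"


def randomize_edge_weights(
    network: SignedNetwork, n_sets: int = 100, seed: int = 0
) -> list[SignedNetwork]:
    """Scale every nonzero edge weight by an independent U(0,1) draw.

    Returns ``n_sets`` networks sharing the sign pattern of the input;
    zero entries stay zero.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    nz = network.adjacency != 0
    for _ in range(n_sets):
        net = network.copy()
        scale = rng.uniform(0.0, 1.0, size=net.adjacency.shape)
        net.adjacency[nz] *= scale[nz]
        out.append(net)
    return out


def apply_asymmetric_weight(
    network: SignedNetwork, focal_node: str, weight: float
) -> AsymmetricWeight:
    """State-dependent strengthening of the focal node's outgoing edges.

    While the focal node is high its off-diagonal outgoing weights count
    as ``weight`` times their baseline; while it is low they keep their
    baseline value.  The returned rule plugs into every simulation entry
    point (``find_steady_states``, ``enumerate_fixed_points``, ...) via
    their ``asym`` argument, leaving the adjacency matrix untouched.
    """
    if weight < 1:
        raise ValueError("asymmetric weight must be >= 1")
    idx = network.index(focal_node)
    if network.cytokine_mask[idx]:
        raise ValueError("cannot place asymmetric weight on a cytokine node")
    return AsymmetricWeight(focal_index=idx, weight=float(weight))


def attach_cytokine(
    network: SignedNetwork,
    target: str,
    strength: float,
    mode: str = MODE_ACTIVATE_ONLY,
    name: str | None = None,
) -> SignedNetwork:
    """Add a clamped-high cytokine node signalling onto ``target``.

    The cytokine activates the target with weight ``+strength``; in
    ``activate_and_inhibit`` mode it additionally inhibits every other
    core node with ``-strength``.  It receives no regulation itself and
    frequency statistics continue to count core nodes only.
    """
    if mode not in (MODE_ACTIVATE_ONLY, MODE_ACTIVATE_AND_INHIBIT):
        raise ValueError(f"unknown cytokine mode {mode!r}")
    if strength < 0:
        raise ValueError("signalling strength must be >= 0")
    t_idx = network.index(target)
    if not network.core_mask[t_idx]:
        raise ValueError("cytokine target must be a core node")
    out_weights = {target: strength}
    if mode == MODE_ACTIVATE_AND_INHIBIT:
        for j in np.flatnonzero(network.core_mask):
            if j != t_idx:
                out_weights[network.node_names[j]] = -strength
    return attach_signalling_node(
        network, out_weights, name=name or f"Cyt_{target}"
    )


def attach_signalling_node(
    network: SignedNetwork,
    out_weights: dict[str, float],
    name: str,
) -> SignedNetwork:
    """Add a clamped-high external input with arbitrary outgoing weights.

    ``out_weights`` maps core-node names to signed weights from the new
    node.  The node is cytokine-tagged (no incoming regulation, clamped
    high, excluded from frequency statistics).
    """
    if name in network.node_names:
        raise ValueError(f"node {name!r} already exists")
    n = network.n_nodes
    adj = np.zeros((n + 1, n + 1))
    adj[:n, :n] = network.adjacency
    for target, w in out_weights.items():
        adj[n, network.index(target)] = w
    return SignedNetwork(
        node_names=list(network.node_names) + [name],
        adjacency=adj,
        roles=list(network.roles) + [ROLE_CYTOKINE],
        teams=None if network.teams is None else dict(network.teams),
    )


@dataclass
class ScanResult:
    """F_A(1) over a (W, W_C) grid plus extracted thresholds.

    ``grid`` is a tidy frame with columns ``W``, ``WC``, ``FA1``, ``ci``.
    ``w_threshold`` is the minimal W for which some scanned W_C reaches
    F_A(1) = 1 (within ``tol``); ``wc_threshold`` the minimal W_C for
    which some scanned W does.  ``None`` means no scanned combination
    achieved complete differentiation.
    """

    grid: pd.DataFrame
    w_threshold: float | None
    wc_threshold: float | None
    focal_node: str
    mode: str
    tol: float = 1e-6


def threshold_scan(
    network: SignedNetwork,
    focal_node: str,
    mode: str = MODE_ACTIVATE_ONLY,
    w_range=range(1, 11),
    wc_range=range(0, 11),
    config: SimulationConfig | None = None,
    tol: float = 1e-6,
) -> ScanResult:
    """Scan F_A(1) over the (edge weight, signalling strength) grid.

    Every (W, W_C) cell attaches a cytokine of strength W_C onto the
    focal node, applies the state-dependent asymmetric weight W, and runs
    an independent Monte-Carlo simulation.  Complete differentiation is
    taken as F_A(1) >= 1 - tol (saturation at exactly 1 is what the
    dynamics produce when they reach it at all).
    """
    if config is None:
        config = SimulationConfig(n_initial_conditions=10_000, n_replicates=1)
    w_values = list(w_range)
    wc_values = list(wc_range)
    if not w_values or not wc_values:
        raise ValueError("W and W_C ranges must be nonempty")

    seeds = np.random.SeedSequence(config.seed).spawn(
        len(w_values) * len(wc_values)
    )
    rows = []
    cell = 0
    for w in w_values:
        asym = apply_asymmetric_weight(network, focal_node, w)
        for wc in wc_values:
            net = attach_cytokine(network, focal_node, wc, mode=mode)
            cell_config = SimulationConfig(
                n_initial_conditions=config.n_initial_conditions,
                max_steps=config.max_steps,
                n_replicates=config.n_replicates,
                seed=int(seeds[cell].generate_state(1)[0] % (2**31)),
            )
            cell += 1
            dist = find_steady_states(net, cell_config, asym=asym)
            fa1 = dist.single_positive_frequency(focal_node)
            ci = 0.0
            if dist.freqs.shape[1] > 1:
                # CI of FA1 across replicates
                per_rep = np.zeros(dist.freqs.shape[1])
                mean = dist.mean_freqs()
                for s in range(dist.n_states):
                    if mean[s] > 0 and _is_single_positive(dist, s, focal_node):
                        per_rep += dist.freqs[s]
                ci = float(
                    1.96 * per_rep.std(ddof=1) / np.sqrt(len(per_rep))
                )
            rows.append({"W": w, "WC": wc, "FA1": fa1, "ci": ci})

    grid = pd.DataFrame(rows)
    hit = grid[grid["FA1"] >= 1.0 - tol]
    w_thr = float(hit["W"].min()) if len(hit) else None
    wc_thr = float(hit["WC"].min()) if len(hit) else None
    return ScanResult(
        grid=grid,
        w_threshold=w_thr,
        wc_threshold=wc_thr,
        focal_node=focal_node,
        mode=mode,
        tol=tol,
    )


def _is_single_positive(dist, s: int, node_name: str) -> bool:
    idx = dist.node_names.index(node_name)
    core_idx = np.flatnonzero(dist.core_mask)
    high = np.flatnonzero(dist.states[s, core_idx] > 0)
    return len(high) == 1 and core_idx[high[0]] == idx
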