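"""Signed, weighted regulatory network container.

The central object is :class:`SignedNetwork`: a node-labelled adjacency
matrix in which entry ``(i, j)`` is the weight of the regulation exerted
*by* node ``i`` *onto* node ``j`` (positive = activation, negative =
inhibition, zero = no interaction).  Every node carries a role tag:

``core``
    a member of the regulatory circuit under study (toggle / team nodes);
    frequency statistics such as F(k) count high nodes among these only.
``embedding``
    a node of a random host graph the circuit was embedded into.
``cytokine``
    an external signalling input, clamped at the high state and never
    regulated by anything (its incoming column is all zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLE_CORE = "core"
ROLE_EMBEDDING = "embedding"
ROLE_CYTOKINE = "cytokine"
_VALID_ROLES = {ROLE_CORE, ROLE_EMBEDDING, ROLE_CYTOKINE}


@dataclass
class SignedNetwork:
    """A directed, signed, real-weighted regulatory network.

    Parameters
    ----------
    node_names :
        Ordered node labels.  The order fixes the coordinate order of every
        state vector used downstream.
    adjacency :
        Square real matrix; ``adjacency[i, j]`` is the weight of the edge
        from ``node_names[i]`` onto ``node_names[j]``.
    roles :
        Per-node role in ``{"core", "embedding", "cytokine"}``; defaults to
        all-core.
    teams :
        Optional mapping team label -> list of member node names.  When
        present the teams must partition exactly the core nodes.
    """

    node_names: list[str]
    adjacency: np.ndarray
    roles: list[str] = field(default_factory=list)
    teams: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if not self.roles:
            self.roles = [ROLE_CORE] * len(self.node_names)
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        n = len(self.node_names)
        if len(set(self.node_names)) != n:
            raise ValueError("duplicate node names")
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} node names"
            )
        if len(self.roles) != n:
            raise ValueError("roles length does not match node count")
        bad = set(self.roles) - _VALID_ROLES
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        for idx in np.flatnonzero(np.array(self.roles) == ROLE_CYTOKINE):
            if np.any(self.adjacency[:, idx] != 0):
                raise ValueError(
                    f"cytokine node {self.node_names[idx]!r} has incoming "
                    "regulation; cytokines must have an all-zero column"
                )
        if self.teams is not None:
            members = [m for team in self.teams.values() for m in team]
            core = [
                name
                for name, role in zip(self.node_names, self.roles)
                if role == ROLE_CORE
            ]
            if sorted(members) != sorted(core):
                raise ValueError("teams must partition exactly the core nodes")
            if any(len(team) == 0 for team in self.teams.values()):
                raise ValueError("empty team")

    # -- basic queries --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"no node named {name!r}") from None

    def role_mask(self, role: str) -> np.ndarray:
        return np.array([r == role for r in self.roles], dtype=bool)

    @property
    def core_mask(self) -> np.ndarray:
        return self.role_mask(ROLE_CORE)

    @property
    def cytokine_mask(self) -> np.ndarray:
        return self.role_mask(ROLE_CYTOKINE)

    @property
    def n_core(self) -> int:
        return int(self.core_mask.sum())

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(
            node_names=list(self.node_names),
            adjacency=self.adjacency.copy(),
            roles=list(self.roles),
            teams=None
            if self.teams is None
            else {k: list(v) for k, v in self.teams.items()},
        )

    def team_indices(self) -> dict[str, list[int]]:
        """Teams as lists of node indices (requires team annotation)."""
        if self.teams is None:
            raise ValueError("network has no team annotation")
        return {
            label: [self.index(m) for m in members]
            for label, members in self.teams.items()
        }

    def is_sign_valued(self) -> bool:
        return bool(np.isin(self.adjacency, (-1.0, 0.0, 1.0)).all())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_edges = int(np.count_nonzero(self.adjacency))
        return (
            f"SignedNetwork(n_nodes={self.n_nodes}, n_edges={n_edges}, "
            f"core={self.n_core})"
        )


def state_to_string(state: np.ndarray) -> str:
    """Render a state as a ``+``/``-`` string in node order.

    Multi-level values strictly between the extremes print as ``p``/``m``
    (partially on / partially off).
    """
    out = []
    for v in np.asarray(state, dtype=float):
        if v >= 1:
            out.append("+")
        elif v <= -1:
            out.append("-")
        elif v > 0:
            out.append("p")
        else:
            out.append("m")
    return "".join(out)


def high_nodes(state: np.ndarray, names: list[str]) -> list[str]:
    """Names of the nodes at a strictly positive value in ``state``."""
    return [name for name, v in zip(names, state) if v > 0]
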