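"""Exact counting of monotone Boolean functions behind toggle-n dynamics.

A toggle-n node sees the other n-1 nodes through inhibitions only, so any
update logic compatible with the network must be a *decreasing* monotone
Boolean function (MBF) of its n-1 inputs: flipping any input from 0 to 1
can never raise the output.  The number of MBFs of s inputs is the
Dedekind number D(s) — (2, 3, 6, 20, 168, 7581) for s = 0..5 — which is
why the analysis stops at n = 6 (s = 5); n = 7, 8 are combinatorially
infeasible.

From the enumerated functions two count tables follow.  With the
canonical input b_j = (1,...,1,0,...,0) containing j ones,

* ``u_n(j)`` counts decreasing MBFs of n-1 inputs with output 0 at b_j,
* ``v_n(j)`` counts those with output 1 (so u + v = D(n-1)),

and the number of compatible function tuples f = (f_1..f_n) for which the
k-high state is a fixed point of toggle-n is the product

    phi_k = v_n(k-1)^k * u_n(k)^(n-k)      (1 <= k <= n-1),

because each of the k high nodes sees k-1 ones among its inputs and must
output 1, while each low node sees k ones and must output 0.  phi_0 =
phi_n = 1 (the constant functions).  A brute-force tally over all tuples
verifies the closed form for small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

DEDEKIND = {0: 2, 1: 3, 2: 6, 3: 20, 4: 168, 5: 7581}

_MAX_INPUTS = 5


@lru_cache(maxsize=None)
def _increasing_mbf_masks(n_inputs: int) -> tuple[int, ...]:
    """All increasing MBFs of ``n_inputs`` variables as truth-table bitmasks.

    Bit ``b`` of a mask is the output at the input whose binary code is
    ``b`` (bit i of b = value of input i).  Functions are built by depth-
    first assignment over inputs ordered by popcount: output 1 is always
    admissible, output 0 only when every immediate predecessor (one bit
    removed) already has output 0.
    """
    size = 1 << n_inputs
    order = sorted(range(size), key=lambda b: (bin(b).count("1"), b))
    preds = [
        [b & ~(1 << i) for i in range(n_inputs) if b & (1 << i)] for b in order
    ]
    values = [0] * size
    results: list[int] = []

    def rec(pos: int) -> None:
        if pos == len(order):
            mask = 0
            for b in range(size):
                if values[b]:
                    mask |= 1 << b
            results.append(mask)
            return
        b = order[pos]
        forced_one = any(values[p] for p in preds[pos])
        if not forced_one:
            values[b] = 0
            rec(pos + 1)
        values[b] = 1
        rec(pos + 1)
        values[b] = 0

    rec(0)
    return tuple(results)


def enumerate_decreasing_mbfs(n_inputs: int) -> list[int]:
    """Truth tables of all decreasing MBFs of ``n_inputs`` variables.

    A decreasing function f satisfies f(x) = g(~x) for an increasing g, so
    the enumeration complements the input codes of the increasing family.
    Returns bitmasks (bit b = output at input code b); the count equals
    the Dedekind number D(n_inputs).  Refuses n_inputs > 5, where the
    family size makes tuple-level analysis infeasible.
    """
    if n_inputs < 0:
        raise ValueError("n_inputs must be >= 0")
    if n_inputs > _MAX_INPUTS:
        raise ValueError(
            f"enumeration of decreasing MBFs is unsupported beyond "
            f"{_MAX_INPUTS} inputs (Dedekind growth)"
        )
    size = 1 << n_inputs
    full = size - 1
    out = []
    for g in _increasing_mbf_masks(n_inputs):
        f = 0
        for b in range(size):
            if g >> (full ^ b) & 1:
                f |= 1 << b
        out.append(f)
    return sorted(out)


def _canonical_input(j: int) -> int:
    """Input code with the first j variables at 1: (1..1, 0..0)."""
    return (1 << j) - 1


@dataclass(frozen=True)
class MBFCountTable:
    """u/v counts for toggle-n: outputs at inputs with j ones, j = 0..n-1."""

    n: int
    u: tuple[int, ...]
    v: tuple[int, ...]

    @property
    def dedekind(self) -> int:
        return self.u[0] + self.v[0]


@dataclass(frozen=True)
class PhiVector:
    """phi_k for k = 0..n: compatible MBF tuples fixing the k-high state."""

    n: int
    phi: tuple[int, ...]


def compute_uv_table(n: int) -> MBFCountTable:
    """Count decreasing MBFs of n-1 inputs by output at canonical inputs.

    Valid for 2 <= n <= 6.  Because an MBF compatible with the symmetric
    toggle is counted identically at any permutation of an input, the
    canonical representative (1..1, 0..0) with j ones suffices.
    """
    if not 2 <= n <= 6:
        raise ValueError("u/v tables are defined for 2 <= n <= 6")
    funcs = enumerate_decreasing_mbfs(n - 1)
    u, v = [], []
    for j in range(n):
        b = _canonical_input(j)
        ones = sum(f >> b & 1 for f in funcs)
        v.append(ones)
        u.append(len(funcs) - ones)
    return MBFCountTable(n=n, u=tuple(u), v=tuple(v))


def phi_vector(n: int) -> PhiVector:
    """Closed-form phi vector from the u/v table (2 <= n <= 6)."""
    table = compute_uv_table(n)
    phi = [1]
    for k in range(1, n):
        phi.append(table.v[k - 1] ** k * table.u[k] ** (n - k))
    phi.append(1)
    return PhiVector(n=n, phi=tuple(phi))


def brute_force_phi(n: int) -> PhiVector:
    """phi by explicit tally over every tuple of decreasing MBFs.

    Independent of the closed form: for each tuple f = (f_1..f_n) and each
    canonical state E_k (k ones followed by zeros), node j's function is
    evaluated at the other n-1 coordinates of E_k in node order and the
    tuple is counted for k when every output reproduces E_k.  Tuple space
    D(n-1)^n restricts this to n <= 3.
    """
    if not 2 <= n <= 3:
        raise ValueError("brute force is limited to n <= 3 (tuple explosion)")
    funcs = enumerate_decreasing_mbfs(n - 1)
    states = []
    for k in range(n + 1):
        states.append([1 if i < k else 0 for i in range(n)])

    # per node j and state k: the input code (other coordinates, node order)
    # and the required output
    inputs = np.zeros((n, n + 1), dtype=int)
    required = np.zeros((n, n + 1), dtype=int)
    for j in range(n):
        for k, ek in enumerate(states):
            others = [ek[i] for i in range(n) if i != j]
            code = sum(bit << pos for pos, bit in enumerate(others))
            inputs[j, k] = code
            required[j, k] = ek[j]

    counts = [0] * (n + 1)
    idx = [0] * n

    def rec(j: int, ok: list[bool]) -> None:
        if j == n:
            for k in range(n + 1):
                if ok[k]:
                    counts[k] += 1
            return
        for f in funcs:
            ok2 = [
                ok[k] and ((f >> inputs[j, k]) & 1) == required[j, k]
                for k in range(n + 1)
            ]
            if any(ok2):
                rec(j + 1, ok2)

    rec(0, [True] * (n + 1))
    return PhiVector(n=n, phi=tuple(counts))


def count_total_tuples(n: int) -> int:
    """Total number of MBF tuples compatible with toggle-n: D(n-1)^n."""
    if not 2 <= n <= 6:
        raise ValueError("defined for 2 <= n <= 6")
    return len(enumerate_decreasing_mbfs(n - 1)) ** n
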