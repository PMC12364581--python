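"""Read and write ``.topo`` network topology files.

The ``.topo`` dialect is the tab-separated edge-list format used by tools
such as RACIPE: a header line ``Source\\tTarget\\tType`` followed by one row
per directed edge, with ``Type`` 1 for activation and 2 for inhibition.

The format carries signs only.  Real-valued edge weights (randomized
weights, asymmetric weight W, signalling strength W_C) are serialized to a
JSON *sidecar* mapping ``"source->target"`` to the weight magnitude;
absence of a key means magnitude 1.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .network import SignedNetwork

_HEADER = ("source", "target", "type")


class TopoFormatError(ValueError):
    """Raised for malformed ``.topo`` input, naming the offending line."""


def read_topo(path: str | Path) -> SignedNetwork:
    """Parse a ``.topo`` file into a :class:`SignedNetwork`.

    Node order is the order of first appearance in the file (sources and
    targets interleaved); all roles default to ``core``.  A missing header
    row is tolerated with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[str, str, int, int]] = []
    start = 0
    if lines:
        first = [f.strip().lower() for f in lines[0].split("\t")]
        if first[:3] == list(_HEADER):
            start = 1
        else:
            warnings.warn(
                f"{path}: no 'Source\\tTarget\\tType' header found; "
                "assuming the first line is an edge",
                stacklevel=2,
            )
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 3:
            raise TopoFormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(fields)}: {raw!r}"
            )
        src, tgt, type_str = (f.strip() for f in fields)
        try:
            edge_type = int(type_str)
        except ValueError:
            raise TopoFormatError(
                f"{path}:{lineno}: Type must be an integer, got {type_str!r}"
            ) from None
        if edge_type not in (1, 2):
            raise TopoFormatError(
                f"{path}:{lineno}: unknown Type {edge_type} "
                "(expected 1=activation or 2=inhibition)"
            )
        rows.append((src, tgt, edge_type, lineno))

    if not rows:
        raise TopoFormatError(f"{path}: no edges found")

    names: list[str] = []
    index: dict[str, int] = {}
    for src, tgt, _, _ in rows:
        for name in (src, tgt):
            if name not in index:
                index[name] = len(names)
                names.append(name)

    adj = np.zeros((len(names), len(names)))
    seen: set[tuple[str, str]] = set()
    for src, tgt, edge_type, lineno in rows:
        if (src, tgt) in seen:
            raise TopoFormatError(
                f"{path}:{lineno}: duplicate edge {src}->{tgt}"
            )
        seen.add((src, tgt))
        adj[index[src], index[tgt]] = 1.0 if edge_type == 1 else -1.0

    return SignedNetwork(node_names=names, adjacency=adj)


def write_topo(network: SignedNetwork, path: str | Path) -> None:
    """Write the sign pattern of ``network`` as a ``.topo`` file.

    Only sign-valued networks (all entries in {-1, 0, +1}) are accepted;
    real-valued weights belong in the JSON sidecar
    (:func:`write_weight_sidecar`).  Round-trips through :func:`read_topo`
    preserve the node order and every entry.
    """
    if not network.is_sign_valued():
        raise ValueError(
            "adjacency has non-sign-valued weights; write the sign pattern "
            "with weights of magnitude 1 and serialize the magnitudes with "
            "write_weight_sidecar()"
        )
    path = Path(path)
    out = ["Source\tTarget\tType"]
    names = network.node_names
    for i, src in enumerate(names):
        for j, tgt in enumerate(names):
            w = network.adjacency[i, j]
            if w > 0:
                out.append(f"{src}\t{tgt}\t1")
            elif w < 0:
                out.append(f"{src}\t{tgt}\t2")
    path.write_text("\n".join(out) + "\n")


def write_weight_sidecar(network: SignedNetwork, path: str | Path) -> None:
    """Serialize nonzero edge-weight magnitudes as ``{"A->B": |w|}`` JSON.

    Edges of magnitude exactly 1 are omitted (the default magnitude).
    """
    weights = {}
    names = network.node_names
    for i, src in enumerate(names):
        for j, tgt in enumerate(names):
            w = network.adjacency[i, j]
            if w != 0 and abs(w) != 1:
                weights[f"{src}->{tgt}"] = abs(float(w))
    Path(path).write_text(json.dumps(weights, indent=1) + "\n")


def read_weight_sidecar(network: SignedNetwork, path: str | Path) -> SignedNetwork:
    """Return a copy of ``network`` with sidecar magnitudes applied."""
    weights = json.loads(Path(path).read_text())
    out = network.copy()
    for key, mag in weights.items():
        try:
            src, tgt = key.split("->")
        except ValueError:
            raise TopoFormatError(f"bad sidecar key {key!r}") from None
        i, j = out.index(src), out.index(tgt)
        if out.adjacency[i, j] == 0:
            raise TopoFormatError(
                f"sidecar weight for absent edge {src}->{tgt}"
            )
        out.adjacency[i, j] = np.sign(out.adjacency[i, j]) * float(mag)
    return out
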