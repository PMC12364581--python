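"""Figure-level experiment drivers, including the T-helper case study.

The T-helper (CD4+ T cell) fixture is a 5-node incomplete toggle network
over the lineage master regulators TBX21 (Th1), GATA3 (Th2), RORC (Th17),
FOXP3 (Treg) and BCL6 (TFH).  Sixteen of the twenty possible ordered
pairs are mutually inhibitory:

* TBX21, GATA3, RORC and FOXP3 mutually inhibit one another (12 edges);
* TBX21 and BCL6 mutually inhibit each other (2 edges);
* BCL6 inhibits GATA3 and RORC (2 edges);

and no inhibition of BCL6 by GATA3, RORC or FOXP3, nor of FOXP3 by BCL6,
has been reported — those four edges are absent.  A variant adds the
documented self-activation of TBX21, GATA3, RORC and FOXP3.

Exogenous cytokine stimulation is modelled generically: each cytokine of
a lineage's stimulating set activates that lineage's master regulator
with strength W_C and inhibits the other regulators with -W_C, with
documented exceptions (IFN-gamma activates FOXP3; TGF-beta activates
RORC) encoded as sign overrides that callers can replace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import netgen, topo_io
from .boolean_sim import (
    SimulationConfig,
    SteadyStateDistribution,
    find_steady_states,
)
from .interventions import (
    apply_asymmetric_weight,
    attach_signalling_node,
    randomize_edge_weights,
)
from .network import SignedNetwork, state_to_string

# lineage master regulators in canonical lineage order
LINEAGE_TFS = {
    "Th1": "TBX21",
    "Th2": "GATA3",
    "Th17": "RORC",
    "Treg": "FOXP3",
    "TFH": "BCL6",
}
LINEAGE_ORDER = ["Th1", "Th2", "Th17", "Treg", "TFH"]

# cytokines reported to stimulate each lineage
LINEAGE_CYTOKINES = {
    "Th1": ["IFNG", "IL12"],
    "Th2": ["IL4", "IL2"],
    "Th17": ["TGFB", "IL6", "IL21"],
    "Treg": ["TGFB", "IL2"],
}

# (cytokine, master regulator) pairs whose sign deviates from the generic
# activate-own / inhibit-others wiring: IFN-gamma activates FOXP3 and
# TGF-beta activates RORC
DEFAULT_CYTOKINE_OVERRIDES = {
    ("IFNG", "FOXP3"): 1.0,
    ("TGFB", "RORC"): 1.0,
}

_SELF_ACTIVATING = ["TBX21", "GATA3", "RORC", "FOXP3"]


def thelper_network(self_activation: bool = False) -> SignedNetwork:
    """The packaged 5-node T-helper master-regulator network.

    With ``self_activation`` the four regulators reported to self-activate
    (TBX21, GATA3, RORC, FOXP3) get +1 self-edges; BCL6 does not.
    """
    with resources.as_file(
        resources.files("togglesim.data") / "thelper.topo"
    ) as path:
        net = topo_io.read_topo(path)
    if self_activation:
        for name in _SELF_ACTIVATING:
            idx = net.index(name)
            net.adjacency[idx, idx] = 1.0
    return net


def fk_table(dist: SteadyStateDistribution) -> pd.DataFrame:
    """Tidy F(k) table with across-replicate mean and 95% CI."""
    n_core = int(dist.core_mask.sum())
    n_rep = dist.freqs.shape[1] if dist.n_states else 1
    per_rep = np.zeros((n_core + 1, n_rep))
    for s, k in enumerate(dist.k):
        per_rep[k] += dist.freqs[s]
    mean = per_rep.mean(axis=1)
    if n_rep > 1:
        ci = 1.96 * per_rep.std(axis=1, ddof=1) / np.sqrt(n_rep)
    else:
        ci = np.zeros(n_core + 1)
    return pd.DataFrame({"k": np.arange(n_core + 1), "F": mean, "ci": ci})


def run_fk_sweep(
    n_range=range(2, 9),
    self_regulation_modes=(netgen.SELF_NONE,),
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """F(k) versus network size for toggle-n with each self-regulation mode."""
    if config is None:
        config = SimulationConfig(n_initial_conditions=10_000)
    rows = []
    for n in n_range:
        for mode in self_regulation_modes:
            net = netgen.make_toggle(n, mode)
            dist = find_steady_states(net, config)
            table = fk_table(dist)
            for _, row in table.iterrows():
                rows.append(
                    {
                        "n": n,
                        "self_regulation": mode,
                        "k": int(row["k"]),
                        "F": row["F"],
                        "ci": row["ci"],
                        "converged_fraction": dist.converged_fraction.mean(),
                    }
                )
    return pd.DataFrame(rows)


def run_impurity_sweep(
    n: int,
    config: SimulationConfig | None = None,
    max_variants: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean F(k) over non-isomorphic impurity variants at each flip count."""
    if config is None:
        config = SimulationConfig(n_initial_conditions=10_000)
    rows = []
    for n_imp in range(n * (n - 1) + 1):
        variants = netgen.make_impurity_variants(
            n, n_imp, max_variants=max_variants, seed=seed
        )
        fks = []
        for variant in variants:
            dist = find_steady_states(variant, config)
            fks.append(fk_table(dist)["F"].to_numpy())
        fks = np.stack(fks)
        mean = fks.mean(axis=0)
        if len(variants) > 1:
            ci = 1.96 * fks.std(axis=0, ddof=1) / np.sqrt(len(variants))
        else:
            ci = np.zeros_like(mean)
        for k in range(n + 1):
            rows.append(
                {
                    "n_imp": n_imp,
                    "k": k,
                    "F": mean[k],
                    "ci": ci[k],
                    "n_variants": len(variants),
                }
            )
    return pd.DataFrame(rows)


def hybrid_label(state: np.ndarray, node_names: list[str]) -> str:
    """Name a T-helper state by the lineages whose regulator is high.

    Lineages are joined with ``/`` in the canonical order Th1, Th2, Th17,
    Treg, TFH; the all-low state is labelled ``(none)``.
    """
    tf_to_lineage = {tf: lin for lin, tf in LINEAGE_TFS.items()}
    high = {
        tf_to_lineage[name]
        for name, v in zip(node_names, state)
        if v > 0 and name in tf_to_lineage
    }
    ordered = [lin for lin in LINEAGE_ORDER if lin in high]
    return "/".join(ordered) if ordered else "(none)"


THELPER_VARIANTS = ("base", "self_activation", "random_weights", "embedded")


def run_thelper_case_study(
    variant: str = "base",
    config: SimulationConfig | None = None,
    n_sets: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Steady-state report of the T-helper network under one variant.

    ``random_weights`` averages over ``n_sets`` U(0,1) edge-weight draws
    and ``embedded`` over ``n_sets`` random host graphs (size 10, density
    2); both report the across-network mean frequency of each observed
    state.  Rows carry the ±1 state string, the hybrid lineage label, the
    high-node count k and the frequency with a 95% CI.
    """
    if variant not in THELPER_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if config is None:
        config = SimulationConfig(n_initial_conditions=10_000)

    if variant in ("base", "self_activation"):
        net = thelper_network(self_activation=variant == "self_activation")
        dist = find_steady_states(net, config)
        return _thelper_report_single(dist)

    base = thelper_network()
    if variant == "random_weights":
        networks = randomize_edge_weights(base, n_sets=n_sets, seed=seed)
    else:
        spec = netgen.EmbeddingSpec(
            embedding_size=10, embedding_density=2, n_replicates=n_sets
        )
        networks = netgen.embed_in_random(base, spec, seed=seed)

    acc: dict[str, list[float]] = {}
    meta: dict[str, tuple[str, int]] = {}
    for i, net in enumerate(networks):
        sub_config = SimulationConfig(
            n_initial_conditions=config.n_initial_conditions,
            max_steps=config.max_steps,
            n_replicates=1,
            seed=config.seed + i + 1,
        )
        dist = find_steady_states(net, sub_config)
        freqs = dist.mean_freqs()
        core_idx = np.flatnonzero(dist.core_mask)
        seen: dict[str, float] = {}
        for s in range(dist.n_states):
            core_state = dist.states[s, core_idx]
            key = state_to_string(core_state)
            seen[key] = seen.get(key, 0.0) + float(freqs[s])
            if key not in meta:
                meta[key] = (
                    hybrid_label(core_state, [dist.node_names[c] for c in core_idx]),
                    int((core_state > 0).sum()),
                )
        for key in set(acc) | set(seen):
            acc.setdefault(key, [0.0] * i)
            acc[key].append(seen.get(key, 0.0))

    rows = []
    for key, values in acc.items():
        values = np.array(values)
        label, k = meta[key]
        ci = (
            1.96 * values.std(ddof=1) / np.sqrt(len(values))
            if len(values) > 1
            else 0.0
        )
        rows.append(
            {"state": key, "label": label, "k": k,
             "frequency": values.mean(), "ci": ci}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("frequency", ascending=False)
        .reset_index(drop=True)
    )


def _thelper_report_single(dist: SteadyStateDistribution) -> pd.DataFrame:
    freqs = dist.mean_freqs()
    ci = dist.ci95()
    core_idx = np.flatnonzero(dist.core_mask)
    rows = []
    for s in range(dist.n_states):
        core_state = dist.states[s, core_idx]
        rows.append(
            {
                "state": state_to_string(core_state),
                "label": hybrid_label(
                    core_state, [dist.node_names[c] for c in core_idx]
                ),
                "k": int((core_state > 0).sum()),
                "frequency": float(freqs[s]),
                "ci": float(ci[s]),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("frequency", ascending=False)
        .reset_index(drop=True)
    )


def thelper_subnetwork(n: int) -> SignedNetwork:
    """Mutually inhibitory subnetwork of the first n master regulators.

    n = 2 gives TBX21-GATA3, n = 3 adds RORC, n = 4 adds FOXP3 — the
    classic toggle-switch / triad / tetrahedron models of T-helper fate.
    """
    if not 2 <= n <= 4:
        raise ValueError("subnetworks are defined for n in 2..4")
    names = [LINEAGE_TFS[lin] for lin in LINEAGE_ORDER[:n]]
    net = netgen.make_toggle(n)
    net.node_names = names
    return net


def stimulated_network(
    base: SignedNetwork,
    lineage: str,
    strength: float,
    overrides: dict[tuple[str, str], float] | None = None,
) -> SignedNetwork:
    """Attach the lineage's stimulating cytokines to a T-helper network.

    Each cytokine activates the stimulated lineage's master regulator
    with ``+strength`` and inhibits every other master regulator present
    with ``-strength``, except where ``overrides`` flips the sign of a
    specific (cytokine, regulator) edge.
    """
    if lineage not in LINEAGE_CYTOKINES:
        raise ValueError(f"no cytokine set defined for lineage {lineage!r}")
    if overrides is None:
        overrides = DEFAULT_CYTOKINE_OVERRIDES
    target_tf = LINEAGE_TFS[lineage]
    if target_tf not in base.node_names:
        raise ValueError(f"{target_tf} not present in the network")
    net = base
    present = [nm for nm in base.node_names if nm in LINEAGE_TFS.values()]
    for cytokine in LINEAGE_CYTOKINES[lineage]:
        weights = {}
        for tf in present:
            sign = 1.0 if tf == target_tf else -1.0
            sign = overrides.get((cytokine, tf), sign)
            weights[tf] = sign * strength
        net = attach_signalling_node(net, weights, name=cytokine)
    return net


def run_thelper_cytokines(
    n: int,
    lineage: str,
    config: SimulationConfig | None = None,
    w_range=(1,),
    wc_range=(1,),
    overrides: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """F_lineage(1) for a T-helper subnetwork under cytokine stimulation.

    Scans the asymmetric edge weight W (on the stimulated regulator) and
    the signalling strength W_C over the given grids, returning one row
    per cell with the single-positive frequency of the stimulated
    lineage's master regulator.
    """
    if config is None:
        config = SimulationConfig(n_initial_conditions=10_000, n_replicates=1)
    base = thelper_subnetwork(n)
    target_tf = LINEAGE_TFS[lineage]
    rows = []
    for w in w_range:
        for wc in wc_range:
            net = stimulated_network(base, lineage, wc, overrides=overrides)
            asym_net = apply_asymmetric_weight(net, target_tf, w)
            dist = find_steady_states(net, config, asym=asym_net)
            rows.append(
                {
                    "n": n,
                    "lineage": lineage,
                    "W": w,
                    "WC": wc,
                    "F_lineage_1": dist.single_positive_frequency(target_tf),
                    "converged_fraction": dist.converged_fraction.mean(),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExperimentManifest:
    """A reproducible experiment: id, parameters, simulation settings.

    Re-running a manifest with the same seed reproduces its outputs
    bit for bit.
    """

    experiment: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def run(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        return run_experiment(self.experiment, self.seed, out_dir, **self.params)


EXPERIMENTS = ("fk_sweep", "impurity", "thelper", "thelper_cytokines")


def run_experiment(
    experiment: str, seed: int, out_dir: str | Path, **params
) -> list[Path]:
    """Run a named experiment and write its CSV outputs to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(
        n_initial_conditions=params.pop("n_initial_conditions", 10_000),
        n_replicates=params.pop("n_replicates", 3),
        seed=seed,
    )
    written = []
    if experiment == "fk_sweep":
        table = run_fk_sweep(
            n_range=params.pop("n_range", range(2, 9)),
            self_regulation_modes=params.pop(
                "modes",
                (netgen.SELF_NONE, netgen.SELF_ACTIVATION, netgen.SELF_INHIBITION),
            ),
            config=config,
        )
        path = out_dir / "fk_sweep.csv"
        table.to_csv(path, index=False)
        written.append(path)
    elif experiment == "impurity":
        table = run_impurity_sweep(
            params.pop("n", 4), config=config, seed=seed
        )
        path = out_dir / "impurity.csv"
        table.to_csv(path, index=False)
        written.append(path)
    elif experiment == "thelper":
        for variant in params.pop("variants", ("base", "self_activation")):
            table = run_thelper_case_study(variant, config=config, seed=seed)
            path = out_dir / f"thelper_{variant}.csv"
            table.to_csv(path, index=False)
            written.append(path)
    elif experiment == "thelper_cytokines":
        frames = []
        for n in params.pop("sizes", (2, 3)):
            for lineage in LINEAGE_ORDER[:n]:
                if lineage in LINEAGE_CYTOKINES:
                    frames.append(
                        run_thelper_cytokines(n, lineage, config=config)
                    )
        path = out_dir / "thelper_cytokines.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return written
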