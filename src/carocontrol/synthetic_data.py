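"""Synthetic master networks, phylogenies, and evolved species networks with
recorded ground truth.

The generator emulates the structure and scale of the combined avian
carotenoid network — ~14 dietary inputs, ~55 compounds, ~88 reactions, with
dietary-anchored modules that merge at shared derived compounds — and binary
gain/loss evolution of compounds and reactions along an ultrametric tree. It
makes no attempt to replicate the real carotenoid biochemistry; truth is
generated forward in time and never read by the inference modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

from carocontrol.core_model import (
    CarotenoidNetwork,
    CharacterMatrix,
    Compound,
    Phylogeny,
    Reaction,
    compound_character,
    networks_to_character_matrix,
    reaction_character,
)
from carocontrol.trees import TreeArrays, _as_arrays, yule_tree

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_master",
    "evolve_networks",
    "simulate_dataset",
    "small_instances",
    "sample_digraphs",
]


@dataclass
class SyntheticConfig:
    """Stated world for the generator.

    Rates are symmetric gain/loss in events/my, set to the order of magnitude
    implied by multi-my control-event intervals on trees of ~10^3 my total
    branch length (see docs/methods.md).
    """

    n_dietary: int = 14
    n_compounds: int = 55
    n_reactions: int = 88
    n_tips: int = 64
    tree_depth: float = 90.0  # my; trajectory analyses window to 45 my
    max_age_window: float = 45.0
    dietary_gain: float = 0.01
    dietary_loss: float = 0.01
    derived_gain: float = 0.01
    derived_loss: float = 0.01
    reaction_gain: float = 0.012
    reaction_loss: float = 0.012
    branching_bias: float = 0.4  # P(new compound attaches to a derived parent)
    reversible_fraction: float = 0.15  # derived-derived reactions marked reversible
    sparse_root: bool = False  # root = dietary nodes only instead of full master
    modular: bool = False  # gain/lose whole dietary-anchored modules at once
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_dietary < self.n_compounds:
            raise ValueError("need 0 < n_dietary < n_compounds")
        rates = (
            self.dietary_gain, self.dietary_loss, self.derived_gain,
            self.derived_loss, self.reaction_gain, self.reaction_loss,
        )
        if min(rates) <= 0:
            raise ValueError("all rates must be > 0")
        if self.n_reactions < self.n_compounds - self.n_dietary:
            raise ValueError(
                "n_reactions too small to connect every derived compound"
            )

    def manifest(self) -> dict:
        return asdict(self)

    def rates_for(self, character: str) -> tuple[float, float]:
        if character.startswith("R:"):
            return (self.reaction_gain, self.reaction_loss)
        return (self.dietary_gain, self.dietary_loss) if character[2:].startswith("d") \
            else (self.derived_gain, self.derived_loss)


@dataclass
class GroundTruth:
    """Forward-simulated truth: never read by inference."""

    states: pd.DataFrame  # every tree node label x character, 0/1 (pre-filter)
    networks: dict[str, CarotenoidNetwork]  # label -> consistency-filtered network
    events: pd.DataFrame  # child label, character, event (gain/loss)
    rates: dict[str, tuple[float, float]]
    manifest: dict = field(default_factory=dict)

    def event_counts(self) -> pd.DataFrame:
        if self.events.empty:
            return pd.DataFrame(columns=["gains", "losses"])
        tab = self.events.pivot_table(
            index="character", columns="event", aggfunc="size", fill_value=0
        )
        return tab.reindex(columns=["gain", "loss"], fill_value=0)


def generate_master(config: SyntheticConfig) -> CarotenoidNetwork:
    """Master network: exact (n_compounds, n_reactions), dietary in-degree 0,
    every derived compound reachable from >= 1 dietary input, and extra
    cross-module reactions creating degenerate merge points.

    The graph is built as a DAG (edges respect a depth ranking), matching the
    predominantly forward flow of the metabolism it emulates.
    """
    rng = np.random.default_rng(config.seed)
    n_derived = config.n_compounds - config.n_dietary
    dw = len(str(config.n_dietary))
    mw = len(str(n_derived))
    dietary = [f"d{i:0{dw}d}" for i in range(1, config.n_dietary + 1)]
    derived = [f"m{i:0{mw}d}" for i in range(1, n_derived + 1)]
    rank = {c: 0 for c in dietary}
    edges: set[tuple[str, str]] = set()
    attached: list[str] = []
    for m in derived:
        if attached and rng.random() < config.branching_bias:
            parent = attached[int(rng.integers(len(attached)))]
        else:
            parent = dietary[int(rng.integers(config.n_dietary))]
        edges.add((parent, m))
        rank[m] = rank[parent] + 1
        attached.append(m)
    # extra reactions: substrate at a strictly lower rank, product derived
    candidates = [
        (u, v)
        for u in dietary + derived
        for v in derived
        if rank[u] < rank[v] and (u, v) not in edges
    ]
    n_extra = config.n_reactions - len(edges)
    if n_extra > len(candidates):
        raise ValueError(
            f"cannot place {n_extra} extra reactions; only {len(candidates)} "
            "candidate pairs (raise branching_bias or n_compounds)"
        )
    for idx in rng.choice(len(candidates), size=n_extra, replace=False):
        edges.add(candidates[int(idx)])
    g = nx.DiGraph(edges)
    reversible = set()
    dd_edges = sorted(
        (u, v) for u, v in edges if u.startswith("m") and v.startswith("m")
    )
    n_rev = int(round(config.reversible_fraction * len(dd_edges)))
    if n_rev:
        for idx in rng.choice(len(dd_edges), size=n_rev, replace=False):
            reversible.add(dd_edges[int(idx)])
    compounds = [Compound(d, "dietary") for d in dietary] + [
        Compound(m, "derived", deposited=g.out_degree(m) == 0) for m in derived
    ]
    reactions = [
        Reaction(u, v, (u, v) in reversible) for u, v in sorted(edges)
    ]
    return CarotenoidNetwork("master", compounds, reactions)


def _module_assignment(master: CarotenoidNetwork) -> dict[str, str]:
    """Nearest dietary anchor of every character (ties lexicographic);
    reactions follow their substrate's anchor."""
    g = master.to_digraph()
    anchor: dict[str, tuple[int, str]] = {}
    for d in master.dietary_ids:
        for v, dist in nx.single_source_shortest_path_length(g, d).items():
            best = anchor.get(v)
            if best is None or (dist, d) < best:
                anchor[v] = (dist, d)
    out = {}
    for c in master.compounds:
        out[compound_character(c)] = anchor.get(c, (0, c))[1]
    for key in master.reactions:
        out[reaction_character(key)] = anchor.get(key[0], (0, key[0]))[1]
    return out


def _simulate_branch(
    state: int, t: float, gain: float, loss: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Gillespie simulation of one 2-state chain along one branch; returns
    (end state, gains, losses)."""
    gains = losses = 0
    clock = 0.0
    while True:
        rate = gain if state == 0 else loss
        clock += rng.exponential(1.0 / rate)
        if clock >= t:
            return state, gains, losses
        if state == 0:
            state, gains = 1, gains + 1
        else:
            state, losses = 0, losses + 1


def evolve_networks(
    master: CarotenoidNetwork,
    tree: "TreeArrays | Phylogeny",
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[dict[str, CarotenoidNetwork], GroundTruth]:
    """Evolve every master compound and reaction as an independent binary
    chain forward along the tree; returns consistency-filtered tip networks
    and the full ground truth.

    The root network is the full master by default (``sparse_root`` starts
    from the dietary compounds only). In ``modular`` mode one chain is run
    per dietary-anchored module and its state applies to all members.
    """
    arrays = _as_arrays(tree)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    characters = [compound_character(c) for c in sorted(master.compounds)] + [
        reaction_character(k) for k in sorted(master.reactions)
    ]
    rates = {ch: config.rates_for(ch) for ch in characters}
    if config.modular:
        modules = _module_assignment(master)
        groups: dict[str, list[str]] = {}
        for ch, anchor in modules.items():
            groups.setdefault(anchor, []).append(ch)
        units = sorted(groups)
    else:
        groups = {ch: [ch] for ch in characters}
        units = characters

    root = arrays.root
    n_nodes = arrays.n_nodes
    states = np.zeros((n_nodes, len(characters)), dtype=int)
    col = {ch: i for i, ch in enumerate(characters)}
    root_state = {
        ch: 1
        if not config.sparse_root
        or (not ch.startswith("R:") and ch[2:] in master.dietary_ids)
        else 0
        for ch in characters
    }
    events = []
    order = arrays.preorder()
    unit_states = {u: None for u in units}
    node_unit_state = np.zeros((n_nodes, len(units)), dtype=int)
    unit_idx = {u: i for i, u in enumerate(units)}
    for node in order:
        p = arrays.parent[node]
        for u in units:
            gain, loss = rates[groups[u][0]]
            if p < 0:
                s = root_state[groups[u][0]]
            else:
                s0 = node_unit_state[p, unit_idx[u]]
                s, gains, losses = _simulate_branch(
                    int(s0), float(arrays.blen[node]), gain, loss, rng
                )
                label = arrays.node_labels[node]
                for ch in groups[u]:
                    events.extend(
                        {"child": label, "character": ch, "event": "gain"}
                        for _ in range(gains)
                    )
                    events.extend(
                        {"child": label, "character": ch, "event": "loss"}
                        for _ in range(losses)
                    )
            node_unit_state[node, unit_idx[u]] = s
            for ch in groups[u]:
                states[node, col[ch]] = s

    labels = arrays.node_labels
    state_df = pd.DataFrame(states, index=labels, columns=characters)
    networks: dict[str, CarotenoidNetwork] = {}
    for i, label in enumerate(labels):
        present_c = [
            c for c in sorted(master.compounds) if states[i, col[compound_character(c)]]
        ]
        present_r = [
            k for k in sorted(master.reactions) if states[i, col[reaction_character(k)]]
        ]
        if not present_c:
            # degenerate all-lost node: keep the first dietary compound so the
            # network stays valid (N >= 1); recorded in the manifest
            present_c = [master.dietary_ids[0]]
        net, _dropped = master.subnetwork(present_c, present_r, label)
        networks[label] = net
    tip_networks = {lab: networks[lab] for lab in arrays.tip_labels}
    truth = GroundTruth(
        states=state_df,
        networks=networks,
        events=pd.DataFrame(events, columns=["child", "character", "event"]),
        rates=rates,
        manifest=config.manifest(),
    )
    return tip_networks, truth


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    master: CarotenoidNetwork
    phylogeny: Phylogeny
    tip_networks: dict[str, CarotenoidNetwork]
    matrix: CharacterMatrix
    truth: GroundTruth


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Master + Yule tree + evolved tip networks + tip character matrix."""
    master = generate_master(config)
    phylo = yule_tree(config.n_tips, config.tree_depth, config.seed + 1)
    tips, truth = evolve_networks(master, phylo, config, seed=config.seed + 2)
    matrix = networks_to_character_matrix(list(tips.values()), master)
    return SyntheticDataset(config, master, phylo, tips, matrix, truth)


def simulate_ctmc_tips(
    tree: "TreeArrays | Phylogeny",
    Q: np.ndarray,
    seed: int,
    root_state: int | None = None,
) -> dict[str, int]:
    """Forward-simulate a k-state CTMC along the tree (Gillespie per branch);
    returns tip state indices. Root state is drawn uniformly unless given."""
    arrays = _as_arrays(tree)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    states = np.zeros(arrays.n_nodes, dtype=int)
    for node in arrays.preorder():
        p = arrays.parent[node]
        if p < 0:
            states[node] = int(rng.integers(k)) if root_state is None else root_state
            continue
        s = int(states[p])
        t = 0.0
        length = float(arrays.blen[node])
        while True:
            out = -Q[s, s]
            if out <= 0:
                break
            t += rng.exponential(1.0 / out)
            if t >= length:
                break
            probs = Q[s].clip(0, None)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        states[node] = s
    return {arrays.tip_labels[i]: int(states[i]) for i in range(arrays.n_tips)}


# ---------------------------------------------------------------------------
# exhaustive / sampled digraph instances for oracle tests
# ---------------------------------------------------------------------------

def _network_from_edges(n: int, edges: list[tuple[int, int]]) -> CarotenoidNetwork:
    labels = [chr(ord("a") + i) for i in range(n)]
    targets = {labels[v] for _, v in edges}
    compounds = [
        Compound(lab, "derived" if lab in targets else "dietary") for lab in labels
    ]
    reactions = [Reaction(labels[u], labels[v]) for u, v in edges]
    return CarotenoidNetwork(f"g{n}", compounds, reactions)


def small_instances(max_nodes: int) -> Iterator[CarotenoidNetwork]:
    """Every labeled self-loop-free digraph on 1..max_nodes nodes,
    deterministically ordered; exhaustive mode is capped at 5 nodes."""
    if max_nodes > 5:
        raise ValueError(
            "exhaustive enumeration capped at 5 nodes; use sample_digraphs"
        )
    for n in range(1, max_nodes + 1):
        pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
        for mask in range(1 << len(pairs)):
            edges = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
            yield _network_from_edges(n, edges)


def sample_digraphs(
    n_nodes: int, count: int, seed: int
) -> Iterator[CarotenoidNetwork]:
    """Uniformly sampled labeled digraphs on exactly ``n_nodes`` nodes."""
    rng = np.random.default_rng(seed)
    pairs = [(u, v) for u in range(n_nodes) for v in range(n_nodes) if u != v]
    for _ in range(count):
        mask = rng.integers(0, 2, size=len(pairs))
        edges = [p for p, m in zip(pairs, mask) if m]
        yield _network_from_edges(n_nodes, edges)
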