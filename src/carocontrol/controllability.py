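"""Structural controllability of directed metabolic networks.

The minimum number of independently controlled nodes (Nc) follows from a
maximum matching on the bipartite out-copy/in-copy representation of the
digraph: a node pointed to by a matched edge is "matched" (driven by an
upstream neighbour); every other node needs its own control. Controls are
decomposed by the counting rule

    Ns = number of source nodes (in-degree 0),
    Ne = max(0, #sinks - #sources)   (excess of terminal nodes over inputs),
    Ni = Nc - Ns - Ne                (internal dilations),

which is matching-independent, unlike the identity of unmatched nodes (ties
between maximum matchings). Degree-asymmetry identities are exposed
separately through :func:`control_node_identities` for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from carocontrol.core_model import CarotenoidNetwork, Reaction

__all__ = [
    "ControlProfile",
    "OrientationVariantSet",
    "maximum_matching",
    "control_profile",
    "control_node_identities",
    "enumerate_orientation_variants",
    "classify_category",
]

CLASS_ALWAYS = "always"      # critical: removal changes Nc in every variant
CLASS_SOMETIMES = "sometimes"  # redundant
CLASS_NEVER = "never"        # ordinary


class OrientationError(ValueError):
    """Raised when an operation requiring a fully oriented network receives
    unresolved reversible reactions."""


@dataclass(frozen=True)
class ControlProfile:
    """Minimum controls and their source/internal/sink decomposition."""

    N: int
    Nc: int
    Ns: int
    Ni: int
    Ne: int
    floored: bool = False  # True when Ni had to be clamped at 0 (diagnostic)

    def __post_init__(self) -> None:
        assert self.Nc == self.Ns + self.Ni + self.Ne, "Nc must decompose exactly"
        assert self.Nc >= 1 and min(self.Ns, self.Ni, self.Ne) >= 0

    @property
    def eta_s(self) -> float:
        return self.Ns / self.Nc

    @property
    def eta_i(self) -> float:
        return self.Ni / self.Nc

    @property
    def eta_e(self) -> float:
        return self.Ne / self.Nc

    @property
    def eta(self) -> tuple[float, float, float]:
        return (self.eta_s, self.eta_i, self.eta_e)


@dataclass
class OrientationVariantSet:
    """Profiles over all direction assignments of reversible reactions."""

    label: str
    variants: list[CarotenoidNetwork]
    profiles: list[ControlProfile]
    reaction_classes: dict[tuple[str, str], str]
    sampled: bool = False  # True when 2^k exceeded the cap and variants were sampled


def _bipartite_matching(graph: nx.DiGraph) -> dict:
    """Hopcroft–Karp maximum matching on the out-copy/in-copy bipartition.

    Returns the matching dict over ("out", u) / ("in", v) keys.
    """
    b = nx.Graph()
    left = [("out", u) for u in graph.nodes]
    right = [("in", v) for v in graph.nodes]
    b.add_nodes_from(left, bipartite=0)
    b.add_nodes_from(right, bipartite=1)
    b.add_edges_from((("out", u), ("in", v)) for u, v in graph.edges)
    return nx.bipartite.hopcroft_karp_matching(b, top_nodes=left)


def _require_oriented(network: CarotenoidNetwork) -> nx.DiGraph:
    if not network.is_oriented:
        raise OrientationError(
            f"network {network.label!r} has unresolved reversible reactions; "
            "enumerate orientation variants first"
        )
    return network.to_digraph()


def maximum_matching(
    network: CarotenoidNetwork,
) -> tuple[set[tuple[str, str]], set[str], set[str]]:
    """Maximum set of reactions sharing no start node and no end node.

    Returns ``(matched_edges, matched_nodes, unmatched_nodes)`` where matched
    nodes are those pointed to by a matched edge.
    """
    g = _require_oriented(network)
    matching = _bipartite_matching(g)
    matched_edges = {
        (u, mate[1])
        for (side, u), mate in matching.items()
        if side == "out"
    }
    matched_nodes = {v for _, v in matched_edges}
    unmatched = set(g.nodes) - matched_nodes
    return matched_edges, matched_nodes, unmatched


def control_profile(network: CarotenoidNetwork) -> ControlProfile:
    """Control profile of a fully oriented network.

    Nc = max(1, N - #matched nodes); the floor covers perfectly matched
    (cycle-covered) graphs, which still need one control. Isolated nodes
    (in-degree = out-degree = 0) count as sources, matching networks that are
    bare dietary inputs.
    """
    g = _require_oriented(network)
    _, matched_nodes, _ = maximum_matching(network)
    n = g.number_of_nodes()
    nc = max(1, n - len(matched_nodes))
    sources = sum(1 for v in g.nodes if g.in_degree(v) == 0)
    # isolated nodes count as sources; the excess-sink rule compares all
    # out-degree-0 nodes (incl. isolated) against all sources
    all_sinks = sum(1 for v in g.nodes if g.out_degree(v) == 0)
    ne = max(0, all_sinks - sources)
    ni = nc - sources - ne
    floored = ni < 0
    ns = sources
    if floored:
        # unreachable for source-anchored networks (Nc >= #sources and the
        # dilation decomposition guarantees Ni >= 0); clamp defensively
        ni = 0
        ns = min(sources, nc)
        ne = nc - ns
    return ControlProfile(N=n, Nc=nc, Ns=ns, Ni=ni, Ne=ne, floored=floored)


def control_node_identities(network: CarotenoidNetwork) -> dict[str, dict]:
    """Which compounds can be unmatched in at least one maximum matching,
    with their degree asymmetry. Advisory: counts always come from
    :func:`control_profile`.

    A node v is matched in *every* maximum matching iff deleting its in-copy
    from the bipartite graph reduces the maximum matching size; otherwise some
    maximum matching leaves it unmatched.
    """
    g = _require_oriented(network)
    b = nx.Graph()
    left = [("out", u) for u in g.nodes]
    b.add_nodes_from(left, bipartite=0)
    b.add_nodes_from((("in", v) for v in g.nodes), bipartite=1)
    b.add_edges_from((("out", u), ("in", v)) for u, v in g.edges)
    full = len(nx.bipartite.hopcroft_karp_matching(b, top_nodes=left)) // 2
    out: dict[str, dict] = {}
    for v in g.nodes:
        sub = b.copy()
        sub.remove_node(("in", v))
        reduced = len(
            nx.bipartite.hopcroft_karp_matching(sub, top_nodes=left)
        ) // 2
        can_be_unmatched = reduced == full
        indeg, outdeg = g.in_degree(v), g.out_degree(v)
        if indeg == 0:
            role = "source"
        elif outdeg == 0:
            role = "sink"
        elif indeg < outdeg:
            role = "internal"
        else:
            role = "matched-like"
        out[v] = {
            "can_be_unmatched": can_be_unmatched,
            "in_degree": indeg,
            "out_degree": outdeg,
            "role": role,
        }
    return out


def _variant_assignments(
    reversible: list[Reaction], indices: Iterable[int]
) -> list[dict[tuple[str, str], bool]]:
    out = []
    k = len(reversible)
    for idx in indices:
        bits = [(idx >> j) & 1 == 0 for j in range(k)]  # True = canonical direction
        out.append({r.key: bits[j] for j, r in enumerate(reversible)})
    return out


def enumerate_orientation_variants(
    network: CarotenoidNetwork,
    cap: int = 4096,
    *,
    sample_seed: int | None = None,
    sample_size: int = 256,
) -> OrientationVariantSet:
    """All 2^k fully oriented versions of a network with k reversible
    reactions, their control profiles, and per-reaction control classes.

    A reaction is "always" (critical) if removing it changes Nc in every
    variant, "never" (ordinary) if in none, else "sometimes" (redundant).
    When 2^k exceeds ``cap``, variants are sampled uniformly (requires
    ``sample_seed``) and the result is flagged ``sampled=True``.
    """
    reversible = network.reversible_reactions
    k = len(reversible)
    total = 1 << k
    if total > cap:
        if sample_seed is None:
            raise ValueError(
                f"2^{k} = {total} orientation variants exceed cap {cap}; raise the "
                "cap or pass sample_seed to sample variants"
            )
        import numpy as np

        rng = np.random.default_rng(sample_seed)
        indices = sorted(
            int(i) for i in rng.choice(total, size=min(sample_size, total), replace=False)
        )
        sampled = True
    else:
        indices = range(total)
        sampled = False

    variants: list[CarotenoidNetwork] = []
    profiles: list[ControlProfile] = []
    # per reaction: in how many variants does its removal change Nc
    changes: dict[tuple[str, str], int] = {r.key: 0 for r in network.reactions.values()}
    n_variants = 0
    for assignment in _variant_assignments(reversible, indices):
        variant = network.oriented(assignment, label=f"{network.label}#v{n_variants}")
        prof = control_profile(variant)
        variants.append(variant)
        profiles.append(prof)
        for key in network.reactions:
            vkey = _oriented_key(network.reactions[key], assignment)
            pruned_reactions = [
                r for r in variant.reactions.values() if r.key != vkey
            ]
            pruned = CarotenoidNetwork(
                variant.label,
                variant.compounds.values(),
                pruned_reactions,
                allow_dietary_indegree=True,
            )
            if control_profile(pruned).Nc != prof.Nc:
                changes[key] += 1
        n_variants += 1

    classes = {}
    for key, n_changed in changes.items():
        if n_changed == n_variants:
            classes[key] = CLASS_ALWAYS
        elif n_changed == 0:
            classes[key] = CLASS_NEVER
        else:
            classes[key] = CLASS_SOMETIMES
    return OrientationVariantSet(
        label=network.label,
        variants=variants,
        profiles=profiles,
        reaction_classes=classes,
        sampled=sampled,
    )


def _oriented_key(
    reaction: Reaction, assignment: dict[tuple[str, str], bool]
) -> tuple[str, str]:
    if not reaction.reversible or assignment.get(reaction.key, True):
        return (reaction.substrate, reaction.product)
    return (reaction.product, reaction.substrate)


def classify_category(profile: ControlProfile, network: CarotenoidNetwork) -> int:
    """Control category 1–6 of a network.

    1: no reactions (bare dietary deposition); 2: fully source-controlled and
    non-degenerate (no derived compound fed by >= 2 dietary compounds);
    3: source-controlled but degenerate; 4: one extra internal control
    (eta_i > 0, eta_e = 0); 6: one extra sink control (eta_e > 0, eta_i = 0);
    5: all three control types present.
    """
    if network.n_reactions == 0:
        return 1
    if profile.eta_s == 1.0:
        return 3 if _is_degenerate(network) else 2
    if profile.eta_i > 0 and profile.eta_e == 0:
        return 4
    if profile.eta_e > 0 and profile.eta_i == 0:
        return 6
    return 5


def _is_degenerate(network: CarotenoidNetwork) -> bool:
    """True when some derived compound is reachable from >= 2 dietary inputs."""
    g = network.to_digraph()
    support: dict[str, int] = {}
    for d in network.dietary_ids:
        for v in nx.descendants(g, d):
            support[v] = support.get(v, 0) + 1
            if support[v] >= 2:
                return True
    return False
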