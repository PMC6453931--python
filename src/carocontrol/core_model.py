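"""Domain types and I/O shared by every analysis stage.

Networks are exchanged as paired node/edge TSV tables (diff-friendly and able
to carry the dietary/derived/deposited annotations the control analysis
needs); trees as Newick via dendropy; character matrices as CSV. A GraphML
exporter is provided for interoperability but is not the source of truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "Reaction",
    "CarotenoidNetwork",
    "Phylogeny",
    "CharacterMatrix",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "write_graphml",
    "networks_to_character_matrix",
    "compound_character",
    "reaction_character",
    "is_reaction_character",
]

ROLE_DIETARY = "dietary"
ROLE_DERIVED = "derived"


class NetworkValidationError(ValueError):
    """A network violated a structural invariant (hard error, not a warning)."""


@dataclass(frozen=True)
class Compound:
    """A carotenoid compound: a node of the metabolic network.

    ``role`` is ``"dietary"`` (exogenously consumed; a network input that must
    have in-degree 0) or ``"derived"`` (enzymatically metabolized product).
    ``deposited`` marks compounds deposited in plumage.
    """

    id: str
    role: str
    deposited: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("compound id must be non-empty")
        if self.role not in (ROLE_DIETARY, ROLE_DERIVED):
            raise NetworkValidationError(
                f"compound {self.id!r}: role must be 'dietary' or 'derived', got {self.role!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """An enzymatic conversion substrate → product.

    Reversible reactions are stored once with ``reversible=True`` and a
    canonical (lexicographic) endpoint order so file output is deterministic.
    Self-loops are forbidden.
    """

    substrate: str
    product: str
    reversible: bool = False

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise NetworkValidationError(
                f"self-loop reaction on {self.substrate!r} is not allowed"
            )

    def canonical(self) -> "Reaction":
        if self.reversible and self.substrate > self.product:
            return Reaction(self.product, self.substrate, True)
        return self

    @property
    def key(self) -> tuple[str, str]:
        r = self.canonical()
        return (r.substrate, r.product)


class CarotenoidNetwork:
    """Directed network of compounds and reactions for one species or node.

    Invariants enforced on construction: unique compound ids, no duplicate
    (substrate, product) pairs, reaction endpoints declared, no self-loops,
    N >= 1. Dietary compounds with nonzero in-degree abort validation unless
    ``allow_dietary_indegree`` is set (the control classification assumes
    dietary = source); the condition is still reported in ``warnings``.
    """

    def __init__(
        self,
        label: str,
        compounds: Iterable[Compound],
        reactions: Iterable[Reaction] = (),
        *,
        allow_dietary_indegree: bool = False,
    ) -> None:
        self.label = label
        self.compounds: dict[str, Compound] = {}
        for c in compounds:
            if c.id in self.compounds:
                raise NetworkValidationError(f"duplicate compound id {c.id!r}")
            self.compounds[c.id] = c
        if not self.compounds:
            raise NetworkValidationError(f"network {label!r} has no compounds (N >= 1)")
        self.reactions: dict[tuple[str, str], Reaction] = {}
        for r in reactions:
            r = r.canonical()
            for end in (r.substrate, r.product):
                if end not in self.compounds:
                    raise NetworkValidationError(
                        f"reaction {r.substrate}->{r.product}: unknown compound {end!r}"
                    )
            if r.key in self.reactions:
                raise NetworkValidationError(
                    f"duplicate reaction {r.substrate}->{r.product}"
                )
            self.reactions[r.key] = r
        self.warnings: list[str] = []
        self._validate(allow_dietary_indegree)

    def _validate(self, allow_dietary_indegree: bool) -> None:
        g = self.to_digraph()
        offenders = [
            c.id
            for c in self.compounds.values()
            if c.role == ROLE_DIETARY and g.in_degree(c.id) > 0
        ]
        if offenders:
            msg = f"dietary compounds with nonzero in-degree: {sorted(offenders)}"
            self.warnings.append(msg)
            if not allow_dietary_indegree:
                raise NetworkValidationError(
                    f"network {self.label!r}: {msg} (pass allow_dietary_indegree=True to override)"
                )
        orphans = [
            c.id
            for c in self.compounds.values()
            if c.role == ROLE_DERIVED and g.in_degree(c.id) == 0
        ]
        if orphans:
            # derived compound without a known precursor reaction: warn only
            self.warnings.append(
                f"derived compounds with in-degree 0: {sorted(orphans)}"
            )

    # -- properties -------------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def dietary_ids(self) -> list[str]:
        return sorted(c.id for c in self.compounds.values() if c.role == ROLE_DIETARY)

    @property
    def derived_ids(self) -> list[str]:
        return sorted(c.id for c in self.compounds.values() if c.role == ROLE_DERIVED)

    @property
    def reversible_reactions(self) -> list[Reaction]:
        return sorted(
            (r for r in self.reactions.values() if r.reversible),
            key=lambda r: r.key,
        )

    @property
    def is_oriented(self) -> bool:
        """True when no reaction is reversible (directions fully resolved)."""
        return not any(r.reversible for r in self.reactions.values())

    # -- conversions ------------------------------------------------------

    def to_digraph(self, *, reversible_both_ways: bool = True) -> nx.DiGraph:
        """Realized directed graph.

        Reversible reactions contribute both directions by default (the
        realized connectivity); pass ``reversible_both_ways=False`` to use the
        stored canonical direction only.
        """
        g = nx.DiGraph()
        for c in self.compounds.values():
            g.add_node(c.id, role=c.role, deposited=c.deposited)
        for r in self.reactions.values():
            g.add_edge(r.substrate, r.product)
            if r.reversible and reversible_both_ways:
                g.add_edge(r.product, r.substrate)
        return g

    def oriented(
        self, assignment: Mapping[tuple[str, str], bool] | None = None, label: str | None = None
    ) -> "CarotenoidNetwork":
        """Fully oriented copy: each reversible reaction keeps its canonical
        direction where ``assignment[key]`` is True (or absent) and is flipped
        where False."""
        assignment = assignment or {}
        reactions = []
        for r in self.reactions.values():
            if not r.reversible:
                reactions.append(r)
            elif assignment.get(r.key, True):
                reactions.append(Reaction(r.substrate, r.product, False))
            else:
                reactions.append(Reaction(r.product, r.substrate, False))
        return CarotenoidNetwork(
            label if label is not None else self.label,
            self.compounds.values(),
            reactions,
            allow_dietary_indegree=True,
        )

    def subnetwork(
        self,
        compound_ids: Iterable[str],
        reaction_keys: Iterable[tuple[str, str]],
        label: str,
    ) -> tuple["CarotenoidNetwork", list[tuple[str, str]]]:
        """Induced network from presence calls, applying the endpoint
        consistency filter: reactions with a missing endpoint are dropped and
        returned in the second element."""
        keep = set(compound_ids)
        compounds = [self.compounds[i] for i in sorted(keep)]
        kept, dropped = [], []
        for key in sorted(set(reaction_keys)):
            r = self.reactions[key]
            if r.substrate in keep and r.product in keep:
                kept.append(r)
            else:
                dropped.append(key)
        net = CarotenoidNetwork(label, compounds, kept, allow_dietary_indegree=True)
        return net, dropped

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CarotenoidNetwork):
            return NotImplemented
        return (
            self.compounds == other.compounds and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return (
            f"CarotenoidNetwork({self.label!r}, N={self.n_compounds}, "
            f"r={self.n_reactions})"
        )


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in millions of years (my)."""

    tree: dendropy.Tree
    ultrametric: bool = True

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise NetworkValidationError("tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise NetworkValidationError("negative branch length")
        if self.ultrametric:
            depths = self._tip_depths()
            depth = max(depths)
            if depth > 0 and max(depths) - min(depths) > 1e-6 * depth:
                raise NetworkValidationError(
                    "tree is not ultrametric within 1e-6 x depth tolerance"
                )

    @classmethod
    def from_newick(cls, source: str | Path, *, ultrametric: bool = True) -> "Phylogeny":
        text = str(source)
        p = Path(text) if len(text) < 4096 and "(" not in text else None
        if p is not None and p.exists():
            tree = dendropy.Tree.get(path=str(p), schema="newick")
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick")
        return cls(tree, ultrametric=ultrametric)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def _tip_depths(self) -> list[float]:
        out = []
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out.append(d)
        return out

    @property
    def depth(self) -> float:
        return max(self._tip_depths())


@dataclass
class CharacterMatrix:
    """Binary presence/absence states: one row per tip, one column per
    compound or reaction character."""

    data: pd.DataFrame  # index = tip labels, columns = character ids, values 0/1

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise NetworkValidationError("character states must be 0 or 1")
        self.data = self.data.astype(int)

    @property
    def tips(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def states(self, character: str) -> pd.Series:
        return self.data[character]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="tip")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CharacterMatrix":
        return cls(pd.read_csv(path, index_col=0))


# -- character naming ------------------------------------------------------

def compound_character(compound_id: str) -> str:
    return f"C:{compound_id}"


def reaction_character(key: tuple[str, str]) -> str:
    return f"R:{key[0]}>{key[1]}"


def is_reaction_character(character: str) -> bool:
    return character.startswith("R:")


def parse_character(character: str) -> str | tuple[str, str]:
    if is_reaction_character(character):
        s, p = character[2:].split(">")
        return (s, p)
    return character[2:]


# -- I/O -------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "t"}


def _parse_bool(text: str, context: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in {"false", "0", "no", "f", ""}:
        return False
    raise NetworkValidationError(f"{context}: cannot parse boolean {text!r}")


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if "\t" in head else ","


def read_network(
    node_table_path: str | Path,
    edge_table_path: str | Path,
    label: str | None = None,
    *,
    allow_dietary_indegree: bool = False,
) -> CarotenoidNetwork:
    """Read a network from paired node/edge tables (TSV or CSV, with headers
    ``id, role, deposited`` and ``substrate, product, reversible``).

    Unknown compound ids and self-loop rows are hard errors naming the row.
    ``reversible=true`` rows represent one bidirectional reaction.
    """
    node_path, edge_path = Path(node_table_path), Path(edge_table_path)
    compounds: list[Compound] = []
    with open(node_path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter=_sniff_delimiter(node_path)), 2):
            compounds.append(
                Compound(
                    row["id"].strip(),
                    row["role"].strip().lower(),
                    _parse_bool(row.get("deposited", "false"), f"{node_path}:{i}"),
                )
            )
    declared = {c.id for c in compounds}
    reactions: list[Reaction] = []
    with open(edge_path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter=_sniff_delimiter(edge_path)), 2):
            s, p = row["substrate"].strip(), row["product"].strip()
            if s == p:
                raise NetworkValidationError(f"{edge_path}:{i}: self-loop on {s!r}")
            for end in (s, p):
                if end not in declared:
                    raise NetworkValidationError(
                        f"{edge_path}:{i}: unknown compound {end!r}"
                    )
            reactions.append(
                Reaction(s, p, _parse_bool(row.get("reversible", "false"), f"{edge_path}:{i}"))
            )
    return CarotenoidNetwork(
        label or node_path.stem,
        compounds,
        reactions,
        allow_dietary_indegree=allow_dietary_indegree,
    )


def write_network(
    network: CarotenoidNetwork,
    node_table_path: str | Path,
    edge_table_path: str | Path,
) -> None:
    """Write the paired TSV tables; deterministic (sorted) row order."""
    with open(node_table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "role", "deposited"])
        for cid in sorted(network.compounds):
            c = network.compounds[cid]
            w.writerow([c.id, c.role, str(c.deposited).lower()])
    with open(edge_table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["substrate", "product", "reversible"])
        for key in sorted(network.reactions):
            r = network.reactions[key]
            w.writerow([r.substrate, r.product, str(r.reversible).lower()])


def write_graphml(network: CarotenoidNetwork, path: str | Path) -> None:
    g = network.to_digraph(reversible_both_ways=False)
    for key, r in network.reactions.items():
        g.edges[r.substrate, r.product]["reversible"] = r.reversible
    nx.write_graphml(g, str(path))


def networks_to_character_matrix(
    networks: Sequence[CarotenoidNetwork], master: CarotenoidNetwork
) -> CharacterMatrix:
    """Encode each species network as binary presence characters against the
    master network (one character per master compound and per master reaction)."""
    if not networks:
        raise NetworkValidationError("no tips: at least one species network required")
    columns = [compound_character(c) for c in sorted(master.compounds)] + [
        reaction_character(k) for k in sorted(master.reactions)
    ]
    rows = {}
    for net in networks:
        extra_c = set(net.compounds) - set(master.compounds)
        extra_r = set(net.reactions) - set(master.reactions)
        if extra_c or extra_r:
            raise NetworkValidationError(
                f"network {net.label!r} has elements absent from master: "
                f"compounds {sorted(extra_c)}, reactions {sorted(extra_r)}"
            )
        row = [int(c in net.compounds) for c in sorted(master.compounds)] + [
            int(k in net.reactions) for k in sorted(master.reactions)
        ]
        rows[net.label] = row
    return CharacterMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=columns))
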