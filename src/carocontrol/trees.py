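"""Array-backed tree representation and tree utilities.

Likelihood kernels (binary-character pruning, multi-state CTMC pruning, joint
reconstruction, contrasts) all run on :class:`TreeArrays`, a flat postorder
representation built once from a dendropy tree. dendropy remains the source
of truth for Newick I/O and topology manipulation.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np

from carocontrol.core_model import Phylogeny

__all__ = [
    "TreeArrays",
    "yule_tree",
    "rescale_to_mean_branch",
    "resolve_polytomies",
]


@dataclass
class TreeArrays:
    """Flat arrays for a rooted tree.

    Nodes 0..n_tips-1 are tips (in ``tip_labels`` order); internal nodes
    follow in postorder, the root last. ``parent[root] == -1`` and
    ``blen[root] == 0``.
    """

    n_tips: int
    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    postorder: np.ndarray  # internal nodes only, root last
    tip_labels: list[str]
    node_labels: list[str]  # every node; internal nodes get stable ids

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def internal_labels(self) -> list[str]:
        return [self.node_labels[i] for i in self.postorder]

    @property
    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def node_ages(self) -> np.ndarray:
        """Age (my before present) of every node, assuming the tree is
        ultrametric; tips have age ~0."""
        depth = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + self.blen[node]
        return depth.max() - depth

    def preorder(self) -> list[int]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return out

    def total_length(self) -> float:
        return float(self.blen.sum())

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    @classmethod
    def from_phylogeny(cls, phylo: Phylogeny | dendropy.Tree) -> "TreeArrays":
        tree = phylo.tree if isinstance(phylo, Phylogeny) else phylo
        leaves = [leaf for leaf in tree.leaf_node_iter()]
        tip_labels = [leaf.taxon.label for leaf in leaves]
        index: dict[int, int] = {id(leaf): i for i, leaf in enumerate(leaves)}
        internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
        for j, node in enumerate(internal):
            index[id(node)] = len(leaves) + j
        n_nodes = len(leaves) + len(internal)
        parent = np.full(n_nodes, -1, dtype=int)
        blen = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        node_labels = list(tip_labels) + [""] * len(internal)
        for node in tree.postorder_node_iter():
            i = index[id(node)]
            blen[i] = node.edge.length or 0.0
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
            if not node.is_leaf():
                children[i] = [index[id(c)] for c in node.child_nodes()]
                label = node.label or f"N{i}"
                node_labels[i] = label
        postorder = np.array([index[id(n)] for n in internal], dtype=int)
        return cls(
            n_tips=len(leaves),
            parent=parent,
            blen=blen,
            children=children,
            postorder=postorder,
            tip_labels=tip_labels,
            node_labels=node_labels,
        )


def _as_arrays(tree: "TreeArrays | Phylogeny | dendropy.Tree") -> TreeArrays:
    if isinstance(tree, TreeArrays):
        return tree
    return TreeArrays.from_phylogeny(tree)


def yule_tree(n_tips: int, depth: float, seed: int, prefix: str = "t") -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` tips scaled to the
    requested root-to-tip depth in my. Bit-reproducible for a given seed."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    birth: dict[int, float] = {0: 0.0}
    parent: dict[int, int] = {}
    alive = [0]
    t = 0.0
    next_id = 1
    while len(alive) < n_tips:
        t += rng.exponential(1.0 / len(alive))
        idx = int(rng.integers(len(alive)))
        splitter = alive.pop(idx)
        for _ in range(2):
            birth[next_id] = t
            parent[next_id] = splitter
            alive.append(next_id)
            next_id += 1
    t_end = t + rng.exponential(1.0 / len(alive))
    # depth is measured from the first split (the root node) to the tips
    t_root = min(birth[k] for k, p in parent.items() if p == 0)
    scale = depth / (t_end - t_root)
    width = len(str(n_tips))
    tip_names = iter(f"{prefix}{i:0{width}d}" for i in range(1, n_tips + 1))

    def newick(node: int) -> str:
        kids = [k for k, p in parent.items() if p == node]
        end = min((birth[k] for k in kids), default=t_end)
        length = 0.0 if node == 0 else (end - birth[node]) * scale
        if not kids:
            return f"{next(tip_names)}:{length:.10f}"
        inner = ",".join(newick(k) for k in sorted(kids))
        return f"({inner}):{length:.10f}"

    return Phylogeny.from_newick(newick(0) + ";")


def rescale_to_mean_branch(
    arrays: TreeArrays, target: float = 0.1
) -> tuple[TreeArrays, float]:
    """Copy of the tree with branch lengths scaled so the mean branch length
    equals ``target`` (rate-estimation convention); returns (tree, factor)."""
    branches = arrays.blen[arrays.parent >= 0]
    mean = branches.mean()
    if mean <= 0:
        raise ValueError("tree has zero total length")
    factor = target / mean
    scaled = TreeArrays(
        n_tips=arrays.n_tips,
        parent=arrays.parent.copy(),
        blen=arrays.blen * factor,
        children=[list(c) for c in arrays.children],
        postorder=arrays.postorder.copy(),
        tip_labels=list(arrays.tip_labels),
        node_labels=list(arrays.node_labels),
    )
    scaled.blen[scaled.postorder[-1]] = 0.0
    return scaled, factor


def resolve_polytomies(phylo: Phylogeny, seed: int) -> Phylogeny:
    """Randomly resolved binary copy (zero-length inserted branches)."""
    tree = phylo.tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False, rng=_random.Random(seed))
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return Phylogeny(tree, ultrametric=phylo.ultrametric)
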