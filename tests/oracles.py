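"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms (and networkx): the
matching oracle recurses over edge subsets, the path oracle is a plain
recursive DFS over adjacency dicts, and the DAG path counter is textbook
dynamic programming.
"""

from __future__ import annotations

import itertools


def brute_max_matching(edges: list[tuple[str, str]]) -> int:
    """Size of the largest edge subset sharing no start node and no end node,
    by exhaustive recursion."""

    def rec(idx: int, used_starts: frozenset, used_ends: frozenset) -> int:
        if idx == len(edges):
            return 0
        best = rec(idx + 1, used_starts, used_ends)
        u, v = edges[idx]
        if u not in used_starts and v not in used_ends:
            best = max(
                best, 1 + rec(idx + 1, used_starts | {u}, used_ends | {v})
            )
        return best

    return rec(0, frozenset(), frozenset())


def brute_control_counts(
    nodes: list[str], edges: list[tuple[str, str]]
) -> tuple[int, int, int, int]:
    """(Nc, Ns, Ni, Ne) from first principles: Nc via the brute matching,
    Ns by direct in-degree counting, Ne as the excess of sinks over sources,
    Ni as the remainder."""
    n = len(nodes)
    matched = brute_max_matching(edges)
    nc = max(1, n - matched)
    indeg = {v: 0 for v in nodes}
    outdeg = {v: 0 for v in nodes}
    for u, v in edges:
        indeg[v] += 1
        outdeg[u] += 1
    ns = sum(1 for v in nodes if indeg[v] == 0)
    sinks = sum(1 for v in nodes if outdeg[v] == 0)
    ne = max(0, sinks - ns)
    return nc, ns, nc - ns - ne, ne


def brute_simple_paths(
    edges: list[tuple[str, str]], source: str, target: str
) -> list[list[str]]:
    """All directed paths with no repeated nodes, recursive DFS."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    out: list[list[str]] = []

    def rec(node: str, path: list[str]) -> None:
        if node == target:
            out.append(list(path))
            return
        for nxt in adj.get(node, []):
            if nxt not in path:
                path.append(nxt)
                rec(nxt, path)
                path.pop()

    rec(source, [source])
    return sorted(out)


def dag_path_counts(
    nodes: list[str], edges: list[tuple[str, str]], source: str
) -> dict[str, int]:
    """Number of distinct directed paths from source to every node of a DAG,
    by dynamic programming over a topological order."""
    adj = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for u, v in edges:
        adj[u].append(v)
        indeg[v] += 1
    order, stack = [], [v for v in nodes if indeg[v] == 0]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    assert len(order) == len(nodes), "graph is not acyclic"
    count = {v: 0 for v in nodes}
    count[source] = 1
    for v in order:
        for w in adj[v]:
            count[w] += count[v]
    return count


def brute_binary_lnL(
    branches: dict[str, tuple[str | None, float]],
    tip_states: dict[str, int],
    q01: float,
    q10: float,
    root_prior: tuple[float, float],
) -> float:
    """Log-likelihood of a binary character by explicit summation over every
    internal-state combination. ``branches`` maps node -> (parent, length)."""
    import numpy as np

    def p(t: float, i: int, j: int) -> float:
        s = q01 + q10
        e = np.exp(-s * t)
        pi1 = q01 / s
        pi0 = 1 - pi1
        if i == 0:
            return pi0 + pi1 * e if j == 0 else pi1 - pi1 * e
        return pi0 - pi0 * e if j == 0 else pi1 + pi0 * e

    internals = [n for n in branches if n not in tip_states]
    root = next(n for n, (par, _) in branches.items() if par is None)
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internals)):
        state = dict(tip_states)
        state.update(dict(zip(internals, combo)))
        prob = root_prior[state[root]]
        for node, (par, t) in branches.items():
            if par is not None:
                prob *= p(t, state[par], state[node])
        total += prob
    return float(np.log(total))
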