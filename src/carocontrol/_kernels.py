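"""Numerical hot paths for pruning likelihoods.

The postorder pruning recursion is the inner loop of every ML fit and MCMC
sweep, so it is jitted with numba when available; a pure-numpy fallback
keeps the package functional without it. Both the binary-character and the
multi-state CTMC likelihoods call the same routine.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _prune_jit(P, partial, po_nodes, child_flat, child_off, root_prior):
    n_internal = po_nodes.shape[0]
    k = partial.shape[1]
    log_scale = 0.0
    for i in range(n_internal):
        node = po_nodes[i]
        m = 0.0
        for s in range(k):
            prod = 1.0
            for ci in range(child_off[i], child_off[i + 1]):
                c = child_flat[ci]
                msg = 0.0
                for j in range(k):
                    msg += P[c, s, j] * partial[c, j]
                prod *= msg
            partial[node, s] = prod
            if prod > m:
                m = prod
        if m <= 0.0:
            return -np.inf
        for s in range(k):
            partial[node, s] /= m
        log_scale += np.log(m)
    root = po_nodes[n_internal - 1]
    val = 0.0
    for s in range(k):
        val += root_prior[s] * partial[root, s]
    if val <= 0.0:
        return -np.inf
    return np.log(val) + log_scale


def _prune_numpy(P, partial, po_nodes, child_flat, child_off, root_prior):
    log_scale = 0.0
    for i, node in enumerate(po_nodes):
        kids = child_flat[child_off[i]: child_off[i + 1]]
        prod = np.ones(partial.shape[1])
        for c in kids:
            prod *= P[c] @ partial[c]
        m = prod.max()
        if m <= 0:
            return -np.inf
        partial[node] = prod / m
        log_scale += np.log(m)
    val = root_prior @ partial[po_nodes[-1]]
    if val <= 0:
        return -np.inf
    return float(np.log(val) + log_scale)


prune = _prune_jit if HAVE_NUMBA else _prune_numpy


def flatten_children(children, postorder):
    """Child index arrays (flat + offsets) aligned with the internal-node
    postorder, for the pruning kernels."""
    child_flat, child_off = [], [0]
    for node in postorder:
        child_flat.extend(children[node])
        child_off.append(len(child_flat))
    return (
        np.asarray(child_flat, dtype=np.int64),
        np.asarray(child_off, dtype=np.int64),
    )
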