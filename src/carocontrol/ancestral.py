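"""Binary-character Markov models on a phylogeny, model selection, joint
ancestral-state reconstruction, and assembly of ancestral networks.

Each compound/reaction character evolves as a 2-state continuous-time Markov
chain with gain rate q01 and loss rate q10 (events/my). Two models are fit
per character: Binary-1 constrains q01 = q10 (k = 1 parameter), Binary-2
allows them to differ (k = 2); the model with lower AIC = 2k - 2 lnL is
retained (ties select Binary-1). The root prior defaults to the chain's
stationary distribution pi = (q10, q01)/(q01+q10); a uniform prior is
available. Joint reconstruction is max-product dynamic programming over
internal states with deterministic tie-break to absence (state 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from carocontrol.core_model import (
    CarotenoidNetwork,
    CharacterMatrix,
    Phylogeny,
    is_reaction_character,
    parse_character,
)
from carocontrol.trees import TreeArrays, _as_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "MarkovFit",
    "AncestralNetworkSet",
    "transition_matrix",
    "pruning_lnL",
    "fit_character",
    "joint_ancestral_states",
    "assemble_ancestral_networks",
]

RATE_LO, RATE_HI = 1e-8, 100.0
_LNL_TOL = 1e-8
# fixed multi-start grid on log10(rate); a coarse Latin square over the bounds
_STARTS_2D = np.array(
    [(-3.0, -1.0), (-2.0, 1.0), (-1.0, -3.0), (0.0, 0.0), (1.0, -2.0)]
)


@dataclass
class MarkovFit:
    """Fitted gain/loss model for one binary character."""

    character: str
    model: str  # "Binary-1" or "Binary-2"
    q01: float
    q10: float
    lnL: float
    aic: float
    selected: bool = True
    constant: bool = False
    constant_state: int | None = None


@dataclass
class AncestralNetworkSet:
    """Reconstructed networks at every internal tree node."""

    networks: dict[str, CarotenoidNetwork]  # internal node label -> network
    fits: dict[str, MarkovFit]  # character -> selected fit
    states: pd.DataFrame  # internal node label x character, 0/1
    filter_log: list[tuple[str, tuple[str, str]]] = field(default_factory=list)

    def fits_table(self) -> pd.DataFrame:
        rows = [
            {
                "character": f.character,
                "model": f.model,
                "q01": f.q01,
                "q10": f.q10,
                "lnL": f.lnL,
                "AIC": f.aic,
                "constant": f.constant,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows).set_index("character")


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2-state transition probabilities P_ij(t)."""
    s = q01 + q10
    e = np.exp(-s * t)
    pi1 = q01 / s
    pi0 = q10 / s
    return np.array(
        [[pi0 + pi1 * e, pi1 - pi1 * e], [pi0 - pi0 * e, pi1 + pi0 * e]]
    )


def _root_prior(q01: float, q10: float, kind: str) -> np.ndarray:
    if kind == "stationary":
        s = q01 + q10
        return np.array([q10 / s, q01 / s])
    if kind == "uniform":
        return np.array([0.5, 0.5])
    raise ValueError(f"unknown root prior {kind!r}")


def _tip_state_vector(
    arrays: TreeArrays, tip_states: "Mapping[str, int] | Sequence[int] | np.ndarray"
) -> np.ndarray:
    if isinstance(tip_states, Mapping):
        missing = [t for t in arrays.tip_labels if t not in tip_states]
        if missing:
            raise ValueError(f"missing tip states for {missing}")
        states = np.array([int(tip_states[t]) for t in arrays.tip_labels])
    else:
        states = np.asarray(tip_states, dtype=int)
        if states.shape != (arrays.n_tips,):
            raise ValueError("tip state vector length must equal tip count")
    if not np.isin(states, (0, 1)).all():
        raise ValueError("tip states must be 0/1")
    return states


def pruning_lnL(
    tree: "TreeArrays | Phylogeny",
    tip_states: "Mapping[str, int] | Sequence[int] | np.ndarray",
    q01: float,
    q10: float,
    root_prior: str = "stationary",
) -> float:
    """Log-likelihood of a binary character by Felsenstein's pruning
    algorithm, with per-node rescaling to avoid underflow."""
    if q01 <= 0 or q10 <= 0:
        raise ValueError("rates must be strictly positive")
    arrays = _as_arrays(tree)
    states = _tip_state_vector(arrays, tip_states)
    return _pruning_lnL_fast(arrays, states, q01, q10, root_prior)


def _branch_propagators(arrays: TreeArrays, q01: float, q10: float) -> np.ndarray:
    """Closed-form 2-state P(t) for every branch at once."""
    s = q01 + q10
    e = np.exp(-s * arrays.blen)
    pi1 = q01 / s
    pi0 = q10 / s
    P = np.empty((arrays.n_nodes, 2, 2))
    P[:, 0, 0] = pi0 + pi1 * e
    P[:, 0, 1] = pi1 - pi1 * e
    P[:, 1, 0] = pi0 - pi0 * e
    P[:, 1, 1] = pi1 + pi0 * e
    return P


def _pruning_lnL_fast(
    arrays: TreeArrays, states: np.ndarray, q01: float, q10: float, root_prior: str
) -> float:
    from carocontrol._kernels import flatten_children, prune

    cache = getattr(arrays, "_prune_cache", None)
    if cache is None:
        child_flat, child_off = flatten_children(arrays.children, arrays.postorder)
        cache = (arrays.postorder.astype(np.int64), child_flat, child_off)
        arrays._prune_cache = cache
    po, child_flat, child_off = cache
    partial = np.zeros((arrays.n_nodes, 2))
    partial[np.arange(arrays.n_tips), states] = 1.0
    P = _branch_propagators(arrays, q01, q10)
    prior = _root_prior(q01, q10, root_prior)
    return float(prune(P, partial, po, child_flat, child_off, prior))


def fit_character(
    tree: "TreeArrays | Phylogeny",
    tip_states: "Mapping[str, int] | Sequence[int] | np.ndarray",
    character: str = "",
    root_prior: str = "stationary",
) -> MarkovFit:
    """Fit Binary-1 and Binary-2 by bounded multi-start ML and return the
    lower-AIC model (ties go to Binary-1).

    Constant characters (all tips 0 or all 1) are short-circuited: the rate
    optimum sits at the lower bound and the constant state is propagated
    without model selection.
    """
    arrays = _as_arrays(tree)
    states = _tip_state_vector(arrays, tip_states)
    if states.min() == states.max():
        state = int(states[0])
        q = RATE_LO
        lnl = pruning_lnL(arrays, states, q, q, root_prior)
        logger.debug("character %s constant at state %d", character, state)
        return MarkovFit(
            character, "Binary-1", q, q, lnl, 2 - 2 * lnl,
            constant=True, constant_state=state,
        )

    lo, hi = np.log(RATE_LO), np.log(RATE_HI)

    def nll1(logq: float) -> float:
        q = float(np.exp(np.clip(logq, lo, hi)))
        return -pruning_lnL(arrays, states, q, q, root_prior)

    # the 1-parameter profile is unimodal in practice; bounded scalar search
    best1 = minimize_scalar(
        nll1, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    q1 = float(np.exp(np.clip(best1.x, lo, hi)))
    lnl1 = -float(best1.fun)

    def nll2(logq: np.ndarray) -> float:
        q01, q10 = np.exp(np.clip(logq, lo, hi))
        return -pruning_lnL(arrays, states, float(q01), float(q10), root_prior)

    best2 = None
    starts = list(_STARTS_2D * np.log(10)) + [np.log([q1, q1])]
    for start in starts:
        res = minimize(
            nll2, x0=np.asarray(start, dtype=float), method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)], options={"ftol": _LNL_TOL},
        )
        if best2 is None or res.fun < best2.fun - _LNL_TOL:
            best2 = res
    if not np.isfinite(best2.fun):
        raise RuntimeError(
            f"optimizer failed to converge for character {character!r}: {best2}"
        )
    q01, q10 = (float(np.exp(np.clip(v, lo, hi))) for v in best2.x)
    lnl2 = -float(best2.fun)

    aic1 = 2 * 1 - 2 * lnl1
    aic2 = 2 * 2 - 2 * lnl2
    if aic1 <= aic2:  # tie selects the one-parameter model
        return MarkovFit(character, "Binary-1", q1, q1, lnl1, aic1)
    return MarkovFit(character, "Binary-2", q01, q10, lnl2, aic2)


def joint_ancestral_states(
    tree: "TreeArrays | Phylogeny",
    tip_states: "Mapping[str, int] | Sequence[int] | np.ndarray",
    fit: MarkovFit,
    root_prior: str = "stationary",
) -> dict[str, int]:
    """Jointly most probable internal states (Pupko-style max-product DP).

    Returns {internal node label: state}; exact ties resolve to 0 (absent).
    """
    arrays = _as_arrays(tree)
    states = _tip_state_vector(arrays, tip_states)
    if fit.constant:
        return {lab: int(fit.constant_state) for lab in arrays.internal_labels}
    q01, q10 = fit.q01, fit.q10
    with np.errstate(divide="ignore"):
        # L[x, i]: best log-prob of x's subtree given parent state i
        L = np.full((arrays.n_nodes, 2), -np.inf)
        back = np.zeros((arrays.n_nodes, 2), dtype=int)
        logp = {
            t: np.log(transition_matrix(q01, q10, t))
            for t in np.unique(arrays.blen)
        }
        for x in range(arrays.n_tips):
            L[x] = logp[arrays.blen[x]][:, states[x]]
            back[x] = states[x]
        for x in arrays.postorder:
            sub = np.zeros(2)  # best subtree log-prob given x's own state j
            for c in arrays.children[x]:
                sub += L[c]
            if x == arrays.root:
                prior = np.log(_root_prior(q01, q10, root_prior))
                total = prior + sub
                back[x, :] = 1 if total[1] > total[0] else 0
                L[x, :] = total.max()
            else:
                P = logp[arrays.blen[x]]
                for i in (0, 1):
                    cand = P[i] + sub
                    j = 1 if cand[1] > cand[0] else 0
                    L[x, i] = cand[j]
                    back[x, i] = j
    assignment = np.zeros(arrays.n_nodes, dtype=int)
    root = arrays.root
    assignment[root] = back[root, 0]
    for node in arrays.preorder():
        for c in arrays.children[node]:
            if c >= arrays.n_tips:
                assignment[c] = back[c, assignment[node]]
    return {
        arrays.node_labels[i]: int(assignment[i]) for i in arrays.postorder
    }


def joint_score(
    tree: "TreeArrays | Phylogeny",
    tip_states,
    fit: MarkovFit,
    assignment: Mapping[str, int],
    root_prior: str = "stationary",
) -> float:
    """Log-probability of one full internal-state assignment (used to check
    the joint reconstruction against exhaustive enumeration)."""
    arrays = _as_arrays(tree)
    states = _tip_state_vector(arrays, tip_states)
    full = np.zeros(arrays.n_nodes, dtype=int)
    full[: arrays.n_tips] = states
    for i in arrays.postorder:
        full[i] = assignment[arrays.node_labels[i]]
    prior = _root_prior(fit.q01, fit.q10, root_prior)
    total = np.log(prior[full[arrays.root]])
    for node in range(arrays.n_nodes):
        p = arrays.parent[node]
        if p >= 0:
            P = transition_matrix(fit.q01, fit.q10, arrays.blen[node])
            total += np.log(P[full[p], full[node]])
    return float(total)


def assemble_ancestral_networks(
    tree: "TreeArrays | Phylogeny",
    matrix: CharacterMatrix,
    master: CarotenoidNetwork,
    root_prior: str = "stationary",
) -> AncestralNetworkSet:
    """Fit every master character, reconstruct joint ancestral states, and
    assemble one network per internal node.

    Reactions whose endpoint compounds are absent at a node are dropped and
    logged (endpoint consistency filter).
    """
    arrays = _as_arrays(tree)
    fits: dict[str, MarkovFit] = {}
    states: dict[str, dict[str, int]] = {}
    for character in matrix.characters:
        tip_states = matrix.states(character).to_dict()
        fit = fit_character(arrays, tip_states, character, root_prior)
        fits[character] = fit
        states[character] = joint_ancestral_states(arrays, tip_states, fit, root_prior)
    state_df = pd.DataFrame(states, index=arrays.internal_labels).astype(int)

    networks: dict[str, CarotenoidNetwork] = {}
    filter_log: list[tuple[str, tuple[str, str]]] = []
    for label in arrays.internal_labels:
        compounds = [
            parse_character(ch)
            for ch in matrix.characters
            if not is_reaction_character(ch) and state_df.loc[label, ch] == 1
        ]
        reactions = [
            parse_character(ch)
            for ch in matrix.characters
            if is_reaction_character(ch) and state_df.loc[label, ch] == 1
        ]
        if not compounds:
            # a node reconstructed empty keeps a placeholder dietary compound
            # so N >= 1 holds; flagged via the filter log
            filter_log.extend((label, r) for r in reactions)
            networks[label] = CarotenoidNetwork(
                label, [next(iter(master.compounds.values()))], []
            )
            continue
        net, dropped = master.subnetwork(compounds, reactions, label)
        filter_log.extend((label, key) for key in dropped)
        networks[label] = net
    if filter_log:
        logger.info(
            "endpoint consistency filter dropped %d reactions across %d nodes",
            len(filter_log), len({n for n, _ in filter_log}),
        )
    return AncestralNetworkSet(networks, fits, state_df, filter_log)
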