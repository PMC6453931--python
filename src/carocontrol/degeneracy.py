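"""Simple-path degeneracy, pathway lengths, node occupancy rates, and the
gain/loss regressions.

Biochemical degeneracy of a derived compound is the number of directed
simple paths (no repeated compounds) reaching it from the network's dietary
inputs; compounds supported by many short paths are structurally redundant.
Occupancy rates translate reconstructed per-branch presence changes into
"one gain every X my" intervals. The "likelihood of gain/loss" of a node is
operationalized as events per my of total branch time, consistent with the
interval phrasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from carocontrol.ancestral import AncestralNetworkSet
from carocontrol.core_model import (
    CarotenoidNetwork,
    CharacterMatrix,
    Phylogeny,
    compound_character,
)
from carocontrol.trees import TreeArrays, _as_arrays

__all__ = [
    "DegeneracyRecord",
    "OccupancyRecord",
    "simple_paths",
    "compound_redundancy",
    "pathway_length",
    "occupancy_rates",
    "gain_loss_regression",
    "GainLossRegression",
]

NODE_CAP = 60
PATH_CAP = 1_000_000


@dataclass
class DegeneracyRecord:
    """Simple-path support of one derived compound from all dietary inputs."""

    compound: str
    n_paths: int
    mean_L: float  # mean path length in reactions; nan when n_paths == 0
    per_dietary: dict[str, int] = field(default_factory=dict)


@dataclass
class OccupancyRecord:
    """Whole-tree pooled gain/loss counts for one compound character."""

    character: str
    gains: int
    losses: int
    total_time: float  # my of branch time summed over the tree
    distance_class: int | None  # reactions from the nearest dietary input
    pathway_type: str  # "linear" or "degenerate"
    n_dietary_support: int  # dietary compounds that reach it

    @property
    def gain_interval(self) -> float | None:
        return self.total_time / self.gains if self.gains else None

    @property
    def loss_interval(self) -> float | None:
        return self.total_time / self.losses if self.losses else None

    @property
    def gain_rate(self) -> float:
        return self.gains / self.total_time

    @property
    def loss_rate(self) -> float:
        return self.losses / self.total_time


def simple_paths(
    network: CarotenoidNetwork, source: str, target: str
) -> list[list[str]]:
    """All directed simple paths source -> target, lexicographically ordered.

    Guards: node cap (default 60) and path cap (1e6) raise explicit overflow
    errors rather than running away on dense graphs.
    """
    for cid in (source, target):
        if cid not in network.compounds:
            raise KeyError(f"unknown compound {cid!r}")
    if network.n_compounds > NODE_CAP:
        raise OverflowError(
            f"network has {network.n_compounds} compounds > cap {NODE_CAP}"
        )
    g = network.to_digraph()
    paths = []
    for path in nx.all_simple_paths(g, source, target):
        paths.append(list(path))
        if len(paths) > PATH_CAP:
            raise OverflowError(f"more than {PATH_CAP} simple paths")
    paths.sort()
    return paths


def compound_redundancy(
    network: CarotenoidNetwork, compound: str
) -> DegeneracyRecord:
    """Aggregate simple-path counts from every dietary input to one derived
    compound; unreachable compounds yield n_paths = 0 with mean_L = nan."""
    c = network.compounds[compound]
    if c.role != "derived":
        raise ValueError(f"{compound!r} is dietary; degeneracy applies to derived compounds")
    per_dietary: dict[str, int] = {}
    lengths: list[int] = []
    for d in network.dietary_ids:
        paths = simple_paths(network, d, compound)
        per_dietary[d] = len(paths)
        lengths.extend(len(p) - 1 for p in paths)
    n = sum(per_dietary.values())
    return DegeneracyRecord(
        compound=compound,
        n_paths=n,
        mean_L=float(np.mean(lengths)) if lengths else float("nan"),
        per_dietary=per_dietary,
    )


def pathway_length(network: CarotenoidNetwork) -> float:
    """Average enzymatic pathway length: for each deposited terminal derived
    compound, the longest of the shortest-path lengths from the dietary
    compounds that reach it; averaged over those compounds. 0 when the
    network has no deposited terminal derived compound (category-1 case)."""
    g = network.to_digraph()
    terminals = [
        c.id
        for c in network.compounds.values()
        if c.role == "derived" and c.deposited and g.out_degree(c.id) == 0
    ]
    if not terminals:
        return 0.0
    lengths = []
    sp = {d: nx.single_source_shortest_path_length(g, d) for d in network.dietary_ids}
    for t in terminals:
        minima = [sp[d][t] for d in network.dietary_ids if t in sp[d]]
        if minima:
            lengths.append(max(minima))
    return float(np.mean(lengths)) if lengths else 0.0


def _control_class_of(compound: str, network: CarotenoidNetwork) -> str:
    if compound not in network.compounds:
        return "absent"
    if network.compounds[compound].role == "dietary":
        return "source"
    g = network.to_digraph()
    indeg, outdeg = g.in_degree(compound), g.out_degree(compound)
    if outdeg == 0:
        return "sink"
    if 0 < indeg < outdeg:
        return "internal"
    return "other"


def occupancy_rates(
    ancestral_set: AncestralNetworkSet,
    tree: "TreeArrays | Phylogeny",
    master: CarotenoidNetwork,
    tip_matrix: CharacterMatrix,
    *,
    include_tip_branches: bool = True,
) -> tuple[list[OccupancyRecord], pd.DataFrame]:
    """Per-compound gain/loss events pooled over the whole tree, plus a
    per-control-class aggregation.

    A gain (0 -> 1) or loss (1 -> 0) is counted on every branch whose parent
    and child presence states differ. Intervals are total branch time divided
    by event count. Class events are attributed by the compound's control
    class in the network at the end of the branch where it is present (the
    child for a gain, the parent for a loss).
    """
    arrays = _as_arrays(tree)
    states = pd.concat([tip_matrix.data, ancestral_set.states])
    missing = [lab for lab in arrays.tip_labels if lab not in states.index]
    if missing:
        raise ValueError(f"tree tips without states: {missing}")

    node_networks: dict[str, CarotenoidNetwork] = dict(ancestral_set.networks)
    total_time = float(
        sum(
            arrays.blen[i]
            for i in range(arrays.n_nodes)
            if arrays.parent[i] >= 0 and (include_tip_branches or i >= arrays.n_tips)
        )
    )
    compounds = sorted(master.compounds)
    records: list[OccupancyRecord] = []
    class_events = {
        cls: {"gains": 0, "losses": 0} for cls in ("source", "internal", "sink", "other")
    }
    master_g = master.to_digraph()
    # distance and degeneracy support from the master network
    dist: dict[str, int] = {}
    support: dict[str, int] = {}
    for d in master.dietary_ids:
        sp = nx.single_source_shortest_path_length(master_g, d)
        for v, length in sp.items():
            if v == d:
                continue
            dist[v] = min(dist.get(v, length), length)
            support[v] = support.get(v, 0) + 1

    for compound in compounds:
        ch = compound_character(compound)
        if ch not in states.columns:
            continue
        gains = losses = 0
        for child in range(arrays.n_nodes):
            p = arrays.parent[child]
            if p < 0 or (not include_tip_branches and child < arrays.n_tips):
                continue
            s_parent = int(states.loc[arrays.node_labels[p], ch])
            s_child = int(states.loc[arrays.node_labels[child], ch])
            if s_parent == s_child:
                continue
            event = "gains" if s_child == 1 else "losses"
            if event == "gains":
                gains += 1
            else:
                losses += 1
            # class attribution at the branch end where the compound exists
            ref_label = arrays.node_labels[child if event == "gains" else p]
            net = node_networks.get(ref_label)
            if net is None:
                cls = (
                    "source"
                    if master.compounds[compound].role == "dietary"
                    else "other"
                )
            else:
                cls = _control_class_of(compound, net)
                if cls == "absent":
                    cls = "other"
            class_events.setdefault(cls, {"gains": 0, "losses": 0})[event] += 1
        is_dietary = master.compounds[compound].role == "dietary"
        records.append(
            OccupancyRecord(
                character=ch,
                gains=gains,
                losses=losses,
                total_time=total_time,
                distance_class=0 if is_dietary else dist.get(compound),
                pathway_type="degenerate" if support.get(compound, 0) >= 2 else "linear",
                n_dietary_support=(
                    0 if is_dietary else support.get(compound, 0)
                ),
            )
        )
    rows = []
    for cls, ev in class_events.items():
        rows.append(
            {
                "control_class": cls,
                "gains": ev["gains"],
                "losses": ev["losses"],
                "gain_interval_my": total_time / ev["gains"] if ev["gains"] else np.nan,
                "loss_interval_my": total_time / ev["losses"] if ev["losses"] else np.nan,
            }
        )
    return records, pd.DataFrame(rows).set_index("control_class")


@dataclass
class GainLossRegression:
    params: pd.Series  # const, n_paths, mean_L
    r_squared: float
    pvalues: pd.Series
    partial_residuals: pd.DataFrame
    n: int


def gain_loss_regression(
    responses: "pd.Series | dict[str, float]",
    degeneracy_records: list[DegeneracyRecord],
    *,
    allow_reduced: bool = False,
) -> GainLossRegression:
    """OLS of (gain rate - loss rate) on path count and mean path length.

    ``responses`` maps compound id -> (gain likelihood - loss likelihood) in
    events/my. Collinear/constant predictors raise unless ``allow_reduced``
    drops the offending column.
    """
    responses = pd.Series(responses)
    rows = {
        rec.compound: (rec.n_paths, rec.mean_L)
        for rec in degeneracy_records
        if rec.compound in responses.index and np.isfinite(rec.mean_L)
    }
    if len(rows) < 3:
        raise ValueError("need at least 3 compounds with defined responses")
    X = pd.DataFrame.from_dict(rows, orient="index", columns=["n_paths", "mean_L"])
    y = responses.loc[X.index].astype(float)
    dropped = [c for c in X.columns if X[c].nunique() == 1]
    full = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(full.to_numpy()) < full.shape[1]:
        if not allow_reduced or not dropped:
            raise ValueError(
                f"rank-deficient design (constant/collinear predictors: {dropped or 'collinear'})"
            )
        X = X.drop(columns=dropped)
        full = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.OLS(y, full).fit()
    resid = fit.resid
    partial = pd.DataFrame(index=X.index)
    for col in X.columns:
        partial[f"partial_{col}"] = resid + fit.params[col] * (X[col] - X[col].mean())
    return GainLossRegression(
        params=fit.params,
        r_squared=float(fit.rsquared),
        pvalues=fit.pvalues,
        partial_residuals=partial,
        n=len(y),
    )
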