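"""Erdős–Rényi null models for observed networks.

For a network of n compounds and r reactions, the null draws exactly r
distinct directed edges uniformly without replacement from the n(n-1)
ordered pairs (no self-loops). The null conserves (n, r) but not the degree
distribution, which is the point of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from carocontrol.core_model import CarotenoidNetwork, Compound, Reaction
from carocontrol.controllability import ControlProfile, control_profile

__all__ = ["RandomizationReport", "er_randomize", "randomize_and_compare"]


@dataclass
class RandomizationReport:
    """Observed-vs-random comparison for one network."""

    label: str
    observed: ControlProfile
    replicates: list[ControlProfile]
    seed: int
    canonical_orientation: bool  # True when reversible reactions were fixed canonically

    @property
    def k(self) -> int:
        return len(self.replicates)

    def _stat(self, attr: str) -> np.ndarray:
        return np.array([getattr(p, attr) for p in self.replicates], dtype=float)

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean and s.e.m. (k-1 denominator) of Nc/N and the eta ratios, plus
        observed minus random-mean differences."""
        out: dict[str, dict[str, float]] = {}
        stats = {
            "nc_over_n": self._stat("Nc") / self.observed.N,
            "eta_s": self._stat("eta_s"),
            "eta_i": self._stat("eta_i"),
            "eta_e": self._stat("eta_e"),
        }
        observed = {
            "nc_over_n": self.observed.Nc / self.observed.N,
            "eta_s": self.observed.eta_s,
            "eta_i": self.observed.eta_i,
            "eta_e": self.observed.eta_e,
        }
        for name, values in stats.items():
            sem = float(values.std(ddof=1) / np.sqrt(self.k)) if self.k > 1 else float("nan")
            out[name] = {
                "observed": observed[name],
                "random_mean": float(values.mean()),
                "random_sem": sem,
                "difference": observed[name] - float(values.mean()),
            }
        return out


def er_randomize(
    n: int, r: int, rng_seed: int | np.random.Generator, labels: list[str] | None = None
) -> CarotenoidNetwork:
    """Uniform random digraph with n nodes and exactly r directed edges.

    Sampling is rejection-free: r ordered pairs are drawn without replacement
    from the n(n-1) possibilities. In-degree-0 nodes get the dietary role so
    the result validates as a network input structure.
    """
    if not 0 <= r <= n * (n - 1):
        raise ValueError(f"r={r} outside [0, n(n-1)={n * (n - 1)}]")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if labels is None:
        width = len(str(n - 1))
        labels = [f"v{i:0{width}d}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    codes = rng.choice(n * (n - 1), size=r, replace=False)
    edges = []
    for code in sorted(int(c) for c in codes):
        u, rem = divmod(code, n - 1)
        v = rem if rem < u else rem + 1  # skip the diagonal: no self-loops
        edges.append((labels[u], labels[v]))
    targets = {v for _, v in edges}
    compounds = [
        Compound(lab, "derived" if lab in targets else "dietary") for lab in labels
    ]
    reactions = [Reaction(u, v, False) for u, v in edges]
    return CarotenoidNetwork("er", compounds, reactions)


def randomize_and_compare(
    network: CarotenoidNetwork,
    k: int = 10,
    rng_seed: int = 0,
    *,
    count_reversible_as_two: bool = False,
) -> RandomizationReport:
    """k ER replicates with the network's (n, r) and the observed-vs-random
    control profile comparison.

    Networks with reversible reactions are compared on the canonical
    (lexicographically first) orientation; by default each reversible
    reaction contributes one directed edge to r (``count_reversible_as_two``
    counts both directions).
    """
    if k < 1:
        raise ValueError("need at least one replicate")
    canonical = not network.is_oriented
    oriented = network.oriented() if canonical else network
    observed = control_profile(oriented)
    n = network.n_compounds
    r = network.n_reactions
    if count_reversible_as_two:
        r += sum(1 for rx in network.reactions.values() if rx.reversible)
    rng = np.random.default_rng(rng_seed)
    replicates = [control_profile(er_randomize(n, r, rng)) for _ in range(k)]
    return RandomizationReport(
        label=network.label,
        observed=observed,
        replicates=replicates,
        seed=rng_seed,
        canonical_orientation=canonical,
    )
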