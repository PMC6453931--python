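# carocontrol

Structural controllability and phylogenetic evolution of diet-derived
enzymatic networks, built for the avian carotenoid system: birds cannot
synthesize carotenoids, so plumage pigmentation depends on dietary compounds
(network inputs) that enzymes convert into derived compounds. `carocontrol`
asks *who controls such a network* — the dietary inputs, the internal
branch points of the metabolism, or its terminal products — and how that
control regime evolves across a phylogeny.

It is aimed at researchers in comparative biology and network evolution who
have per-species metabolic networks (node/edge tables), an ultrametric tree
in millions of years (my), and want reproducible control-profile, null-model,
ancestral-reconstruction, degeneracy and trait-evolution analyses, plus a
synthetic-data generator with recorded ground truth for validating all of it.

## The core quantities

For a directed network with `N` compounds, a **maximum matching** is the
largest set of reactions sharing no substrate and no product. Nodes not
pointed to by a matched reaction cannot be driven by an upstream neighbour,
so the minimum number of controls is

```
Nc = max(1, N − N_matched)
```

decomposed as **source controls** `Ns` (nodes with in-degree 0 — the dietary
compounds), **sink controls** `Ne = max(0, #sinks − #sources)` (excess of
terminal nodes over inputs), and **internal controls** `Ni = Nc − Ns − Ne`
(enzymatic expansion points where outgoing connectivity exceeds upstream
supply). The **control profile** is the triple

```
η_s = Ns/Nc,   η_i = Ni/Nc,   η_e = Ne/Nc
```

Networks fall into six categories: (1) bare dietary deposition, (2) linear
and (3) degenerate source-controlled networks (η_s = 1), (4) networks with
an internal control, (6) with a sink control, and (5) requiring all three.

Around this core the package provides Erdős–Rényi nulls with identical
(n, r); binary-character Markov models (equal-rate and unequal-rate gain/loss,
selected by AIC) with joint maximum-likelihood ancestral reconstruction;
simple-path degeneracy and occupancy-rate statistics; multi-state CTMC
transition models with spike-at-zero posteriors (zero-rate fraction `z`);
Pagel-style correlated-evolution tests with stepping-stone marginal
likelihoods; independent contrasts; and ternary trajectory binning.

## Worked example

```python
from carocontrol import (CarotenoidNetwork, Compound, Reaction,
                         control_profile, classify_category)
from carocontrol.randomization import randomize_and_compare

net = CarotenoidNetwork(
    "house_finch_like",
    [Compound("lutein", "dietary"), Compound("zeaxanthin", "dietary"),
     Compound("3dehydrolutein", "derived", deposited=True),
     Compound("canary_xanthophyll_A", "derived", deposited=True),
     Compound("canary_xanthophyll_B", "derived", deposited=True)],
    [Reaction("lutein", "3dehydrolutein"), Reaction("zeaxanthin", "3dehydrolutein"),
     Reaction("3dehydrolutein", "canary_xanthophyll_A"),
     Reaction("3dehydrolutein", "canary_xanthophyll_B")],
)
p = control_profile(net)
print(f"N={p.N}  Nc={p.Nc}  (Ns, Ni, Ne)=({p.Ns}, {p.Ni}, {p.Ne})")
print(f"control profile = ({p.eta_s:.3f}, {p.eta_i:.3f}, {p.eta_e:.3f})")
print("category:", classify_category(p, net))
s = randomize_and_compare(net, k=10, rng_seed=1).summary()
print(f"observed eta_i = {s['eta_i']['observed']:.3f}, "
      f"ER-random mean = {s['eta_i']['random_mean']:.3f}")
```

prints

```
N=5  Nc=3  (Ns, Ni, Ne)=(2, 1, 0)
control profile = (0.667, 0.333, 0.000)
category: 4
observed eta_i = 0.333, ER-random mean = 0.000
```

Two redundant dietary inputs merge at one derived compound which then
branches: the merge point needs its own (internal) control, so a third of
the control burden has moved inside the metabolism (category 4) — a feature
the size-matched random networks do not show.

## Command line

`carocontrol` exposes `profile`, `randomize`, `degeneracy`, `simulate` and
`run` subcommands; `carocontrol run --config run.yaml` executes the full
pipeline (simulate/load → profile → randomize → reconstruct → degeneracy →
transitions) and writes per-stage CSVs and a JSON manifest that reproduces
the run.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch on the synthetic world (a master
network at the emulated avian scale — 14 dietary inputs, 55 compounds, 88
reactions — evolved along a 32-tip ultrametric tree) and writes the target
report to `--out`.
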