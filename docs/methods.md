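# Methods

This note documents the models, numerical choices and open design decisions
behind `carocontrol`, in the spirit of the methods documentation shipped by
statistical packages: it states what the code computes and under which
assumptions, not results — every number reported elsewhere is produced by
the tests or by `scripts/acceptance.py` at run time.

## Structural controllability

The controllable portion of a directed network is determined by a maximum
matching on its bipartite representation (each compound split into an
out-copy and an in-copy; every reaction is an edge between an out-copy and
an in-copy). The matching is computed with Hopcroft–Karp (networkx). A node
pointed to by a matched edge is driven by an upstream neighbour; the rest
need independent controls, so `Nc = max(1, N − N_matched)`. The floor at 1
covers perfectly matched (cycle-covered) graphs, which can arise in
Erdős–Rényi nulls but not in source-anchored metabolic networks.

**Counting vs identity.** Which specific nodes are unmatched depends on the
matching chosen (ties are common), so control counts use the
matching-independent decomposition: `Ns` = number of sources (in-degree 0,
isolated nodes included), `Ne` = excess of sinks over sources, `Ni` =
remainder. The degree-asymmetry view ("internal controls have
in-degree < out-degree") is exposed separately by
`control_node_identities`, which reports for each compound whether *some*
maximum matching leaves it unmatched (tested by deleting its in-copy and
recomputing the matching size). The counting rule is authoritative because
the identity rule mislabels the canonical merge-and-branch motif
(d1→m←d2, m→p1, m→p2): the third control there is internal although `m`
has symmetric degree.

**Orientation variants.** Reversible reactions are stored once
(lexicographic canonical order). All `2^k` orientations are enumerated up to
a cap (default 4096); beyond it variants are sampled with a declared seed
and flagged approximate. Within each variant a reaction is critical if its
removal changes `Nc`; a reaction is classed `always`/`sometimes`/`never`
across variants.

## Erdős–Rényi null

For a network with `n` compounds and `r` reactions the null draws exactly
`r` ordered pairs without replacement from the `n(n−1)` off-diagonal pairs
(rejection-free, via indexing the pair lattice), so `(n, r)` is conserved
exactly while degree distributions vary. Ten replicates per network by
default; s.e.m. uses the `k−1` denominator. Networks with reversible
reactions are compared on the canonical orientation, each reversible
reaction counting as one directed edge toward `r` (a flag counts both
directions).

## Binary-character evolution and ancestral networks

Each compound and reaction is a binary presence/absence character evolving
as a 2-state CTMC with gain rate `q01` and loss rate `q10` (events/my).
Likelihoods use Felsenstein pruning with closed-form 2-state transition
probabilities and per-node rescaling; the inner recursion is a shared,
numba-jitted kernel also used by the multi-state models (with a pure-numpy
fallback), so the 2-state CTMC likelihood and the binary pruning likelihood
agree to machine precision — a tested invariant.

* Models: equal-rate (1 parameter) vs unequal-rate (2 parameters), selected
  by AIC = 2k − 2 lnL; ties go to the simpler model.
* Optimization: log-parameterized, bounds `[1e-8, 100]` events/my; the
  1-parameter model by bounded scalar minimization, the 2-parameter model by
  L-BFGS-B from a fixed 5-point log-grid plus a warm start at the symmetric
  optimum; lnL tolerance 1e-8.
* Root prior: stationary distribution `π1 = q01/(q01+q10)` by default
  (the standard choice for unconstrained 2-state chains; widely used
  reconstruction tools do not document theirs), `uniform` available.
* Constant characters short-circuit: the rate optimum sits at the lower
  bound and the constant state propagates to all nodes, logged.
* Joint reconstruction is max-product dynamic programming over internal
  states (Pupko-style) with deterministic tie-break to absence; its score
  can never exceed the marginal likelihood (tested).
* Ancestral networks take all compounds/reactions present at a node;
  reactions with a missing endpoint are dropped and logged (endpoint
  consistency filter). Characters are reconstructed independently, so the
  filter is a post-hoc repair whose frequency is inspectable.
* Deeper nodes are reconstructed less reliably; trajectory analyses
  therefore window to the most recent 45 my by default.

## Degeneracy and occupancy

Degeneracy of a derived compound is the number of directed simple paths
from every dietary input, enumerated by DFS (networkx `all_simple_paths`)
with deterministic lexicographic output, guarded by node (60) and path
(1e6) caps. On DAGs the totals equal a dynamic-programming count — used as
an independent oracle in the tests.

"Likelihood of gain/loss" of a node is operationalized as events per my:
per-branch parent/child state differences pooled over the whole tree
(tip branches included by default; both conventions are exposed), divided
into the summed branch time. The gain-minus-loss response is regressed by
OLS on path count and mean path length jointly (statsmodels), with partial
residuals for plotting; rank-deficient designs raise unless a reduced model
is requested.

## Control-regime macroevolution

Categories at every node (from the per-node networks) give per-branch
transition events. Two transition tallies are reported, because the
denominator convention is genuinely ambiguous: category changes per branch,
and control-count changes pooled over the three classes.

**CTMC fits.** Branch lengths are rescaled to a mean of 0.1 before rate
estimation (so rates are O(1) per scaled unit), ML rates by bounded
L-BFGS-B on log-rates with multiple starts. The zero-rate fraction `z` per
rate comes from a Metropolis sampler with an independent spike-and-slab
prior on each rate: point mass 0.5 at exactly zero, slab exponential
(mean 10) or uniform(0, 100). Toggle moves propose from the slab (so slab
densities cancel); scale moves are log-normal random walks with the
Jacobian correction. Defaults 40 000 iterations, 1 000 burn-in, thinning 20
— a 1/1000 scaling of typical full-scale reverse-jump runs; `z` retains its
meaning as the fraction of sampled models in which the rate is zero, with
classes <1.5% / ≤10% / ≤20% / >20%.

**Correlated evolution.** Two binary characters (control class:
η_s-dominated categories 1–3 vs η_i-dominated 4–5, category 6 excluded;
dietary richness: ≤2 vs >2 dietary compounds — both thresholds are
configuration values) are compared under an independent model (two 2-state
chains; 4 free rates tied across the 4-state joint space) and a dependent
model (8 single-change rates; dual transitions forbidden). Marginal
likelihoods by stepping-stone sampling along the Beta(0.4, 1.0) quantile
schedule (`β_k = (k/K)^{2.5}`), default 100 stones × 1000 iterations; one
iteration is one single-rate Metropolis proposal, the prior stone is
sampled directly. The rate prior is exponential with mean 1 — mass at the
O(1) scale that motivates the 0.1 mean-branch rescaling; a diffuse prior
mostly inflates the dependent model's dimensionality penalty and the
stepping-stone variance at reduced scale. log BF = dependent − independent.

**Contrasts and trajectories.** Felsenstein contrasts with seeded random
polytomy resolution (zero-length inserted branches; `tips − 1` contrasts on
a binary tree). Ancestral control profiles are binned by node age in
left-open right-closed 10-my bins (nodes at exactly the boundary fall in
the older-edge bin of the younger interval), windowed to 45 my; the cycle
amplitude of a lineage group is the range of the per-bin mean `η_s − η_i`
divided by the time spanned by the populated bins. Per-branch evolution
rate is (reactions gained + lost)/branch length; standardized OLS on ΔNs
and ΔNi with squared-semipartial variance decomposition, and group means
for loss/retention/gain of each control class.

## Synthetic world

The generator emulates the structure and scale of the combined avian
carotenoid network, not its chemistry:

* Master network: 14 dietary inputs, 55 compounds, 88 reactions. Each
  derived compound attaches to a dietary parent or (with probability
  `branching_bias`, default 0.4) an existing derived compound; remaining
  reactions connect lower-rank to higher-rank compounds, keeping the graph
  acyclic, dietary in-degree 0, and creating the merge points that generate
  internal control. 15% of derived–derived reactions are marked reversible
  (bidirectionality between derived compounds is widespread in the real
  system).
* Phylogeny: seeded Yule process with 64 tips scaled to 90 my root depth.
* Evolution: every character follows an independent 2-state chain simulated
  by Gillespie along each branch, so the truth records every individual
  event, not just endpoints. Root = full master (a sparse, dietary-only
  root is available). An optional modular mode gains/loses whole
  dietary-anchored modules at once, to stress the independence assumption
  of the inference model.
* Rates: symmetric 0.01 events/my for compounds and 0.012 events/my for
  reactions. The real system's class-level event intervals of a few my,
  pooled over ~14 dietary characters on a tree of total length on the order
  of 10^3 my, put per-character rates at 0.01–0.02 events/my; the defaults
  sit at that order of magnitude and are fixed, not tuned.

What a green test establishes: that the estimators recover a world whose
generating process matches the inference model (independent characters,
time-homogeneous rates, correct tree). Real networks violate all three to
unknown degrees — characters are linked by the consistency constraint,
rates vary across lineages, and the tree is itself estimated — so recovery
accuracies measured here are upper bounds, not guarantees.

Calibration worlds are likewise fixed: the correlated-evolution check uses
32-tip trees (mean branch 0.1 after rescaling), true rates 1.0, and for the
dependence case a chain in which matched joint states are sticky
(mismatch-correcting rates 10× the matched-state rates). Smaller trees
(16 tips) leave such tests underpowered, as expected for this family of
tests.

## Known limitations

* Ancestral reconstruction treats characters independently; the endpoint
  filter repairs but does not model the dependency between a reaction and
  its substrates.
* The spike-and-slab sampler runs on a single tree; topological uncertainty
  (originally handled by sampling over a tree distribution) is supported
  only by looping externally over user-supplied trees.
* The stepping-stone estimator at reduced scale (20 stones × 200
  iterations) carries Monte-Carlo noise of order ±0.5 on log marginal
  likelihoods; borderline Bayes factors (|log BF| near 2) should be re-run
  at the full 100 × 1000 defaults.
* Simple-path enumeration is exponential in the worst case; the caps make
  overflow explicit rather than preventing it.
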