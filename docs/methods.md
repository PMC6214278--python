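# Methods

## Problem and approach

Given an undirected simple graph `G(N, E)`, the task is to name the top-k
most efficient spreaders (k = 1%…10% of `|N|`) while observing only a sample
of the graph.  A sampler explores `G`, the discovered subgraph is ranked by a
centrality measure, and the ranking is scored against an epidemic-simulation
ground truth.  The package implements the full loop: samplers, epidemic
models with calibration, centralities, and the evaluation statistics.

## The maxRD sampler

maxRD runs `s` parallel traverses from uniformly drawn seeds (default
`s = 1%` of `|N|`).  Each round, every current seed `i` selects its
neighbour `j` of maximum **residual degree** — the degree in a working copy
of the graph from which every previously crossed edge has been deleted — the
edge `{i, j}` is removed from the working copy, and `j` joins the next
round's seed set.  Nodes are never removed, so a node can be re-entered along
a different path, but no edge is crossed twice.  The sample is the set of
crossed edges; the sampler halts after the first full round in which the
discovered-node count reaches `⌈x·|N|⌉` (default `x = 0.2`), so a slight
overshoot is possible.

Choices where the published description is ambiguous:

- **Tie-break.** Several neighbours can share the maximum residual degree
  (frequent at small degrees).  Ties are broken uniformly at random from the
  run's seeded generator, avoiding any node-id-order bias while staying
  exactly reproducible.
- **Random jump.** The traverse can strand (every current seed out of
  incident edges).  The jump fires on that exhaustion condition and re-seeds
  with `s` fresh uniform nodes.  A stricter trigger — jump as soon as every
  current seed has residual degree ≤ 1 — is available as
  `maxrd_jump_trigger="degree_one"`; exhaustion is the default because it is
  the only condition under which the walker is actually stuck.
- **Duplicate frontier collapse.** If several seeds select the same `j` in
  one round, `j` enters the next seed set once; all distinct crossed edges
  are kept.

With a fixed seed a run is bit-identical across repetitions, and on a graph
whose relevant neighbourhoods have strict degree orderings the traverse is
deterministic irrespective of the RNG (verified against a hand-simulated
trace in the tests).

## Baseline samplers

- **Forest Fire**: from each frontier node burn `x ~ Geometric` edges to
  unburned neighbours, `x` with support {0, 1, 2, …} and mean
  `p_f/(1−p_f)` (`p_f = 0.7` default, mean 7/3); burned nodes are never
  revisited; a dead fire restarts from a fresh uniform unburned node.  One
  initial seed by convention.
- **MHRW**: `s` parallel walks; move `x→y` (y uniform among neighbours)
  accepted with probability `min(1, deg(x)/deg(y))` using original-graph
  degrees, making the walk's stationary distribution uniform over nodes.
  Rejections cross no edge; trapped walks simply stop contributing.
- **Metropolis–Hastings (centralized)**: a fixed-size node sample; each
  iteration proposes swapping one in-sample node for one outside.  Quality is
  the L1 distance between the normalized degree histograms of the induced
  subgraph and of `G`; improving swaps are accepted, degrading ones with
  probability `Δ_old/Δ_new`.  The objective and acceptance rule are this
  package's concrete choices for a scheme the literature leaves open; both
  the iteration budget (default 20 000) and the rule live in
  `SamplerConfig`.  The histogram is maintained incrementally, so an
  iteration costs O(deg).

## Epidemic models

Time is discrete with synchronous updates; "probability per unit time" is a
per-period probability, which matches the period-based equilibrium protocol.
Within a period infections are evaluated before recoveries, and nodes
infected this period neither transmit nor recover until the next — with
γ = 1 any other order would make transmission impossible.

- **SIR** (`β` infection, `γ` recovery, default γ = 1): runs to extinction;
  `M_i` counts every node ever infected, including the seed, so
  `M_i ∈ [1, |N|]`.  With γ = 1 the model is exactly bond percolation with
  occupation probability β, which the tests exploit as an exhaustive oracle
  on tiny graphs.  Simulation is vectorized as (runs × nodes) boolean
  matrices against a sparse adjacency: a susceptible node with `m` infected
  neighbours is infected with probability `1 − (1−β)^m`, which is exact
  because attempts on distinct targets are independent.
- **SIS** (`ν` infection, `δ` recovery, default δ = 0.8): starts from 20% of
  nodes infected uniformly at random, runs until the equilibrium protocol
  declares the stable state, then measures persistence `ρ_v` as the fraction
  of the next 100 periods (configurable) node `v` is infected.

**Equilibrium protocol.**  Track `Δ(I) = I(t+1) − I(t)` of the infected
density.  After the first `Δ(I) ≥ 0`, rest 100 periods; then declare
equilibrium at the first period where the running mean of `Δ(I)` over a
window of ≥ 100 periods satisfies `|mean| ≤ tol`.  The window mean
telescopes to `(I(t) − I(w₀))/(t − w₀)`, so the online check is O(1).
`tol` defaults to 0.5 nodes per period (0.5/|N| in density units) — a
concrete reading of "close to zero".  Extinction satisfies the protocol with
`Δ(I) = 0` and is returned as an all-zero, flagged persistence rather than
an error, because the SIS calibration is defined by observing exactly that
outcome.  Exceeding `max_periods` (default 20 000) without equilibrium
raises a "no equilibrium" error.

**Calibration.**  Both scans walk `p = 1, 1.1, 1.2, …` (default up to 3.0):

- SIR: `T* = p·T^c` is the first grid point at which, in *every* simulation
  instance, the instance's own top-20% nodes average an outbreak strictly
  larger than 1% of `|N|` (strict ">", per the criterion's wording).
- SIS: `λ̂` is the first grid point with non-zero mean equilibrium density
  over `n_runs` independent runs (default 10); `λ*` the first ≥ λ̂ with
  density ≥ 1% (inclusive "≥").

Persistence ground truth averages over `n_simulations` independent runs
(configurable down to a single long run); averaging was chosen because a
single run's equilibrium can sit in an atypical stochastic excursion on
small graphs.

**Reproducibility.**  SIR ground truth derives one RNG stream per
`(rng_seed, node)` and vectorizes the instances inside it; SIS ground truth
derives one stream per `(rng_seed, run)`.  Identical seeds give identical
ground truths.

## Centrality and rankings

Degree, k-core (iterative minimum-degree peeling) and exact unnormalized
betweenness (unordered-pair convention).  Betweenness is exact rather than
sampled so that measure noise cannot contaminate sample-vs-graph
comparisons.  Rankings are descending by score with ties broken by a seeded
random shuffle, recorded on the ranking; tie handling is surfaced because
k-core ties are massive and materially affect top-k overlap.  On a sample,
centrality is computed on the crossed-edge subgraph only, and only
discovered nodes are eligible for the sample's top-k.

## Evaluation

`k = max(1, round(fraction·|N|))` with `|N|` always the original graph's
node count.  For a candidate ranking `r_C`:

- `ε(top-k) = 1 − M̄_C/M̄_eff` (SIR), `δρ(top-k) = 1 − ρ̄_C/ρ̄_eff` (SIS);
  both in [0, 1] since the true top-k maximizes the k-mean (tiny negative
  rounding residues are clamped to 0).
- `OSim = |A ∩ B|/k` over the two top-k sets.
- Kendall tau between the candidate's top-k order and those same k nodes
  ordered by ground-truth value, wherever they sit in the full ground-truth
  ranking.  Tie-adjusted tau-b by default (scores tie heavily); plain tau-a
  selectable; the tie fraction among the compared values is reported
  alongside.

`run_experiment` drives ground truth → `n_samples` samples → rankings →
statistics, and aggregates mean ± sd over samples.  A sample that discovered
fewer than k nodes yields a missing cell for that top-k, excluded from the
mean and counted in the report.

## Synthetic fixtures

Generated graphs carry their closed-form expectations (moments, thresholds,
core numbers, component sizes), asserted at generation.  The default
end-to-end fixture is a Barabási–Albert graph (n = 500, m = 3): heavy-tailed
degrees are what give spreader identification its signal.  What BA fixtures
do **not** emulate: community structure, degree correlations and — most
consequentially — a deep k-core hierarchy.  In a BA graph every node's core
number is exactly m (nodes attach with degree m), so the k-core ranking is a
single tie group and carries no information on these fixtures; conclusions
about k-core accuracy therefore do not transfer from BA fixtures to real
networks, and the test suite's k-core-based overlap check documents this
honestly rather than papering over it.  Sizes used in the shipped runs — 20
samples, 100 SIR instances, 10 SIS calibration runs — were chosen as the
smallest giving stable means on a 500-node graph.

## Known limitations

- Synchronous discrete-time dynamics only; no Gillespie/continuous-time
  variant, no heterogeneous per-edge rates.
- Betweenness is exact and thus O(|N||E|); intended for fixture-scale
  graphs, not millions of nodes.
- The MH sampler's objective follows this package's L1 formulation, not any
  particular historical implementation.
- The SIS equilibrium tolerance and measurement window are conventions; both
  are exposed in `EquilibriumPolicy`/`SISConfig`.
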