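"""Graph samplers: maxRD rank-degree exploration, Forest Fire, MHRW and MH.

The central algorithm is :func:`max_rank_degree_sample` (maxRD), a graph
exploration method that discovers influential nodes using only local degree
information.  It runs ``s`` parallel traverses; each traverse repeatedly moves
from its current node to that node's maximum-*residual*-degree neighbour,
where residual degree is the degree in a working copy of the graph from which
every crossed edge has been deleted.  Visited nodes stay in the working copy —
only edges are removed — so a node can be revisited along a different path but
no edge is ever crossed twice.  When every current seed has run out of
incident edges the sampler performs a random jump (a fresh uniform re-seed) so
it cannot get trapped.  The output is the set of crossed edges plus the set of
discovered nodes.

The three reference samplers it is compared against:

* Forest Fire — stochastic burning: from each frontier node, burn a
  geometrically distributed number of edges to unburned neighbours
  (mean p_f/(1−p_f), support {0, 1, 2, …}); restart from a fresh node if the
  fire dies before the target size is reached.
* Metropolis–Hastings Random Walk — parallel random walks whose move x→y is
  accepted with probability min(1, deg(x)/deg(y)), making the stationary
  distribution uniform over nodes of a connected graph.
* Metropolis–Hastings — a centralized sampler that swaps nodes in and out of
  a fixed-size sample so that the induced subgraph's normalized degree
  histogram approaches the original graph's (L1 objective).

All samplers draw every random decision from one seeded generator recorded in
the sample's provenance, so a run is exactly reproducible from its config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SamplerConfig",
    "Sample",
    "SamplingError",
    "max_rank_degree_sample",
    "forest_fire_sample",
    "mhrw_sample",
    "metropolis_hastings_sample",
    "sample_subgraph",
    "SAMPLERS",
]


class SamplingError(RuntimeError):
    """A sampler could not reach its target size within its retry budget."""


def _edge(u, v) -> tuple:
    """Canonical ordered form of an undirected edge."""
    return (u, v) if repr(u) <= repr(v) else (v, u)


@dataclass(frozen=True)
class SamplerConfig:
    """Shared sampler configuration.

    Parameters
    ----------
    target_node_fraction:
        Fraction x of the graph's nodes a sample must discover (0.20 in the
        reference protocol).
    seed_fraction, seed_count:
        Number of initial traverses s, given either as a fraction of |N|
        (1% for maxRD and MHRW) or as an absolute count (1 for Forest Fire).
        Exactly one of the two may be set; the default is ``seed_fraction=0.01``.
    rng_seed:
        Seed of the single generator all random decisions are drawn from.
    forward_burning_prob:
        Forest Fire p_f (default 0.7).
    n_iterations:
        Metropolis–Hastings swap iterations (20 000 / 30 000 in the reference
        protocol depending on graph size).
    jump_budget:
        Maximum consecutive unproductive random jumps / restarts / stalled
        walk rounds before the sampler gives up with :class:`SamplingError`.
    maxrd_jump_trigger:
        ``"exhausted"`` (default): jump when no current seed has an incident
        edge left in the working copy.  ``"degree_one"``: additionally jump as
        soon as every current seed has residual degree ≤ 1 (a stricter,
        literal reading of the jump condition; both are exposed because the
        published description is ambiguous).
    track_quality:
        MH only — record the L1 objective after every iteration in provenance.
    """

    target_node_fraction: float = 0.20
    seed_fraction: float | None = 0.01
    seed_count: int | None = None
    rng_seed: int = 0
    forward_burning_prob: float = 0.7
    n_iterations: int = 20_000
    jump_budget: int = 1_000
    maxrd_jump_trigger: str = "exhausted"
    track_quality: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.target_node_fraction <= 1.0:
            raise ValueError("target_node_fraction must be in (0, 1]")
        if (self.seed_fraction is None) == (self.seed_count is None):
            raise ValueError("exactly one of seed_fraction / seed_count must be set")
        if self.seed_fraction is not None and not 0.0 < self.seed_fraction <= 1.0:
            raise ValueError("seed_fraction must be in (0, 1]")
        if self.seed_count is not None and self.seed_count < 1:
            raise ValueError("seed_count must be positive")
        if not 0.0 < self.forward_burning_prob < 1.0:
            raise ValueError("forward_burning_prob must be in (0, 1)")
        if self.maxrd_jump_trigger not in ("exhausted", "degree_one"):
            raise ValueError("maxrd_jump_trigger must be 'exhausted' or 'degree_one'")

    def n_seeds(self, n_nodes: int) -> int:
        if self.seed_count is not None:
            return min(self.seed_count, n_nodes)
        return min(max(1, round(self.seed_fraction * n_nodes)), n_nodes)

    def target_size(self, n_nodes: int) -> int:
        target = math.ceil(self.target_node_fraction * n_nodes)
        return max(1, target)


@dataclass(frozen=True)
class Sample:
    """Output of a sampler: crossed edges, discovered nodes and provenance.

    ``discovered_nodes`` is the union of the endpoints of ``crossed_edges``
    and every (initial or re-seeded) seed, so seeds that never crossed an edge
    appear as isolated nodes in :func:`sample_subgraph`.
    """

    crossed_edges: frozenset[tuple]
    discovered_nodes: frozenset
    provenance: dict = field(compare=False)

    @property
    def algorithm(self) -> str:
        return self.provenance["algorithm"]


def _sorted_nodes(graph: nx.Graph) -> list:
    # Stable node universe so rng draws are reproducible across runs.
    return sorted(graph.nodes, key=repr)


def _draw_nodes(universe: Sequence, count: int, rng: np.random.Generator) -> list:
    idx = rng.choice(len(universe), size=min(count, len(universe)), replace=False)
    return [universe[i] for i in np.atleast_1d(idx)]


def _make_sample(algorithm: str, config: SamplerConfig, crossed, discovered,
                 n_jumps: int, **extra) -> Sample:
    provenance = {
        "algorithm": algorithm,
        "config": config,
        "rng_seed": config.rng_seed,
        "n_jumps": n_jumps,
        **extra,
    }
    return Sample(
        crossed_edges=frozenset(crossed),
        discovered_nodes=frozenset(discovered),
        provenance=provenance,
    )


def max_rank_degree_sample(
    graph: nx.Graph,
    config: SamplerConfig,
    initial_seeds: Sequence | None = None,
) -> Sample:
    """maxRD: parallel max-residual-degree traverses with edge elimination.

    Each round, every current seed i selects the neighbour j with the largest
    residual degree (ties broken uniformly at random from the seeded
    generator), the edge {i, j} is removed from the working copy, and j joins
    the next round's seed set.  The halt check runs after each full round, so
    the round that crosses the target completes (slight overshoot allowed).
    When no current seed has an incident edge left, the sampler re-seeds with
    s fresh uniformly drawn nodes (a random jump).

    ``initial_seeds`` pins the starting nodes (for deterministic traces);
    otherwise s nodes are drawn uniformly without replacement.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot sample an empty graph")
    rng = np.random.default_rng(config.rng_seed)
    universe = _sorted_nodes(graph)
    n = len(universe)
    target = config.target_size(n)
    work = graph.copy()

    if initial_seeds is not None:
        seeds = list(initial_seeds)
    else:
        seeds = _draw_nodes(universe, config.n_seeds(n), rng)
    discovered: set = set(seeds)
    crossed: list[tuple] = []
    crossed_set: set[tuple] = set()
    current = list(dict.fromkeys(seeds))
    n_jumps = 0
    stalled_jumps = 0

    while len(discovered) < target:
        if config.maxrd_jump_trigger == "degree_one" and current and all(
            work.degree(i) <= 1 for i in current
        ):
            next_seeds: list = []
        else:
            next_seeds = []
            for i in current:
                neighbours = list(work.adj[i])
                if not neighbours:
                    continue
                best = max(work.degree(v) for v in neighbours)
                candidates = sorted(
                    (v for v in neighbours if work.degree(v) == best), key=repr
                )
                j = candidates[rng.integers(len(candidates))] if len(candidates) > 1 \
                    else candidates[0]
                work.remove_edge(i, j)
                e = _edge(i, j)
                # An edge leaves the working copy the moment it is crossed,
                # so it can never be selected again.
                crossed_set.add(e)
                crossed.append(e)
                discovered.add(j)
                next_seeds.append(j)
        if next_seeds:
            current = list(dict.fromkeys(next_seeds))
            stalled_jumps = 0
        else:
            n_jumps += 1
            before = len(discovered)
            current = _draw_nodes(universe, config.n_seeds(n), rng)
            discovered.update(current)
            stalled_jumps = 0 if len(discovered) > before else stalled_jumps + 1
            if stalled_jumps > config.jump_budget:
                raise SamplingError(
                    f"maxRD could not reach target {target} "
                    f"(discovered {len(discovered)}) within the jump budget"
                )
    assert len(crossed_set) == len(crossed), "an edge was crossed twice"
    return _make_sample("maxrd", config, crossed_set, discovered, n_jumps,
                        crossed_sequence=tuple(crossed))


def _burn_count(rng: np.random.Generator, p_f: float) -> int:
    """Forest Fire burn count x ~ Geometric(mean p_f/(1−p_f)), support {0,1,…}."""
    return int(rng.geometric(1.0 - p_f)) - 1


def forest_fire_sample(graph: nx.Graph, config: SamplerConfig) -> Sample:
    """Forest Fire: geometric burning from a single seed, restart on die-out.

    From each frontier node w, draw x ~ Geometric with mean p_f/(1−p_f)
    (support {0, 1, 2, …}) and burn x uniformly chosen edges to unburned
    neighbours (all of them if fewer than x remain).  Burned nodes are never
    revisited.  If the fire dies before the target size, restart from a fresh
    uniformly drawn unburned node.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot sample an empty graph")
    rng = np.random.default_rng(config.rng_seed)
    p_f = config.forward_burning_prob
    universe = _sorted_nodes(graph)
    n = len(universe)
    target = config.target_size(n)

    burned: set = set()
    crossed: set[tuple] = set()
    frontier: list = []
    n_restarts = 0

    def restart() -> None:
        nonlocal frontier
        unburned = [v for v in universe if v not in burned]
        start = unburned[rng.integers(len(unburned))]
        burned.add(start)
        frontier = [start]

    restart()
    while len(burned) < target:
        if not frontier:
            n_restarts += 1
            if n_restarts > config.jump_budget:
                raise SamplingError(
                    f"forest fire could not reach target {target} within "
                    "the restart budget"
                )
            restart()
            continue
        next_frontier: list = []
        for w in frontier:
            x = _burn_count(rng, p_f)
            if x == 0:
                continue
            unburned_nbrs = sorted(
                (v for v in graph.adj[w] if v not in burned), key=repr
            )
            if not unburned_nbrs:
                continue
            take = min(x, len(unburned_nbrs))
            chosen_idx = rng.choice(len(unburned_nbrs), size=take, replace=False)
            for i in np.atleast_1d(chosen_idx):
                v = unburned_nbrs[i]
                crossed.add(_edge(w, v))
                burned.add(v)
                next_frontier.append(v)
        frontier = next_frontier
    return _make_sample("ff", config, crossed, burned, n_restarts)


def _metropolis_walk_step(graph: nx.Graph, x, rng: np.random.Generator):
    """One MHRW step from x; returns (next node, crossed edge or None)."""
    neighbours = sorted(graph.adj[x], key=repr)
    if not neighbours:
        return x, None
    y = neighbours[rng.integers(len(neighbours))]
    if rng.random() <= graph.degree(x) / graph.degree(y):
        return y, _edge(x, y)
    return x, None


def mhrw_sample(graph: nx.Graph, config: SamplerConfig) -> Sample:
    """Metropolis–Hastings Random Walk: s parallel degree-corrected walks.

    A proposed move x→y (y uniform among x's neighbours) is accepted with
    probability min(1, deg(x)/deg(y)), with degrees taken in the original
    graph; no edges are removed.  Rejected proposals cross no edge.  Distinct
    visited nodes count toward the target, so a walk trapped in a small
    component simply stops contributing while the others continue.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot sample an empty graph")
    rng = np.random.default_rng(config.rng_seed)
    universe = _sorted_nodes(graph)
    n = len(universe)
    target = config.target_size(n)

    positions = _draw_nodes(universe, config.n_seeds(n), rng)
    visited: set = set(positions)
    crossed: set[tuple] = set()
    stalled_rounds = 0
    # A stalled round = a full sweep over all walks with no new node; the
    # budget is generous because rejection plateaus are normal for MHRW.
    stall_budget = config.jump_budget * 100
    while len(visited) < target:
        before = len(visited)
        for k, x in enumerate(positions):
            y, edge = _metropolis_walk_step(graph, x, rng)
            positions[k] = y
            if edge is not None:
                crossed.add(edge)
                visited.add(y)
        stalled_rounds = 0 if len(visited) > before else stalled_rounds + 1
        if stalled_rounds > stall_budget:
            raise SamplingError(
                f"MHRW walks stalled at {len(visited)}/{target} discovered nodes"
            )
    return _make_sample("mhrw", config, crossed, visited, 0)


def metropolis_hastings_sample(graph: nx.Graph, config: SamplerConfig) -> Sample:
    """Metropolis–Hastings degree-distribution sampler (centralized).

    Holds a sample of n = ⌈x·|N|⌉ nodes and repeatedly proposes swapping one
    in-sample node for one out-of-sample node.  The quality of a sample is the
    L1 distance between the normalized degree histogram of its induced
    subgraph and that of the original graph; a swap is accepted if it lowers
    the distance, and otherwise with probability Δ_old/Δ_new.  Returns the
    final induced subgraph's edges as the crossed edges.
    """
    rng = np.random.default_rng(config.rng_seed)
    universe = _sorted_nodes(graph)
    n = len(universe)
    n_sample = config.target_size(n)
    if n < n_sample:
        raise ValueError("sample size exceeds the number of nodes")

    max_deg = max((d for _, d in graph.degree()), default=0)
    orig_hist = np.zeros(max_deg + 1)
    for _, d in graph.degree():
        orig_hist[d] += 1
    orig_hist /= n

    in_sample = set(_draw_nodes(universe, n_sample, rng))
    out_sample = [v for v in universe if v not in in_sample]
    # Induced degree of every in-sample node, plus its histogram.
    in_deg = {v: sum(1 for w in graph.adj[v] if w in in_sample) for v in in_sample}
    hist = np.zeros(max_deg + 1)
    for d in in_deg.values():
        hist[d] += 1

    def l1() -> float:
        return float(np.abs(hist / n_sample - orig_hist).sum())

    def swap(u, v) -> None:
        """Replace in-sample node u by out-of-sample node v, updating hist."""
        hist[in_deg.pop(u)] -= 1
        in_sample.discard(u)
        for w in graph.adj[u]:
            if w in in_sample:
                hist[in_deg[w]] -= 1
                in_deg[w] -= 1
                hist[in_deg[w]] += 1
        in_sample.add(v)
        for w in graph.adj[v]:
            if w in in_sample and w != v:
                hist[in_deg[w]] -= 1
                in_deg[w] += 1
                hist[in_deg[w]] += 1
        in_deg[v] = sum(1 for w in graph.adj[v] if w in in_sample and w != v)
        hist[in_deg[v]] += 1

    delta_old = l1()
    trace = [delta_old] if config.track_quality else None
    n_accepted = 0
    in_list = sorted(in_sample, key=repr)
    for _ in range(config.n_iterations):
        if not out_sample:
            break
        u = in_list[rng.integers(len(in_list))]
        vi = int(rng.integers(len(out_sample)))
        v = out_sample[vi]
        swap(u, v)
        delta_new = l1()
        accept = delta_new < delta_old or (
            delta_new > 0 and rng.random() < delta_old / delta_new
        )
        if accept:
            delta_old = delta_new
            out_sample[vi] = u
            in_list = sorted(in_sample, key=repr)
            n_accepted += 1
        else:
            swap(v, u)  # undo
        if trace is not None:
            trace.append(delta_old)

    crossed = {
        _edge(u, v) for u in in_sample for v in graph.adj[u] if v in in_sample
    }
    extra = {"final_l1": delta_old, "n_accepted": n_accepted}
    if trace is not None:
        extra["quality_trace"] = tuple(trace)
    return _make_sample("mh", config, crossed, set(in_sample), 0, **extra)


def sample_subgraph(sample: Sample) -> nx.Graph:
    """Graph whose edges are the crossed edges and nodes the discovered nodes.

    Seeds that never crossed an edge appear as isolated nodes.  All
    sample-based centrality is computed on this subgraph structure.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sample.discovered_nodes)
    graph.add_edges_from(sample.crossed_edges)
    return graph


SAMPLERS: dict[str, Callable[[nx.Graph, SamplerConfig], Sample]] = {
    "maxrd": max_rank_degree_sample,
    "ff": forest_fire_sample,
    "mhrw": mhrw_sample,
    "mh": metropolis_hastings_sample,
}


def with_rng_seed(config: SamplerConfig, rng_seed: int) -> SamplerConfig:
    """Copy of ``config`` with a different rng_seed (helper for sample sweeps)."""
    return replace(config, rng_seed=rng_seed)
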