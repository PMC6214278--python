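"""Centrality measures and ranked-list construction for top-k analysis.

Three classical spreading-related measures: degree (local), k-core
decomposition (global placement — a node's core number is the largest k such
that it belongs to a maximal subgraph of minimum degree ≥ k) and exact
shortest-path betweenness (unnormalized, unordered-pair convention).

Rankings are descending by score.  Because degree and especially k-core tie
heavily, tie handling materially affects top-k overlap statistics; ties are
therefore broken by a seeded random shuffle within each tie group and the rule
is recorded on the ranking itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "RankedList",
    "degree_centrality",
    "k_core",
    "betweenness",
    "rank_nodes",
]


@dataclass(frozen=True)
class RankedList:
    """Nodes ordered best-first with their scores and the tie rule applied."""

    ordered_nodes: tuple
    scores: Mapping[object, float] = field(compare=False)
    tie_policy: str = "seeded_random_shuffle"

    def __len__(self) -> int:
        return len(self.ordered_nodes)

    def top(self, k: int) -> tuple:
        if k > len(self.ordered_nodes):
            raise ValueError(
                f"requested top-{k} from a ranking of {len(self.ordered_nodes)} nodes"
            )
        return self.ordered_nodes[:k]

    def top_set(self, k: int) -> frozenset:
        return frozenset(self.top(k))


def degree_centrality(graph: nx.Graph) -> dict:
    """Raw degree of every node."""
    return dict(graph.degree())


def k_core(graph: nx.Graph) -> dict:
    """Core number of every node (iterative minimum-degree peeling)."""
    return nx.core_number(graph)


def betweenness(graph: nx.Graph) -> dict:
    """Exact shortest-path betweenness, unnormalized.

    Uses the unordered-pair convention (each {s, t} pair counted once);
    disconnected pairs contribute nothing.  Exact rather than sampled, so the
    measure itself adds no noise to sample-vs-graph comparisons.
    """
    return nx.betweenness_centrality(graph, normalized=False)


def rank_nodes(scores: Mapping[object, float], rng_seed: int = 0) -> RankedList:
    """Rank nodes by descending score, shuffling within each tie group.

    The shuffle is drawn from a generator seeded with ``rng_seed`` so the
    ranking is reproducible; each tie group stays contiguous in the output.
    """
    rng = np.random.default_rng(rng_seed)
    by_value: dict[float, list] = {}
    for node, value in scores.items():
        by_value.setdefault(value, []).append(node)
    ordered: list = []
    for value in sorted(by_value, reverse=True):
        group = sorted(by_value[value], key=repr)
        if len(group) > 1:
            group = [group[i] for i in rng.permutation(len(group))]
        ordered.extend(group)
    return RankedList(
        ordered_nodes=tuple(ordered),
        scores=dict(scores),
        tie_policy="seeded_random_shuffle",
    )
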