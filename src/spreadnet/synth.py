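"""Synthetic graph fixtures with analytically known properties.

Every family comes with closed-form expectations (degree moments, epidemic
thresholds, core numbers, component sizes) that are *asserted against the
generated graph at generation time*, so any fixture a test receives is
self-verified.  The Barabási–Albert family is the default end-to-end fixture:
its heavy-tailed degree distribution is what gives the spreader-identification
problem its signal, mirroring the real social and collaboration networks this
kind of analysis targets.

Also provides toy ground-truth/candidate ranking pairs with controllable
overlap and tie structure for exercising the evaluation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .centrality import RankedList, rank_nodes
from .epidemic import GroundTruth
from .graph import degree_moments

__all__ = ["FixtureSpec", "make_fixture", "make_toy_ranking_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """A named graph family plus its size parameters and RNG seed.

    Families and parameters:

    - ``regular``: n, k (n·k even) — random k-regular graph
    - ``erdos_renyi``: n, p
    - ``barabasi_albert``: n, m
    - ``star``: n (total nodes: one center, n−1 leaves)
    - ``complete``: n
    - ``path``: n
    - ``union``: components = list of FixtureSpec — disjoint union with
      component-prefixed node labels
    """

    family: str
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )


def _expected_regular(n: int, k: int) -> dict:
    expected = {
        "mean_degree": float(k),
        "mean_squared_degree": float(k * k),
        "sis_threshold": 1.0 / k,
        "core_numbers": {v: k for v in range(n)},
    }
    if k >= 2:
        expected["sir_threshold"] = 1.0 / (k - 1)
    return expected


def _build(spec: FixtureSpec) -> tuple[nx.Graph, dict]:
    p = spec.params
    family = spec.family
    if family == "regular":
        n, k = p["n"], p["k"]
        if (n * k) % 2 or k >= n:
            raise ValueError("regular graph needs n*k even and k < n")
        graph = nx.random_regular_graph(k, n, seed=spec.rng_seed)
        return graph, _expected_regular(n, k)
    if family == "erdos_renyi":
        graph = nx.gnp_random_graph(p["n"], p["p"], seed=spec.rng_seed)
        return graph, {"n_nodes": p["n"]}
    if family == "barabasi_albert":
        n, m = p["n"], p["m"]
        graph = nx.barabasi_albert_graph(n, m, seed=spec.rng_seed)
        return graph, {"n_nodes": n, "n_edges": (n - m) * m}
    if family == "star":
        n = p["n"]
        if n < 2:
            raise ValueError("star needs at least 2 nodes")
        graph = nx.star_graph(n - 1)  # node 0 is the center
        leaves = n - 1
        return graph, {
            "mean_degree": 2 * leaves / n,
            "mean_squared_degree": (leaves + leaves**2) / n,
            "core_numbers": {v: 1 for v in graph.nodes},
        }
    if family == "complete":
        n = p["n"]
        graph = nx.complete_graph(n)
        expected = {
            "mean_degree": float(n - 1),
            "mean_squared_degree": float((n - 1) ** 2),
            "core_numbers": {v: n - 1 for v in graph.nodes},
            "sis_threshold": 1.0 / (n - 1),
        }
        if n >= 3:
            expected["sir_threshold"] = 1.0 / (n - 2)
        return graph, expected
    if family == "path":
        n = p["n"]
        graph = nx.path_graph(n)
        return graph, {
            "mean_degree": 2 * (n - 1) / n,
            "mean_squared_degree": (4 * (n - 2) + 2) / n if n >= 2 else 0.0,
            "core_numbers": {v: 1 if n >= 2 else 0 for v in graph.nodes},
        }
    if family == "union":
        parts = [make_fixture(sub) for sub in p["components"]]
        graph = nx.Graph()
        sizes = []
        for i, (part, _) in enumerate(parts):
            graph.update(nx.relabel_nodes(part, {v: f"c{i}_{v}" for v in part.nodes}))
            sizes.append(part.number_of_nodes())
        return graph, {"component_sizes": sorted(sizes)}
    raise AssertionError(family)


_FAMILIES = {
    "regular", "erdos_renyi", "barabasi_albert", "star", "complete", "path", "union",
}


def make_fixture(spec: FixtureSpec) -> tuple[nx.Graph, dict]:
    """Generate a fixture graph and verify its closed-form expectations."""
    graph, expected = _build(spec)
    if "mean_degree" in expected:
        moments = degree_moments(graph)
        assert abs(moments.mean_degree - expected["mean_degree"]) < 1e-9
        assert abs(moments.mean_squared_degree - expected["mean_squared_degree"]) < 1e-9
    if "core_numbers" in expected:
        assert nx.core_number(graph) == expected["core_numbers"]
    if "n_edges" in expected:
        assert graph.number_of_edges() == expected["n_edges"]
    if "n_nodes" in expected:
        assert graph.number_of_nodes() == expected["n_nodes"]
    if "component_sizes" in expected:
        assert sorted(len(c) for c in nx.connected_components(graph)) == expected[
            "component_sizes"
        ]
    assert nx.number_of_selfloops(graph) == 0
    return graph, expected


def make_toy_ranking_fixture(
    n: int,
    values: dict | None = None,
    k: int = 3,
    overlap: int | None = None,
    rng_seed: int = 0,
) -> tuple[GroundTruth, RankedList]:
    """Synthetic ground truth plus a candidate ranking at a chosen overlap.

    ``values`` defaults to the tie-free linear profile n, n−1, …, 1 on nodes
    ``v1 … vn``.  The candidate ranking keeps ``overlap`` of the true top-k
    nodes (defaults to all k, i.e. a perfect candidate) and fills the rest of
    its top-k with the best nodes outside the true top-k, so
    OSim(truth, candidate) = overlap/k exactly — asserted before returning.
    """
    if n < 2:
        raise ValueError("need at least two nodes")
    if values is None:
        values = {f"v{i}": float(n - i) for i in range(n)}
    if overlap is None:
        overlap = k
    if not 0 <= overlap <= k <= len(values):
        raise ValueError("need 0 <= overlap <= k <= n")
    truth_ranking = rank_nodes(values, rng_seed=rng_seed)
    ground_truth = GroundTruth(
        kind="sir_efficiency",
        values=dict(values),
        ranking=truth_ranking,
        provenance={"synthetic": True, "rng_seed": rng_seed},
    )
    top = list(truth_ranking.top(k))
    rest = [v for v in truth_ranking.ordered_nodes if v not in top]
    candidate_order = top[:overlap] + rest[: k - overlap]
    candidate_order += [v for v in truth_ranking.ordered_nodes if v not in candidate_order]
    candidate = RankedList(
        ordered_nodes=tuple(candidate_order),
        scores={v: float(len(candidate_order) - i) for i, v in enumerate(candidate_order)},
        tie_policy="constructed",
    )
    achieved = len(set(candidate_order[:k]) & set(top)) / k
    assert abs(achieved - overlap / k) < 1e-12
    return ground_truth, candidate
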