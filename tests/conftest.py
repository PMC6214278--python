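"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: k-core by
subset enumeration, betweenness by explicit shortest-path counting, SIR mean
outbreak size by exhaustive bond-percolation enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from spreadnet import FixtureSpec, make_fixture


def small_graph_zoo() -> dict[str, nx.Graph]:
    """Named small fixtures spanning the structures the samplers meet."""
    k4_pendant = nx.complete_graph(4)
    k4_pendant.add_edge(3, "leaf")
    zoo = {
        "triangle": nx.cycle_graph(3),
        "path5": nx.path_graph(5),
        "cycle6": nx.cycle_graph(6),
        "star5": nx.star_graph(4),
        "k5": nx.complete_graph(5),
        "k4_pendant": k4_pendant,
        "two_components": make_fixture(
            FixtureSpec(
                "union",
                {
                    "components": [
                        FixtureSpec("complete", {"n": 4}),
                        FixtureSpec("complete", {"n": 2}),
                    ]
                },
            )
        )[0],
        "er12": make_fixture(FixtureSpec("erdos_renyi", {"n": 12, "p": 0.35}, 3))[0],
        "ba30": make_fixture(FixtureSpec("barabasi_albert", {"n": 30, "m": 2}, 5))[0],
    }
    return zoo


@pytest.fixture(scope="session")
def graph_zoo() -> dict[str, nx.Graph]:
    return small_graph_zoo()


@pytest.fixture(scope="session")
def ba200() -> nx.Graph:
    return make_fixture(FixtureSpec("barabasi_albert", {"n": 200, "m": 3}, 11))[0]


@pytest.fixture(scope="session")
def maxrd_trace_graph() -> nx.Graph:
    """Six-node fixture on which maxRD is deterministic irrespective of RNG.

    Degrees: s 1, a 2, h 3, x1 2, x2 1, x3 1.  Starting from s, every round
    has a unique maximum-residual-degree neighbour, so no tie-break or jump
    ever fires before five nodes are discovered.
    """
    graph = nx.Graph()
    graph.add_edges_from(
        [("s", "a"), ("a", "h"), ("h", "x1"), ("h", "x2"), ("x1", "x3")]
    )
    return graph


def brute_force_core_numbers(graph: nx.Graph) -> dict:
    """core(v) = max over induced subgraphs containing v of the min degree."""
    nodes = list(graph.nodes)
    core = {v: 0 for v in nodes}
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            min_degree = min(d for _, d in sub.degree())
            for v in subset:
                core[v] = max(core[v], min_degree)
    return core


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by enumerating all shortest paths per pair."""
    result = {v: 0.0 for v in graph.nodes}
    for s, t in itertools.combinations(graph.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                result[v] += 1.0 / len(paths)
    return result


def bond_percolation_mean_outbreak(graph: nx.Graph, seed, beta: float) -> float:
    """Exact E[M_seed] for SIR with gamma=1 via bond-percolation enumeration.

    With gamma=1 each edge independently transmits with probability beta, so
    the outbreak is the seed's component in the percolated graph.  Sums over
    all 2^|E| edge subsets; only usable on tiny graphs.
    """
    edges = list(graph.edges())
    m = len(edges)
    expectation = 0.0
    for mask in range(2**m):
        kept = [edges[i] for i in range(m) if mask >> i & 1]
        n_kept = len(kept)
        probability = beta**n_kept * (1 - beta) ** (m - n_kept)
        percolated = nx.Graph()
        percolated.add_nodes_from(graph.nodes)
        percolated.add_edges_from(kept)
        expectation += probability * len(nx.node_connected_component(percolated, seed))
    return expectation
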