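"""Undirected simple-graph model, SNAP-dialect edge-list I/O and degree moments.

Graphs are plain :class:`networkx.Graph` objects throughout the package.  Node
identifiers are opaque: ids read from a file stay strings exactly as written,
ids supplied in memory are kept as given and never coerced.  Every reader and
constructor enforces the simple-graph contract — no self-loops, no parallel
edges, symmetric adjacency — so downstream code can rely on it.

The edge-list dialect is the one used by the SNAP network collection: one edge
per line as two whitespace-separated endpoint ids, with ``#``-prefixed comment
lines.  Directed inputs are symmetrized (each ordered pair contributes one
undirected edge) and self-loops are dropped, which is the standard
preprocessing for spreading-process studies on these datasets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import networkx as nx

__all__ = [
    "Graph",
    "DegreeMoments",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "symmetrize_and_clean",
    "degree_moments",
]

#: Alias for the in-memory graph container used across the package.
Graph = nx.Graph


class EdgeListParseError(ValueError):
    """A non-comment line of an edge-list file had fewer than two tokens."""

    def __init__(self, line_number: int, line: str):
        self.line_number = line_number
        super().__init__(
            f"edge-list line {line_number} has fewer than two tokens: {line!r}"
        )


@dataclass(frozen=True)
class DegreeMoments:
    """First and second moments ⟨k⟩ and ⟨k²⟩ of a graph's degree distribution.

    These two numbers fully determine the heterogeneous-mean-field epidemic
    thresholds (T^c for SIR, λ^c for SIS), which is the only reason they get a
    type of their own.  Jensen's inequality guarantees ⟨k²⟩ ≥ ⟨k⟩²; the SIR
    threshold additionally needs ⟨k²⟩ > ⟨k⟩, which callers must check.
    """

    mean_degree: float
    mean_squared_degree: float

    def __post_init__(self) -> None:
        if self.mean_degree < 0 or self.mean_squared_degree < 0:
            raise ValueError("degree moments must be non-negative")
        # Jensen: strict violations indicate an upstream bug, allow fp slack.
        if self.mean_squared_degree < self.mean_degree**2 - 1e-9:
            raise ValueError(
                "mean_squared_degree < mean_degree**2 violates Jensen's inequality"
            )


def symmetrize_and_clean(
    pairs: Iterable[tuple[object, object]],
    extra_nodes: Iterable[object] = (),
) -> nx.Graph:
    """Build an undirected simple graph from (possibly directed) node pairs.

    Every ordered pair ``(u, v)`` with ``u != v`` contributes the undirected
    edge ``{u, v}`` exactly once; pairs ``(u, u)`` are dropped.  ``extra_nodes``
    lets callers add isolated nodes, which an edge list alone cannot express.
    """
    graph = nx.Graph()
    graph.add_nodes_from(extra_nodes)
    for u, v in pairs:
        if u == v:
            graph.add_node(u)
        else:
            graph.add_edge(u, v)
    return graph


def _iter_lines(source: str | os.PathLike | IO[str]) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source  # type: ignore[misc]
    else:
        with open(source, "r", encoding="utf-8") as handle:
            yield from handle


def read_edge_list(
    source: str | os.PathLike | IO[str],
    node_list: Iterable[object] | None = None,
) -> nx.Graph:
    """Read a SNAP-dialect edge list into an undirected simple graph.

    Parameters
    ----------
    source:
        Path or open text stream.  Lines starting with ``#`` are comments;
        every other non-blank line must hold at least two whitespace-separated
        endpoint ids (extra tokens are ignored).
    node_list:
        Optional explicit node set, the only way isolated nodes can enter a
        graph; endpoints found in the edge list are added to it.

    Raises
    ------
    EdgeListParseError
        If a non-comment line holds fewer than two tokens.  Empty input yields
        an empty graph, not an error.
    """

    def pairs() -> Iterator[tuple[str, str]]:
        for line_number, line in enumerate(_iter_lines(source), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(line_number, line.rstrip("\n"))
            yield tokens[0], tokens[1]

    return symmetrize_and_clean(pairs(), extra_nodes=node_list or ())


def write_edge_list(graph: nx.Graph, sink: str | os.PathLike | IO[str]) -> None:
    """Write one line per undirected edge; round-trips through read_edge_list."""
    if hasattr(sink, "write"):
        for u, v in graph.edges():
            sink.write(f"{u} {v}\n")  # type: ignore[union-attr]
    else:
        with open(sink, "w", encoding="utf-8") as handle:
            write_edge_list(graph, handle)


def degree_moments(graph: nx.Graph) -> DegreeMoments:
    """Compute ⟨k⟩ and ⟨k²⟩ over all nodes (isolated nodes count with degree 0)."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("degree moments are undefined for an empty graph")
    degrees = [d for _, d in graph.degree()]
    return DegreeMoments(
        mean_degree=sum(degrees) / n,
        mean_squared_degree=sum(d * d for d in degrees) / n,
    )
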