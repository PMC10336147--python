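"""Graph layer: vertex weightings, edge partitions, and plain-text I/O.

Graphs are plain :class:`networkx.Graph` objects (simple, undirected, no
self-loops or parallel edges; atoms are vertices, bonds are edges). This
module adds the two vertex weightings used by irregularity indices and the
*edge partition*, the sufficient statistic for every edge-additive index:
edges grouped by the unordered pair of endpoint weights, with a frequency
per class.

Isolated vertices are tolerated here (their neighborhood weight is 0); index
forms that take logs, ratios or roots of weights reject zero weights
downstream in :mod:`nanoirr.indices`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "GraphValidationError",
    "VertexWeighting",
    "degree_weights",
    "neighborhood_weights",
    "EdgePartition",
    "edge_partition",
    "read_graph",
    "write_graph",
]


class GraphValidationError(ValueError):
    """A graph or graph file violates the simple-graph invariants."""


def _check_simple(g: nx.Graph, source: str = "graph") -> None:
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise GraphValidationError(f"{source}: self-loop at vertex {loops[0][0]!r}")


@dataclass(frozen=True)
class VertexWeighting:
    """A positive-integer weight per vertex.

    ``kind`` is ``"degree"`` (weight = vertex degree d_u) or
    ``"neighborhood"`` (weight = sum of the degrees of u's neighbors,
    delta_u). The neighborhood weights satisfy the first-Zagreb identity
    sum_v delta_v = sum_v d_v**2.
    """

    kind: str
    values: Mapping[object, int] = field(hash=False)

    def __getitem__(self, v):
        return self.values[v]

    def total(self) -> int:
        return sum(self.values.values())


def degree_weights(g: nx.Graph) -> VertexWeighting:
    """Degree weighting d_u; the totals satisfy the handshake identity 2|E|."""
    _check_simple(g)
    return VertexWeighting("degree", dict(g.degree()))


def neighborhood_weights(g: nx.Graph) -> VertexWeighting:
    """Neighborhood degree-sum weighting delta_u = sum of neighbors' degrees.

    Isolated vertices receive weight 0 (permitted here; rejected by
    ratio/log/root index forms when they would enter an edge term, which
    cannot happen for edge endpoints).
    """
    _check_simple(g)
    deg = g.degree()
    return VertexWeighting(
        "neighborhood", {v: sum(deg(u) for u in g[v]) for v in g}
    )


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of unordered endpoint-weight pairs with integer frequencies.

    Entries map ``(w_hi, w_lo)`` with ``w_hi >= w_lo`` to a non-negative
    frequency; frequencies sum to |E| of the source graph. Sufficient to
    evaluate any edge-additive index.
    """

    entries: Mapping[tuple[int, int], int] = field(hash=False)
    weighting: str = "neighborhood"

    def __post_init__(self):
        for (hi, lo), freq in self.entries.items():
            if hi < lo:
                raise ValueError(f"pair {(hi, lo)} not ordered hi >= lo")
            if lo < 0 or int(hi) != hi or int(lo) != lo:
                raise ValueError(f"weights must be non-negative integers: {(hi, lo)}")
            if freq < 0 or int(freq) != freq:
                raise ValueError(f"frequency must be a non-negative integer: {freq}")

    @classmethod
    def from_graph(cls, g: nx.Graph, w: VertexWeighting) -> "EdgePartition":
        return edge_partition(g, w)

    def total(self) -> int:
        """Total edge count represented by the partition."""
        return sum(self.entries.values())

    def sorted_entries(self) -> list[tuple[tuple[int, int], int]]:
        """Entries sorted by (w_hi, w_lo) descending — the canonical
        summation order used by every evaluator for reproducibility."""
        return sorted(self.entries.items(), key=lambda kv: kv[0], reverse=True)

    def scaled(self, k: int) -> "EdgePartition":
        """Partition with every frequency multiplied by ``k``."""
        return EdgePartition(
            {pair: k * f for pair, f in self.entries.items()}, self.weighting
        )

    def as_dict(self) -> dict[tuple[int, int], int]:
        return dict(self.entries)


def edge_partition(g: nx.Graph, w: VertexWeighting) -> EdgePartition:
    """Group edges of ``g`` by the unordered pair of endpoint weights.

    Parameters
    ----------
    g : networkx.Graph
        Simple graph.
    w : VertexWeighting
        Must cover every vertex of ``g``.
    """
    missing = [v for v in g if v not in w.values]
    if missing:
        raise ValueError(f"weighting does not cover vertex {missing[0]!r}")
    entries: dict[tuple[int, int], int] = {}
    for u, v in g.edges():
        a, b = w[u], w[v]
        pair = (a, b) if a >= b else (b, a)
        entries[pair] = entries.get(pair, 0) + 1
    return EdgePartition(entries, w.kind)


# ---------------------------------------------------------------------------
# I/O: whitespace-separated edge lists ('#' comments) and GraphML.
# ---------------------------------------------------------------------------

_FORMATS = ("edgelist", "graphml")


def _coerce_labels(g: nx.Graph) -> nx.Graph:
    # Edge-list convention: integer ids where they parse as such.
    if all(isinstance(v, str) and v.lstrip("-").isdigit() for v in g):
        return nx.relabel_nodes(g, {v: int(v) for v in g})
    return g


def read_graph(path, format: str = "edgelist") -> nx.Graph:
    """Read a simple undirected graph from an edge list or GraphML file.

    The edge-list dialect is one whitespace-separated vertex pair per line,
    ``#`` starting a comment, 0-based integer ids by convention (non-integer
    labels are kept as strings). Duplicate edges collapse with a warning;
    self-loops raise :class:`GraphValidationError` naming the line.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "graphml":
        g = nx.Graph(nx.read_graphml(path))
        _check_simple(g, source=str(path))
        return _coerce_labels(g)

    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphValidationError(
                    f"{path}:{lineno}: expected two vertex ids, got {raw.strip()!r}"
                )
            u, v = parts
            if u == v:
                raise GraphValidationError(f"{path}:{lineno}: self-loop at {u!r}")
            if g.has_edge(u, v):
                warnings.warn(
                    f"{path}:{lineno}: duplicate edge {u} {v} collapsed",
                    stacklevel=2,
                )
            g.add_edge(u, v)
    return _coerce_labels(g)


def write_graph(g: nx.Graph, path, format: str = "edgelist") -> None:
    """Write ``g`` so that ``read_graph`` round-trips it with identical
    labels and edge set."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    _check_simple(g)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
        return
    with open(path, "w") as fh:
        fh.write(f"# {g.number_of_nodes()} vertices, {g.number_of_edges()} edges\n")
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def graph_from_edges(edges: Iterable[tuple], vertices: Iterable = ()) -> nx.Graph:
    """Convenience constructor enforcing the simple-graph invariants."""
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for u, v in edges:
        if u == v:
            raise GraphValidationError(f"self-loop at {u!r}")
        g.add_edge(u, v)
    return g
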