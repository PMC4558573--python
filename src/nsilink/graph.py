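"""Undirected simple-graph container, edge-list I/O, and structural queries.

Every predictor in this package consumes a training network through the small
query surface defined here: neighbor sets Γ(x), common neighbors
Γ(x) ∩ Γ(y), the links running across two neighbor sets, walk counts
(A^2)_xy / (A^3)_xy, and the enumeration of candidate (non-adjacent) pairs
U − E.  The container enforces the simple-graph contract: no self-loops, no
multi-edges, adjacency symmetric by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable
Pair = tuple  # canonical unordered pair, see node_pair()


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class SelfLoopError(ValueError):
    """An edge joins a node to itself, which simple graphs forbid."""


def _sort_key(label: Node):
    # stable total order across mixed label types
    return (type(label).__name__, str(label))


def node_pair(x: Node, y: Node) -> Pair:
    """Canonicalize an unordered node pair so (x, y) ≡ (y, x).

    Raises ``SelfLoopError`` for x == y: candidate links, like edges, never
    join a node to itself.
    """
    if x == y:
        raise SelfLoopError(f"pair ({x!r}, {y!r}) is a self-loop")
    try:
        return (x, y) if x < y else (y, x)
    except TypeError:
        return tuple(sorted((x, y), key=_sort_key))


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph over hashable node labels.

    Thin immutable wrapper over :class:`networkx.Graph`; construction
    validates the simple-graph invariants once so every downstream query can
    trust them.
    """

    _nx: nx.Graph = field(repr=False)

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[tuple] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise SelfLoopError(f"self-loop ({u!r}, {v!r}) not allowed")
            g.add_edge(u, v)
        object.__setattr__(self, "_nx", g)

    @classmethod
    def _wrap(cls, g: nx.Graph) -> "Graph":
        for u, v in g.edges():
            if u == v:
                raise SelfLoopError(f"self-loop ({u!r}, {v!r}) not allowed")
        obj = cls.__new__(cls)
        object.__setattr__(obj, "_nx", g)
        return obj

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self._nx.nodes)

    @property
    def edges(self) -> set:
        return {node_pair(u, v) for u, v in self._nx.edges}

    def number_of_nodes(self) -> int:
        return self._nx.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._nx.number_of_edges()

    def has_node(self, x: Node) -> bool:
        return self._nx.has_node(x)

    def has_edge(self, x: Node, y: Node) -> bool:
        return self._nx.has_edge(x, y)

    def degree(self, x: Node) -> int:
        if not self._nx.has_node(x):
            raise KeyError(f"unknown node {x!r}")
        return self._nx.degree(x)

    def sorted_nodes(self) -> list:
        return sorted(self._nx.nodes, key=_sort_key)

    def to_networkx(self) -> nx.Graph:
        """A defensive copy as a plain networkx graph."""
        return self._nx.copy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_edge_list(source: TextIO | Iterable[str], comment_prefix: str = "#") -> Graph:
    """Read an undirected edge list: two whitespace-separated labels per line.

    Blank lines and lines starting with *comment_prefix* are skipped; extra
    columns (e.g. weights) are ignored with one logged warning; repeated
    edges are deduplicated.  Node labels are kept as opaque strings.
    """
    g = nx.Graph()
    warned_extra = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected two node labels, got {line!r}"
            )
        if len(tokens) > 2 and not warned_extra:
            logger.warning(
                "line %d: extra columns ignored (first seen: %r)", lineno, line
            )
            warned_extra = True
        u, v = tokens[0], tokens[1]
        if u == v:
            raise SelfLoopError(f"line {lineno}: self-loop {u!r}-{v!r} not allowed")
        g.add_edge(u, v)
    return Graph._wrap(g)


def write_edge_list(g: Graph, sink: TextIO) -> None:
    """Write one ``u\\tv`` line per canonical edge, sorted, bit-exact."""
    for u, v in sorted(g.edges, key=lambda e: (_sort_key(e[0]), _sort_key(e[1]))):
        sink.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Structural queries
# ---------------------------------------------------------------------------

def neighbors(g: Graph, x: Node) -> set:
    """Γ(x): the neighbor set of x; |Γ(x)| = k_x."""
    if not g.has_node(x):
        raise KeyError(f"unknown node {x!r}")
    return set(g._nx.adj[x])


def common_neighbors(g: Graph, pair: Pair) -> set:
    """Γ(x) ∩ Γ(y) for the candidate pair."""
    x, y = pair
    return neighbors(g, x) & neighbors(g, y)


def cross_links(g: Graph, pair: Pair) -> set:
    """Edges running across the two neighbor sets of the candidate pair.

    Returns { {u,v} ∈ E : u ∈ Γ(x)\\{y}, v ∈ Γ(y)\\{x} } as canonical pairs.
    Edges incident to x or y themselves are excluded — the feature measures
    connectivity *between* the neighborhoods, not the pair's own stars.  An
    edge joining two common neighbors qualifies (it lies across both sets)
    and is reported once.
    """
    x, y = pair
    gx = neighbors(g, x) - {y}
    gy = neighbors(g, y) - {x}
    out = set()
    for u in gx:
        for v in g._nx.adj[u]:
            if v in gy and v != u:
                out.add(node_pair(u, v))
    return out


def walk_counts(g: Graph, pair: Pair, length: int) -> int:
    """(A^length)_xy: the number of walks of the given length joining the pair.

    Only lengths 2 and 3 are supported.  For the non-adjacent pairs scored
    in link prediction these equal the counts of length-2 / length-3 simple
    paths.
    """
    x, y = pair
    gx = neighbors(g, x)
    gy = neighbors(g, y)
    if length == 2:
        return len(gx & gy)
    if length == 3:
        # (A^3)_xy = sum over u in Γ(x) of (A^2)_uy
        return sum(len(set(g._nx.adj[u]) & gy) for u in gx)
    raise ValueError(f"unsupported walk length {length}; only 2 and 3")


def candidate_pairs(g: Graph) -> Iterator[Pair]:
    """Every unordered pair of distinct nodes not joined by an edge (U − E)."""
    order = g.sorted_nodes()
    for i, x in enumerate(order):
        adj = g._nx.adj[x]
        for y in order[i + 1:]:
            if y not in adj:
                yield node_pair(x, y)
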