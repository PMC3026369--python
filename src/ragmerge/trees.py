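"""Unlabeled trees: validation, canonical forms, enumeration and Laplacian spectra.

A tree here is an unlabeled simple tree given as an order ``n`` and a set of
edges over the labels ``0..n-1``.  Only the isomorphism class is meaningful;
labels carry no external convention.  Orders start at 2, matching the smallest
motif in the RNA-As-Graphs (RAG) catalogs (a single stem joining two loops).

Canonical forms use the classic AHU (rooted level-sequence) encoding, rooted
at the tree's center; two trees receive equal keys exactly when they are
isomorphic.  Vertex orbits under the automorphism group are obtained by
grouping vertices on the AHU code of the tree rooted at each vertex: an
automorphism maps u to v iff the two rooted trees are isomorphic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import cached_property

import networkx as nx
import numpy as np

__all__ = [
    "Tree",
    "TreeError",
    "VertexType",
    "canonical_form",
    "are_isomorphic",
    "enumerate_trees",
    "lambda2",
    "laplacian_spectrum",
    "vertex_type",
    "orbits",
]

MAX_ORDER = 12  # soft tractability cap for exhaustive enumeration


class TreeError(ValueError):
    """Raised for malformed trees or invalid vertices."""


class VertexType(enum.Enum):
    """Role of a vertex in a tree.

    In the RNA reading: leaves are hairpins, degree-2 vertices are bulges or
    internal loops, and vertices of degree >= 3 are junctions.  A *support*
    vertex is any neighbor of a leaf (degree >= 2); an *internal* vertex is
    neither a leaf nor a support vertex.
    """

    LEAF = "leaf"
    SUPPORT = "support"
    INTERNAL = "internal"


@dataclass(frozen=True)
class Tree:
    """An unlabeled simple tree on vertices ``0..order-1``.

    Invariants (checked on construction): exactly ``order - 1`` edges, no
    loops, labels in range, connected.  Acyclicity follows from the edge
    count plus connectivity.
    """

    order: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n = self.order
        if n < 2:
            raise TreeError(f"tree order must be >= 2, got {n}")
        if len(self.edges) != n - 1:
            raise TreeError(f"a tree on {n} vertices needs {n - 1} edges, got {len(self.edges)}")
        for a, b in self.edges:
            if a == b:
                raise TreeError(f"loop at vertex {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise TreeError(f"edge ({a}, {b}) outside label range 0..{n - 1}")
        # connectivity via BFS; with n-1 edges this also excludes cycles
        adj = self.adjacency
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != n:
            raise TreeError("tree is not connected")

    @classmethod
    def from_edges(cls, edges, order: int | None = None) -> "Tree":
        es = frozenset(tuple(sorted(map(int, e))) for e in edges)
        if order is None:
            order = 1 + max((max(e) for e in es), default=0)
        return cls(order, es)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Tree":
        g = nx.convert_node_labels_to_integers(g)
        return cls.from_edges(g.edges(), order=g.number_of_nodes())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.order))
        g.add_edges_from(self.edges)
        return g

    @cached_property
    def adjacency(self) -> dict[int, tuple[int, ...]]:
        adj: dict[int, list[int]] = {v: [] for v in range(self.order)}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return {v: tuple(ws) for v, ws in adj.items()}

    def degree(self, v: int) -> int:
        self._check_vertex(v)
        return len(self.adjacency[v])

    def _check_vertex(self, v: int) -> None:
        if not (0 <= v < self.order):
            raise TreeError(f"vertex {v} not in tree of order {self.order}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        es = ";".join(f"{a}-{b}" for a, b in sorted(self.edges))
        return f"Tree(order={self.order}, edges={es})"


def path_tree(n: int) -> Tree:
    """The path on ``n`` vertices (the most linear motif of its order)."""
    return Tree.from_edges([(i, i + 1) for i in range(n - 1)], order=n)


def star_tree(n: int) -> Tree:
    """The star on ``n`` vertices (the most branched motif of its order)."""
    return Tree.from_edges([(0, i) for i in range(1, n)], order=n)


def _rooted_code(adj: dict[int, tuple[int, ...]], root: int, parent: int | None = None) -> str:
    children = sorted(
        _rooted_code(adj, w, root) for w in adj[root] if w != parent
    )
    return "(" + "".join(children) + ")"


def _centers(t: Tree) -> list[int]:
    """Center vertex/vertices by iterative leaf stripping (1 or 2 for a tree)."""
    if t.order <= 2:
        return list(range(t.order))
    deg = {v: len(ws) for v, ws in t.adjacency.items()}
    layer = [v for v, d in deg.items() if d == 1]
    remaining = t.order
    while remaining > 2:
        remaining -= len(layer)
        nxt = []
        for v in layer:
            deg[v] = 0
            for w in t.adjacency[v]:
                if deg[w] > 1:
                    deg[w] -= 1
                    if deg[w] == 1:
                        nxt.append(w)
        layer = nxt
    return sorted(layer)


def canonical_form(t: Tree) -> str:
    """A total-order-comparable key identifying ``t``'s isomorphism class.

    The AHU code of the tree rooted at its center; for bicentral trees the
    lexicographic minimum over the two centers.  Equal keys <=> isomorphic.
    """
    return min(_rooted_code(t.adjacency, c) for c in _centers(t))


def are_isomorphic(t1: Tree, t2: Tree) -> bool:
    if t1.order != t2.order:
        return False
    return canonical_form(t1) == canonical_form(t2)


def enumerate_trees(n: int) -> list[Tree]:
    """All non-isomorphic trees on ``n`` vertices, one representative each.

    Counts for n = 2..9 are 1, 1, 2, 3, 6, 11, 23, 47 (94 trees in total),
    the universe of small RNA tree motifs.
    """
    if n < 2:
        raise TreeError(f"tree enumeration requires n >= 2, got {n}")
    if n > MAX_ORDER:
        raise TreeError(f"tree enumeration capped at n <= {MAX_ORDER}, got {n}")
    return [Tree.from_networkx(g) for g in nx.nonisomorphic_trees(n)]


def laplacian_spectrum(t: Tree) -> np.ndarray:
    """Eigenvalues of the Laplacian L = D - A, ascending."""
    n = t.order
    lap = np.zeros((n, n))
    for a, b in t.edges:
        lap[a, b] = lap[b, a] = -1.0
        lap[a, a] += 1.0
        lap[b, b] += 1.0
    return np.linalg.eigvalsh(lap)


def lambda2(t: Tree) -> float:
    """Algebraic connectivity: the second-smallest Laplacian eigenvalue.

    Strictly positive for a connected graph.  Linear trees score low,
    highly branched trees score high; RAG ranks motifs of an order by it.
    """
    return float(laplacian_spectrum(t)[1])


def vertex_type(t: Tree, v: int) -> VertexType:
    t._check_vertex(v)
    if t.degree(v) == 1:
        return VertexType.LEAF
    if any(t.degree(w) == 1 for w in t.adjacency[v]):
        return VertexType.SUPPORT
    return VertexType.INTERNAL


def orbits(t: Tree) -> list[frozenset[int]]:
    """Automorphism orbits of the vertex set.

    Vertices u, v lie in one orbit iff the tree rooted at u is isomorphic,
    as a rooted tree, to the tree rooted at v.  Orbits are returned sorted
    by their smallest member.
    """
    by_code: dict[str, list[int]] = {}
    for v in range(t.order):
        by_code.setdefault(_rooted_code(t.adjacency, v), []).append(v)
    return sorted((frozenset(vs) for vs in by_code.values()), key=min)
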