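"""Independent brute-force oracles used by the unit and property tests.

These deliberately avoid the package's canonical-form machinery: isomorphism
and automorphisms are decided by exhaustive permutation search (feasible for
n <= 7), and AUC by direct pairwise comparison.  They exist so the fast
implementations can be checked against something that is obviously correct.
"""

from __future__ import annotations

import itertools

from ragmerge import Tree


def brute_isomorphic(t1: Tree, t2: Tree) -> bool:
    """Exhaustive permutation search for an edge-preserving bijection."""
    if t1.order != t2.order:
        return False
    e2 = t2.edges
    for perm in itertools.permutations(range(t1.order)):
        if all(tuple(sorted((perm[a], perm[b]))) in e2 for a, b in t1.edges) :
            return True
    return False


def brute_automorphisms(t: Tree):
    edges = t.edges
    for perm in itertools.permutations(range(t.order)):
        if all(tuple(sorted((perm[a], perm[b]))) in edges for a, b in edges):
            yield perm


def brute_orbits(t: Tree) -> set[frozenset[int]]:
    """Vertex orbits via union over all automorphisms."""
    parent = list(range(t.order))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in brute_automorphisms(t):
        for v, w in enumerate(perm):
            ra, rb = find(v), find(w)
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for v in range(t.order):
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


def brute_auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def prufer_tree(seq: list[int], n: int) -> Tree:
    """Tree on n vertices from a Prüfer sequence (length n - 2)."""
    assert len(seq) == n - 2 and all(0 <= x < n for x in seq)
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    import heapq

    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((u, v))
    return Tree.from_edges(edges, order=n)


def relabel(t: Tree, perm) -> Tree:
    return Tree.from_edges(
        [(perm[a], perm[b]) for a, b in t.edges], order=t.order
    )
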