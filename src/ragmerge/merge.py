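"""Vertex-identification merges between tree motifs and their data vectors.

The merge of trees T1 (n vertices) and T2 (m vertices) at u in V(T1), v in
V(T2) identifies u and v into one vertex whose neighborhood is the union of
the two originals, giving a tree on n + m - 1 vertices.  There are n*m
labeled identifications; identifications related by automorphisms of the
inputs give isomorphic results, so the n*m outcomes are grouped into classes
indexed by pairs of automorphism orbits, each class carrying a frequency
|orbit(u)| * |orbit(v)|.  This mirrors the merge tables of the source data:
one row per orbit-pair class with the degrees and types of the identified
vertices, the RAG index and color of the result, and the class frequency.

Each row is also expressible as a 4-feature data vector
<c1, c2, deg(v1), deg(v2)> — the binary RNA-likeness of the two inputs
(1 = red or blue, 0 = black) and the degrees of the identified vertices —
with a 2-component target <y1, y2> = <1, 0> when the *result* tree is
RNA-like and <0, 1> when it is black.  These weighted vectors are the
perceptron's training and prediction inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .catalog import Catalog, CatalogEntry
from .trees import Tree, TreeError, orbits, vertex_type

__all__ = [
    "MergeRow",
    "MergeDataVector",
    "merge_at",
    "enumerate_merges",
    "all_merges_upto",
    "data_vectors_for",
    "vectors_by_result",
    "training_vectors",
    "write_merge_table",
]


@dataclass(frozen=True)
class MergeRow:
    """One orbit-pair class of vertex identifications between two motifs."""

    t1_index: str
    t2_index: str
    deg_v1: int
    deg_v2: int
    type_v1: str
    type_v2: str
    result_index: str
    result_color: str
    frequency: int


@dataclass(frozen=True)
class MergeDataVector:
    """Perceptron input for one identification class, with multiplicity.

    ``target`` is None when the result tree is unclassified (prediction-time
    vectors); such vectors never enter training.
    """

    c1: int
    c2: int
    deg_v1: int
    deg_v2: int
    target: tuple[int, int] | None
    weight: int
    t1_index: str = ""
    t2_index: str = ""
    result_index: str = ""

    @property
    def features(self) -> tuple[int, int, int, int]:
        return (self.c1, self.c2, self.deg_v1, self.deg_v2)


def merge_at(t1: Tree, u: int, t2: Tree, v: int) -> Tree:
    """Identify vertex ``u`` of ``t1`` with vertex ``v`` of ``t2``.

    The identified vertex keeps label ``u``; the remaining vertices of
    ``t2`` are relabeled onto ``t1.order ..``.  The result is a tree on
    ``t1.order + t2.order - 1`` vertices.
    """
    t1._check_vertex(u)
    t2._check_vertex(v)
    n1 = t1.order
    relabel = {}
    nxt = n1
    for x in range(t2.order):
        if x == v:
            relabel[x] = u
        else:
            relabel[x] = nxt
            nxt += 1
    edges = set(t1.edges)
    edges.update(tuple(sorted((relabel[a], relabel[b]))) for a, b in t2.edges)
    return Tree(n1 + t2.order - 1, frozenset(edges))


def _oriented(e1: CatalogEntry, e2: CatalogEntry) -> tuple[CatalogEntry, CatalogEntry]:
    # reproducible vector orientation: smaller order first, ties by rank z
    if (e1.order, e1.z) <= (e2.order, e2.z):
        return e1, e2
    return e2, e1


def enumerate_merges(
    e1: CatalogEntry, e2: CatalogEntry, catalog: Catalog
) -> list[MergeRow]:
    """All identification classes between two catalog motifs.

    One row per pair of automorphism orbits (unordered pairs when the two
    inputs are the same motif); frequencies sum to n * m.  Result trees are
    resolved against ``catalog`` for their index and color.
    """
    e1, e2 = _oriented(e1, e2)
    t1, t2 = e1.tree, e2.tree
    orbs1, orbs2 = orbits(t1), orbits(t2)
    self_merge = e1.index == e2.index
    rows = []
    for i, o1 in enumerate(orbs1):
        u = min(o1)
        for j, o2 in enumerate(orbs2):
            if self_merge and j < i:
                continue  # unordered orbit pair {a, b}
            v = min(o2)
            if self_merge and j > i:
                freq = 2 * len(o1) * len(o2)
            else:
                freq = len(o1) * len(o2)
            result = catalog.entry_for(merge_at(t1, u, t2, v))
            rows.append(
                MergeRow(
                    t1_index=e1.index,
                    t2_index=e2.index,
                    deg_v1=t1.degree(u),
                    deg_v2=t2.degree(v),
                    type_v1=vertex_type(t1, u).value,
                    type_v2=vertex_type(t2, v).value,
                    result_index=result.index,
                    result_color=result.color,
                    frequency=freq,
                )
            )
    return rows


def all_merges_upto(max_order: int, catalog: Catalog) -> list[MergeRow]:
    """Every identification class over all motif pairs with results of order
    ``<= max_order`` (self-pairs included)."""
    if max_order < 3:
        raise TreeError(f"merges need max_order >= 3, got {max_order}")
    needed = set(range(2, max_order))
    missing = needed - set(catalog.orders)
    if missing:
        raise TreeError(
            f"catalog incomplete for merges up to order {max_order}: "
            f"missing orders {sorted(missing)}"
        )
    if max_order not in catalog.orders:
        raise TreeError(
            f"catalog incomplete: result order {max_order} not covered"
        )
    rows: list[MergeRow] = []
    entries = [e for e in catalog if e.order <= max_order - 1]
    for a, e1 in enumerate(entries):
        for e2 in entries[a:]:
            if e1.order + e2.order - 1 <= max_order:
                rows.extend(enumerate_merges(e1, e2, catalog))
    return rows


def _c_feature(entry: CatalogEntry) -> int:
    if entry.rna_like is None:
        raise TreeError(
            f"input tree {entry.index} has no decided color class; "
            "c-features require a decided catalog"
        )
    return 1 if entry.rna_like else 0


def _row_vector(row: MergeRow, catalog: Catalog) -> MergeDataVector:
    c1 = _c_feature(catalog.by_index(row.t1_index))
    c2 = _c_feature(catalog.by_index(row.t2_index))
    result = catalog.by_index(row.result_index)
    if result.rna_like is None:
        target = None
    else:
        target = (1, 0) if result.rna_like else (0, 1)
    return MergeDataVector(
        c1=c1,
        c2=c2,
        deg_v1=row.deg_v1,
        deg_v2=row.deg_v2,
        target=target,
        weight=row.frequency,
        t1_index=row.t1_index,
        t2_index=row.t2_index,
        result_index=row.result_index,
    )


def data_vectors_for(
    result: CatalogEntry, rows: list[MergeRow], catalog: Catalog
) -> list[MergeDataVector]:
    """Data vectors of all identification classes producing ``result``."""
    return [
        _row_vector(r, catalog) for r in rows if r.result_index == result.index
    ]


def vectors_by_result(
    rows: list[MergeRow], catalog: Catalog
) -> dict[str, list[MergeDataVector]]:
    out: dict[str, list[MergeDataVector]] = {}
    for r in rows:
        out.setdefault(r.result_index, []).append(_row_vector(r, catalog))
    return out


def training_vectors(
    catalog: Catalog,
    rows: list[MergeRow],
    orders: tuple[int, ...] = (7, 8, 9),
) -> list[MergeDataVector]:
    """Targeted vectors for the classified (red/black) result trees.

    With the bundled catalog and orders 7-9 this is the training corpus of
    the study: the 15 known (red) trees of orders 7-9 plus the 11
    non-candidate (black) trees of orders 7-8.  Blue candidates are not
    training results.
    """
    vecs: list[MergeDataVector] = []
    for entry in catalog.classified(orders=orders):
        vecs.extend(data_vectors_for(entry, rows, catalog))
    return vecs


_TABLE_HEADER = [
    "pair",
    "deg_v1",
    "type_v1",
    "deg_v2",
    "type_v2",
    "result_index",
    "result_color",
    "frequency",
]


def write_merge_table(rows: list[MergeRow], path, fmt: str = "tsv") -> None:
    """Render rows as the merge-table artifact (TSV or JSON)."""
    path = Path(path)
    if fmt == "json":
        payload = [
            {
                "pair": f"{r.t1_index}+{r.t2_index}",
                **{k: getattr(r, k) for k in _TABLE_HEADER[1:]},
            }
            for r in rows
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = ["\t".join(_TABLE_HEADER)]
    for r in rows:
        lines.append(
            f"{r.t1_index}+{r.t2_index}\t{r.deg_v1}\t{r.type_v1}\t{r.deg_v2}"
            f"\t{r.type_v2}\t{r.result_index}\t{r.result_color}\t{r.frequency}"
        )
    path.write_text("\n".join(lines) + "\n")
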