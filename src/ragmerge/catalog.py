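"""RAG-style catalog: (n.z) indices by algebraic-connectivity rank + color classes.

Each tree motif of order n receives an index n.z where z is its rank within
the order under ascending lambda2 (algebraic connectivity): z = 1 is the path
(most linear), z = k the star (most branched).  Exact lambda2 ties between
non-isomorphic trees do occur (e.g. two order-8 trees share lambda2 = 2 - phi);
ranks are then decided by comparing the full Laplacian spectrum
lexicographically, which is unambiguous for every tree of order <= 9, with
the canonical-form key as a final fallback.  An explicit z-override hook is
provided for pinning indices should a different external numbering be needed.

Color classes follow the RAG convention: red = known RNA motif, blue =
candidate motif, black = non-candidate; red and blue together are "RNA-like".
Orders 2-8 are fully classified; order 9 has four red entries and 43 unknown.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .trees import (
    Tree,
    TreeError,
    canonical_form,
    enumerate_trees,
    lambda2,
    laplacian_spectrum,
)

__all__ = [
    "CatalogEntry",
    "Catalog",
    "rag_rank",
    "build_catalog",
    "load_default_catalog",
    "read_catalog",
    "write_catalog",
    "COLORS",
    "RNA_LIKE_COLORS",
]

COLORS = ("red", "blue", "black", "unknown")
RNA_LIKE_COLORS = ("red", "blue")

# Colors printed in the source tables: the order-6 anchors, the 15 red trees
# of orders 7-9 and the 11 black trees of orders 7-8.
_PAPER_COLORS: dict[str, str] = {
    "6.2": "red", "6.4": "blue", "6.5": "black", "6.6": "red",
    "7.1": "red", "7.2": "red", "7.3": "red", "7.6": "red",
    "7.9": "black", "7.10": "black", "7.11": "black",
    "8.3": "red", "8.5": "red", "8.7": "red", "8.10": "red",
    "8.11": "red", "8.15": "red", "8.20": "red",
    "8.9": "black", "8.14": "black", "8.17": "black", "8.18": "black",
    "8.19": "black", "8.21": "black", "8.22": "black", "8.23": "black",
    "9.6": "red", "9.11": "red", "9.13": "red", "9.27": "red",
}


def _default_color(order: int) -> str:
    # Orders 2-8 are fully classified in RAG.  Every red (order 7-9) and
    # black (order 7-8) motif is listed explicitly, so unlisted trees of
    # orders 7-8 are the blue candidates.  Small motifs (orders 2-6) without
    # an explicit entry default to red: short paths and caterpillars are
    # ubiquitous known RNA shapes.  Order-9 trees without an entry are the
    # 43 unclassified motifs the classifier is for.
    if order <= 6:
        return "red"
    if order <= 8:
        return "blue"
    return "unknown"


@dataclass(frozen=True)
class CatalogEntry:
    """A tree with its RAG index, algebraic connectivity and color class."""

    tree: Tree
    order: int
    z: int
    lambda2: float
    color: str = "unknown"
    source: str = "default"  # "paper" if the color is printed in the source tables

    @property
    def index(self) -> str:
        return f"{self.order}.{self.z}"

    @property
    def rag_index(self) -> tuple[int, int]:
        return (self.order, self.z)

    @property
    def rna_like(self) -> bool | None:
        """True for red/blue, False for black, None when unclassified."""
        if self.color in RNA_LIKE_COLORS:
            return True
        if self.color == "black":
            return False
        return None


def rag_rank(
    trees: list[Tree],
    colors: dict[str, str] | None = None,
    z_overrides: dict[str, int] | None = None,
) -> list[CatalogEntry]:
    """Assign z = 1..k by ascending lambda2 within a single order.

    ``colors`` maps "n.z" index strings to color classes; ``z_overrides``
    maps canonical-form keys to pinned ranks (remaining trees fill the free
    ranks in spectral order).
    """
    if not trees:
        return []
    order = trees[0].order
    if any(t.order != order for t in trees):
        raise TreeError("rag_rank requires trees of a single order")
    keys = [canonical_form(t) for t in trees]
    if len(set(keys)) != len(keys):
        raise TreeError("rag_rank requires pairwise non-isomorphic trees")

    ranked = sorted(
        zip(trees, keys),
        key=lambda tk: (tuple(laplacian_spectrum(tk[0]).round(9)), tk[1]),
    )
    z_overrides = z_overrides or {}
    assignment: dict[int, Tree] = {}
    free = [z for z in range(1, len(trees) + 1)]
    for key, z in z_overrides.items():
        free.remove(z)
    it = iter(free)
    for t, key in ranked:
        z = z_overrides.get(key)
        if z is None:
            z = next(it)
        assignment[z] = t

    colors = colors if colors is not None else _PAPER_COLORS
    entries = []
    for z in sorted(assignment):
        t = assignment[z]
        idx = f"{order}.{z}"
        if idx in colors:
            color, source = colors[idx], "paper"
        else:
            color, source = _default_color(order), "default"
        entries.append(CatalogEntry(t, order, z, lambda2(t), color, source))
    return entries


class Catalog:
    """Indexed collection of catalog entries across orders."""

    def __init__(self, entries: list[CatalogEntry]):
        self.entries = sorted(entries, key=lambda e: (e.order, e.z))
        self._by_index = {e.index: e for e in self.entries}
        self._by_key = {canonical_form(e.tree): e for e in self.entries}
        if len(self._by_index) != len(self.entries):
            raise TreeError("duplicate RAG indices in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def orders(self) -> list[int]:
        return sorted({e.order for e in self.entries})

    def by_index(self, index: str) -> CatalogEntry:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"no catalog entry with RAG index {index!r}") from None

    def of_order(self, order: int) -> list[CatalogEntry]:
        return [e for e in self.entries if e.order == order]

    def entry_for(self, t: Tree) -> CatalogEntry:
        """The entry whose tree is isomorphic to ``t``."""
        key = canonical_form(t)
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(
                f"no catalog entry isomorphic to the given tree of order {t.order}"
            ) from None

    def classified(self, orders=None) -> list[CatalogEntry]:
        """Entries with a decided red/black class (the training universe)."""
        return [
            e
            for e in self.entries
            if e.color in ("red", "black") and (orders is None or e.order in orders)
        ]

    def unknown(self, orders=None) -> list[CatalogEntry]:
        return [
            e
            for e in self.entries
            if e.color == "unknown" and (orders is None or e.order in orders)
        ]


def build_catalog(
    max_order: int = 9,
    colors: dict[str, str] | None = None,
    z_overrides: dict[int, dict[str, int]] | None = None,
) -> Catalog:
    """Enumerate and rank all trees of orders 2..max_order from scratch."""
    entries: list[CatalogEntry] = []
    for n in range(2, max_order + 1):
        ov = (z_overrides or {}).get(n)
        entries.extend(rag_rank(enumerate_trees(n), colors=colors, z_overrides=ov))
    return Catalog(entries)


_CATALOG_HEADER = ["rag_index", "order", "edges", "lambda2", "color", "source"]


def write_catalog(catalog: Catalog, path) -> None:
    lines = ["\t".join(_CATALOG_HEADER)]
    for e in catalog:
        edges = ";".join(f"{a}-{b}" for a, b in sorted(e.tree.edges))
        lines.append(
            f"{e.index}\t{e.order}\t{edges}\t{e.lambda2:.5f}\t{e.color}\t{e.source}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_catalog(path) -> Catalog:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines[0].split("\t") != _CATALOG_HEADER:
        raise ValueError(f"unrecognized catalog header in {path}")
    entries = []
    for ln in lines[1:]:
        idx, order, edges, lam, color, source = ln.split("\t")
        n = int(order)
        tree = Tree.from_edges(
            (tuple(map(int, e.split("-"))) for e in edges.split(";")), order=n
        )
        if color not in COLORS:
            raise ValueError(f"unknown color {color!r} for entry {idx}")
        entries.append(
            CatalogEntry(tree, n, int(idx.split(".")[1]), float(lam), color, source)
        )
    return Catalog(entries)


def load_default_catalog() -> Catalog:
    """The bundled catalog of all 94 trees on 2-9 vertices."""
    ref = importlib.resources.files("ragmerge").joinpath("data/catalog.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_catalog(p)
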