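"""Signed circular gene orders and breakpoint-style rearrangement distance.

A genome's gene order is the circular sequence of signed gene labels (sign =
coding strand) read by start coordinate. Two orders are compared on their
common label universe through signed adjacencies: the unordered pair of
oriented neighbours on the circle, canonicalised so that a whole-molecule
flip (reverse-complement of the circle, which negates both signs and swaps
the order) maps every adjacency onto itself. The breakpoint count is the
number of common genes minus the number of shared adjacencies; it is zero
exactly when the two circular orders coincide up to rotation and reflection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_model import MitoGenome

__all__ = ["GeneOrder", "extract_order", "order_distance", "OrderDistance"]


@dataclass
class GeneOrder:
    species: str
    order: list[tuple[str, int]]  # (label, +1/-1) in circular start order

    def __len__(self) -> int:
        return len(self.order)

    def labels(self) -> set[str]:
        return {lab for lab, _ in self.order}

    def restrict(self, universe: set[str]) -> "GeneOrder":
        return GeneOrder(self.species, [(l, s) for l, s in self.order if l in universe])

    def as_text(self) -> str:
        return ",".join(("" if s > 0 else "-") + l for l, s in self.order)


def extract_order(
    genome: MitoGenome,
    universe: set[str] | None = None,
    include_trna: bool = True,
) -> GeneOrder:
    """Read the signed circular gene order of a genome.

    Top-level features (core PCGs, ORFs only if in ``universe``, rRNAs,
    tRNAs unless collapsed, rnpB) are listed by start coordinate; duplicated
    labels (e.g. three trnM isoacceptors) are disambiguated by anticodon when
    available, then by occurrence rank (``trnM.1``, ``trnM.2``, ...).
    """
    feats = []
    for f in genome.genes():
        if universe is not None:
            if f.name not in universe:
                continue
        elif f.ftype == "orf":
            continue
        if f.ftype == "trna" and not include_trna:
            continue
        feats.append(f)
    feats.sort(key=lambda f: (f.start, f.end))
    name_counts = Counter(f.name for f in feats)
    base_labels = [
        f"{f.name}-{f.anticodon}" if name_counts[f.name] > 1 and f.anticodon else f.name
        for f in feats
    ]
    label_counts = Counter(base_labels)
    seen: Counter[str] = Counter()
    order: list[tuple[str, int]] = []
    for f, base in zip(feats, base_labels):
        label = base
        if label_counts[base] > 1:
            seen[base] += 1
            label = f"{base}.{seen[base]}"
        order.append((label, 1 if f.strand == "+" else -1))
    return GeneOrder(genome.id, order)


def _adjacencies(order: list[tuple[str, int]]) -> set[tuple]:
    """Canonical signed adjacency set of a circular order.

    Adjacency ((x, sx), (y, sy)) for consecutive x then y; the reflected
    molecule yields ((y, -sy), (x, -sx)), so the canonical form is the
    lexicographic minimum of the two representations.
    """
    n = len(order)
    out = set()
    for i in range(n):
        x, sx = order[i]
        y, sy = order[(i + 1) % n]
        fwd = ((x, sx), (y, sy))
        rev = ((y, -sy), (x, -sx))
        out.add(min(fwd, rev))
    return out


@dataclass
class OrderDistance:
    shared_adjacencies: int
    breakpoints: int
    common_genes: int
    identical: bool


def order_distance(a: GeneOrder, b: GeneOrder) -> OrderDistance:
    """Shared-adjacency / breakpoint comparison of two circular gene orders.

    Orders are first reduced to the common label universe. ``identical`` is
    true iff the circular orders agree up to rotation and whole-molecule
    reflection with strand flip, equivalently iff the breakpoint count is 0.
    """
    common = a.labels() & b.labels()
    if len(common) < 3:
        raise ValueError(f"fewer than 3 common labels ({len(common)})")
    ra, rb = a.restrict(common), b.restrict(common)
    adj_a, adj_b = _adjacencies(ra.order), _adjacencies(rb.order)
    shared = len(adj_a & adj_b)
    breakpoints = len(common) - shared
    return OrderDistance(
        shared_adjacencies=shared,
        breakpoints=breakpoints,
        common_genes=len(common),
        identical=(breakpoints == 0),
    )
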