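"""Concatenated-gene supermatrix and neighbor-joining distance phylogeny.

Builds the combined mitochondrial gene set (by default the 15 core
protein-coding genes plus the two rRNAs), concatenates per-gene alignments
into a supermatrix with recorded partition boundaries, computes pairwise K2P
distances with pairwise deletion, and infers an unrooted tree by canonical
neighbor joining (Saitou & Nei agglomeration) with deterministic
lexicographic tie-breaking. Negative NJ branch-length estimates are clamped
to zero and flagged. Optional nonparametric bootstrap resamples alignment
columns with a seeded RNG and maps split support onto the NJ tree.

This distance tree is a fast, fully reproducible stand-in for Bayesian /
maximum-likelihood inference, which is deliberately out of scope; writers
for relaxed PHYLIP, FASTA and a plain-text partition file let users hand the
supermatrix to external ML/BI tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._align import align_pair
from .genome_model import CORE_PCGS, GenomeSet, spliced_cds
from .molevol import k2p

__all__ = [
    "Supermatrix",
    "TreeNode",
    "build_supermatrix",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_support",
    "DEFAULT_GENES",
]

DEFAULT_GENES = sorted(CORE_PCGS) + ["rnl", "rns"]


@dataclass
class Supermatrix:
    species: list[str]
    rows: dict[str, str]  # species -> concatenated aligned sequence
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp in self.species:
                fh.write(f">{sp}\n{self.rows[sp]}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.species)} {self.width}\n")
            for sp in self.species:
                fh.write(f"{sp}  {self.rows[sp]}\n")

    def write_partitions(self, path) -> None:
        with open(path, "w") as fh:
            for gene, s, e in self.partitions:
                fh.write(f"DNA, {gene} = {s}-{e}\n")


def _reference_project(seqs: dict[str, str], ref_id: str) -> dict[str, str]:
    """Align every row to the reference row and project onto its columns.

    Insertions relative to the reference are dropped; deletions become gaps.
    Exact (a no-op) whenever all rows have equal length, which is the case
    for indel-free data.
    """
    ref = seqs[ref_id]
    if len(set(map(len, seqs.values()))) == 1:
        return dict(seqs)
    out = {}
    for sp, seq in seqs.items():
        if len(seq) == len(ref):
            out[sp] = seq
            continue
        a_seq, a_ref = align_pair(seq, ref, kind="dna")
        row = []
        for cs, cr in zip(a_seq, a_ref):
            if cr != "-":
                row.append(cs if cs != "-" else "-")
        out[sp] = "".join(row)
    return out


def build_supermatrix(
    genomes: GenomeSet,
    genes: list[str] | None = None,
    max_missing_frac: float = 0.25,
) -> Supermatrix:
    """Concatenate per-gene alignments across a genome set.

    A gene missing from a species is gap-filled for that row; a species
    missing more than ``max_missing_frac`` of the genes is excluded with a
    warning. Partition boundaries (1-based inclusive) are recorded per gene.
    """
    if genes is None:
        genes = DEFAULT_GENES
    per_gene: dict[str, dict[str, str]] = {}
    for gene in genes:
        seqs: dict[str, str] = {}
        for g in genomes:
            try:
                if gene in ("rnl", "rns"):
                    feat = g.get(gene, "rrna")
                    seqs[g.id] = g.extract(feat)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        seqs[g.id] = spliced_cds(g, gene)
            except KeyError:
                continue
        if len(seqs) >= 2:
            ref_id = next(iter(seqs))
            per_gene[gene] = _reference_project(seqs, ref_id)

    species = [g.id for g in genomes]
    missing = {
        sp: sum(1 for gene in per_gene if sp not in per_gene[gene]) for sp in species
    }
    kept = []
    for sp in species:
        if per_gene and missing[sp] > max_missing_frac * len(per_gene):
            warnings.warn(f"{sp}: missing {missing[sp]}/{len(per_gene)} genes; excluded")
        else:
            kept.append(sp)

    rows = {sp: [] for sp in kept}
    partitions = []
    pos = 1
    for gene in genes:
        if gene not in per_gene:
            continue
        aligned = per_gene[gene]
        width = len(next(iter(aligned.values())))
        for sp in kept:
            rows[sp].append(aligned.get(sp, "-" * width))
        partitions.append((gene, pos, pos + width - 1))
        pos += width
    return Supermatrix(
        species=kept,
        rows={sp: "".join(chunks) for sp, chunks in rows.items()},
        partitions=partitions,
    )


def k2p_matrix(sm: Supermatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P distance matrix on the supermatrix (pairwise deletion)."""
    ids = list(sm.species)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p(sm.rows[ids[i]], sm.rows[ids[j]])
            if res.saturated or not np.isfinite(res.distance):
                raise ValueError(f"non-finite distance between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = res.distance
    return ids, d


@dataclass
class TreeNode:
    """Minimal unrooted-tree node (rooted representation for serialisation)."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    clamped: bool = False  # a negative NJ branch estimate was clamped to 0

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out

    def splits(self) -> set[frozenset]:
        """Unrooted bipartitions, each as frozenset({side, complement})."""
        all_leaves = frozenset(self.leaves())
        out = set()

        def walk(node: TreeNode):
            for child, _bl in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(frozenset({side, all_leaves - side}))
                walk(child)

        walk(self)
        return out

    def newick(self, support: dict[frozenset, float] | None = None) -> str:
        all_leaves = frozenset(self.leaves())

        def fmt(node: TreeNode, bl: float | None) -> str:
            if not node.children:
                core = node.label
            else:
                inner = ",".join(
                    fmt(c, b) for c, b in sorted(
                        node.children, key=lambda cb: min(cb[0].leaves())
                    )
                )
                lab = ""
                if support is not None:
                    side = frozenset(node.leaves())
                    key = frozenset({side, all_leaves - side})
                    if key in support:
                        lab = f"{support[key]:.0f}"
                core = f"({inner}){lab}"
            return core if bl is None else f"{core}:{bl:.6f}"

        return fmt(self, None) + ";"


def nj_tree(ids: list[str], dist: np.ndarray) -> TreeNode:
    """Canonical neighbor joining with lexicographic tie-breaking.

    For n = 3 the unique unrooted star is returned with closed-form branch
    lengths. Ties in the Q criterion are broken by the sorted label pair, so
    the result is independent of input taxon order. Negative branch-length
    estimates are clamped to zero and flagged on the child node.
    """
    if not np.all(np.isfinite(dist)):
        bad = [
            (ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if not np.isfinite(dist[i, j])
        ]
        raise ValueError(f"non-finite distances for pairs: {bad}")
    nodes: dict[str, TreeNode] = {t: TreeNode(label=t) for t in ids}
    # active map: key -> (node, min leaf label for tie-breaks)
    active = list(ids)
    d = {(a, b): float(dist[i, j]) for i, a in enumerate(ids) for j, b in enumerate(ids)}

    def D(a: str, b: str) -> float:
        return d[(a, b)] if a != b else 0.0

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D(a, b) for b in active) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * D(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = D(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        ca, cb = max(0.0, la), max(0.0, lb)
        node_a, node_b = nodes[a], nodes[b]
        node_a.clamped = node_a.clamped or la < 0
        node_b.clamped = node_b.clamped or lb < 0
        counter += 1
        new_key = f"@{min(a, b)}"
        parent = TreeNode(children=[(node_a, ca), (node_b, cb)])
        for c in active:
            if c in (a, b):
                continue
            d[(new_key, c)] = d[(c, new_key)] = 0.5 * (D(a, c) + D(b, c) - dab)
        nodes[new_key] = parent
        active = sorted(set(active) - {a, b} | {new_key})

    if len(active) == 3:
        a, b, c = sorted(active)
        la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
        lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
        lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
        root = TreeNode(
            children=[
                (nodes[a], max(0.0, la)),
                (nodes[b], max(0.0, lb)),
                (nodes[c], max(0.0, lc)),
            ]
        )
        for nd, raw in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
            nd.clamped = nd.clamped or raw < 0
        return root
    if len(active) == 2:
        a, b = sorted(active)
        return TreeNode(children=[(nodes[a], D(a, b) / 2), (nodes[b], D(a, b) / 2)])
    return nodes[active[0]]


def bootstrap_support(
    sm: Supermatrix,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Site-resampling bootstrap support mapped onto the full-data NJ tree."""
    ids, d = k2p_matrix(sm)
    main = nj_tree(ids, d)
    main_splits = main.splits()
    counts = {s: 0 for s in main_splits}
    rng = np.random.default_rng(seed)
    cols = np.array([list(sm.rows[sp]) for sp in sm.species])
    width = cols.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, width, size=width)
        boot_rows = {
            sp: "".join(cols[i, idx]) for i, sp in enumerate(sm.species)
        }
        boot = Supermatrix(species=sm.species, rows=boot_rows, partitions=sm.partitions)
        try:
            bids, bd = k2p_matrix(boot)
            splits = nj_tree(bids, bd).splits()
        except ValueError:
            continue
        for s in main_splits:
            if s in splits:
                counts[s] += 1
    support = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return main, support
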