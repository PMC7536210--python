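"""Base composition, strand skews, region partitioning and codon usage.

Strand asymmetry follows the standard skew statistics
``AT skew = (A - T)/(A + T)`` and ``GC skew = (G - C)/(G + C)``. The genome
is partitioned position-by-position into four mutually exclusive categories
— RNA genes (tRNA + rRNA exons + rnpB), protein-coding exons, intronic
(intron spans, including any intron-encoded ORF), and intergenic — whose
totals conserve the genome length exactly. Codon usage is computed under the
mold-mitochondrial genetic code (translation table 4, TGA = Trp).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .genome_model import CORE_PCGS, GenomeSet, MitoGenome, spliced_cds

__all__ = [
    "CompositionSummary",
    "RegionPartition",
    "OverlapRecord",
    "CodonUsageTable",
    "composition_summary",
    "partition_regions",
    "detect_overlaps",
    "codon_usage",
]

CATEGORIES = ("coding", "intronic", "rna", "intergenic")


@dataclass
class CompositionSummary:
    a: int
    c: int
    g: int
    t: int
    n: int
    gc_percent: float
    at_percent: float
    at_skew: float
    gc_skew: float

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.n


def composition_summary(seq: str) -> CompositionSummary:
    """Base counts, GC/AT content and strand skews of a DNA sequence.

    Positions holding the ambiguity code N are excluded from every numerator
    and denominator. Percentages are on the 0-100 scale.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    a, c, g, t, n = (counts.get(b, 0) for b in "ACGTN")
    acgt = a + c + g + t
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    at = a + t
    gc = g + c
    return CompositionSummary(
        a=a, c=c, g=g, t=t, n=n,
        gc_percent=100.0 * gc / acgt,
        at_percent=100.0 * at / acgt,
        at_skew=(a - t) / at if at else float("nan"),
        gc_skew=(g - c) / gc if gc else float("nan"),
    )


@dataclass
class RegionPartition:
    """Per-nucleotide four-way split of a genome and derived totals."""

    categories: np.ndarray  # int8 codes indexing CATEGORIES, length = genome
    totals: dict[str, int]
    percents: dict[str, float]
    spacers: list[tuple[str, str, int]]  # (left gene, right gene, length)

    @property
    def intergenic_total(self) -> int:
        return self.totals["intergenic"]

    @property
    def longest_spacer(self) -> tuple[str, str, int] | None:
        return max(self.spacers, key=lambda s: s[2]) if self.spacers else None


def _paint(mask: np.ndarray, intervals, code: int) -> None:
    for s, e in intervals:
        mask[s - 1 : e] = code


def partition_regions(genome: MitoGenome) -> RegionPartition:
    """Assign every nucleotide to exactly one of the four region categories.

    Precedence (highest first): rna > coding > intronic > intergenic, i.e.
    a position inside both an rRNA exon and something else counts as rna,
    intron-encoded ORFs count as intronic, and overlapping coding genes are
    counted once so the four totals sum exactly to the genome length.
    """
    n = genome.length
    cat = np.zeros(n, dtype=np.int8)  # 0 = intergenic
    code = {"intergenic": 0, "intronic": 1, "coding": 2, "rna": 3}
    # lowest precedence painted first so later paints win
    for f in genome.features:
        if f.ftype in ("intron", "intronic_orf"):
            _paint(cat, f.intervals, code["intronic"])
    for f in genome.features:
        if f.ftype in ("core_pcg", "orf"):
            _paint(cat, f.intervals, code["coding"])
    for f in genome.features:
        if f.ftype in ("trna", "rrna", "rnpB"):
            _paint(cat, f.intervals, code["rna"])

    totals = {c: int(np.sum(cat == code[c])) for c in CATEGORIES}
    percents = {c: 100.0 * totals[c] / n for c in CATEGORIES}

    # Intergenic spacers: gaps between consecutive top-level features around
    # the circle, zero-length gaps included. Each feature occupies its full
    # span (introns travel with their host gene).
    genes = genome.genes()
    spacers: list[tuple[str, str, int]] = []
    if genes:
        spans = sorted((f.span(), f.name) for f in genes)
        m = len(spans)
        for i in range(m):
            (s1, e1), left = spans[i]
            (s2, _e2), right = spans[(i + 1) % m]
            if i + 1 < m:
                gap = s2 - e1 - 1
            elif genome.circular:
                gap = (s2 - 1) + (n - e1)
            else:
                continue
            if gap >= 0:
                spacers.append((left, right, gap))
    return RegionPartition(categories=cat, totals=totals, percents=percents, spacers=spacers)


@dataclass
class OverlapRecord:
    gene_a: str
    gene_b: str
    overlap: int  # nt


def detect_overlaps(genome: MitoGenome) -> list[OverlapRecord]:
    """Report every pair of non-intron features sharing at least one nucleotide.

    Circular adjacency is included; the shared length is the exact size of the
    position-set intersection of the two features' segments. Intronic ORFs are
    excluded (they lie inside their host's intron by construction), as are
    intron features themselves.
    """
    genes = genome.genes()
    n = genome.length
    cover: dict[int, list[int]] = {}
    for idx, f in enumerate(genes):
        for p in f.positions():
            cover.setdefault(p % n, []).append(idx)
    shared: Counter[tuple[int, int]] = Counter()
    for occupants in cover.values():
        if len(occupants) > 1:
            uniq = sorted(set(occupants))
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    shared[(uniq[i], uniq[j])] += 1
    out = [
        OverlapRecord(genes[i].name, genes[j].name, cnt)
        for (i, j), cnt in sorted(shared.items())
    ]
    return out


@dataclass
class CodonUsageTable:
    """Codon counts and RSCU over a set of coding sequences (code 4)."""

    counts: dict[str, int]
    rscu: dict[str, float]
    starts: dict[tuple[str, str], str]  # (genome id, gene) -> start codon
    stops: dict[tuple[str, str], str]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def most_frequent(self, k: int = 6) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def codon_usage(
    genomes: GenomeSet | MitoGenome,
    genes: list[str] | None = None,
    table: int = 4,
) -> CodonUsageTable:
    """Codon usage over the selected genes of one genome or a genome set.

    Counts cover every codon of each spliced CDS, including start and stop;
    the start codon is the first triplet and the stop codon the last triplet
    as annotated, with no re-calling of alternative starts. A CDS whose
    spliced length is not divisible by 3 is excluded with a warning. RSCU for
    a codon is its count divided by the mean count of its synonym family
    under the requested genetic code.
    """
    if isinstance(genomes, MitoGenome):
        genomes = GenomeSet([genomes])
    ct = CodonTable.unambiguous_dna_by_id[table]
    counts: Counter[str] = Counter()
    starts: dict[tuple[str, str], str] = {}
    stops: dict[tuple[str, str], str] = {}
    excluded: list[tuple[str, str]] = []
    for g in genomes:
        present = [
            f.name
            for f in g.features
            if f.ftype in ("core_pcg", "orf")
            and (genes is None or f.name in genes)
        ]
        for gene in present:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cds = spliced_cds(g, gene)
            if len(cds) % 3 or not cds:
                warnings.warn(f"{g.id}:{gene}: length {len(cds)} not divisible by 3; excluded")
                excluded.append((g.id, gene))
                continue
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            counts.update(c for c in codons if set(c) <= set("ACGT"))
            starts[(g.id, gene)] = codons[0]
            stops[(g.id, gene)] = codons[-1]

    # RSCU: observed / expected-under-uniform-synonym-use
    families: dict[str, list[str]] = {}
    for codon, aa in ct.forward_table.items():
        families.setdefault(aa, []).append(codon)
    families["*"] = list(ct.stop_codons)
    rscu: dict[str, float] = {}
    for aa, codons in families.items():
        tot = sum(counts.get(c, 0) for c in codons)
        if tot == 0:
            continue
        mean = tot / len(codons)
        for c in codons:
            rscu[c] = counts.get(c, 0) / mean
    return CodonUsageTable(counts=dict(counts), rscu=rscu, starts=starts, stops=stops, excluded=excluded)
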