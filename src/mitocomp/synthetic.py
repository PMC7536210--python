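"""Synthetic annotated mitogenomes with complete ground-truth manifests.

The generator emulates the architecture of a Polyporales-type fungal
mitochondrial genome: a circular molecule in the 50-160 kb range carrying
the 15 core protein-coding genes, free-standing ORFs, the two rRNAs, a tRNA
complement of ~25-29, *rnpB*, group-I introns inserted at controlled codon
positions of host genes, planted direct / inverted / tandem repeats, and an
AT-rich base composition with controllable GC content and strand skews.
Every realized coordinate, repeat pair, intron class, substitution count and
gene order is recorded in a truth manifest sufficient to recompute expected
analysis output without re-running the generator.

Divergence is simulated by :func:`evolve_set`: the ancestor genome is
decomposed into its gene and intergenic components, sequences evolve down a
tree under a Kimura-type substitution process (transition/transversion ratio
``kappa``) with per-gene dN/dS enforced by acceptance sampling over codon
changes (start and stop codons held fixed, stop-creating changes rejected),
and each leaf genome is reassembled with its planned intron complement and
gene-order rearrangements.

All randomness flows from a single :class:`numpy.random.Generator` keyed by
the mandatory seed, so identical specs produce byte-identical output.
"""

from __future__ import annotations

import copy
import json
import math
import re
from dataclasses import asdict, dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .genome_model import Feature, GenomeSet, MitoGenome, reverse_complement

__all__ = [
    "GenePlan",
    "IntronPlan",
    "RepeatPlan",
    "TandemPlan",
    "SyntheticSpec",
    "DivergencePlan",
    "default_spec",
    "generate_genome",
    "evolve_set",
    "parse_newick",
    "spec_from_json",
]

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# Plans


@dataclass
class GenePlan:
    name: str
    ftype: str  # core_pcg, orf, trna, rrna, rnpB
    length: int  # nt; for coding genes includes start and stop codons
    strand: str = "+"
    anticodon: str | None = None


@dataclass
class IntronPlan:
    host: str
    codon: int
    phase: int
    length: int
    group_type: str = "I"
    orf_length: int = 0  # optional intron-encoded ORF, 0 = none


@dataclass
class RepeatPlan:
    length: int
    orientation: str = "forward"  # forward | palindromic | reverse | complemented
    identity: float = 100.0


@dataclass
class TandemPlan:
    unit_length: int
    copies: int


@dataclass
class SyntheticSpec:
    length: int
    genes: list[GenePlan]
    introns: list[IntronPlan] = field(default_factory=list)
    repeats: list[RepeatPlan] = field(default_factory=list)
    tandems: list[TandemPlan] = field(default_factory=list)
    gc: float = 0.26
    at_skew: float = -0.03
    gc_skew: float = 0.06
    codon_weights: dict[str, float] | None = None
    genome_id: str = "synthetic"
    seed: int | None = None

    def base_probs(self) -> np.ndarray:
        at = 1.0 - self.gc
        pa = at * (1.0 + self.at_skew) / 2.0
        pt = at * (1.0 - self.at_skew) / 2.0
        pg = self.gc * (1.0 + self.gc_skew) / 2.0
        pc = self.gc * (1.0 - self.gc_skew) / 2.0
        return np.array([pa, pc, pg, pt])  # ACGT order


def spec_from_json(path) -> SyntheticSpec:
    """Load a spec from a structured JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    return SyntheticSpec(
        length=raw["length"],
        genes=[GenePlan(**g) for g in raw.get("genes", [])],
        introns=[IntronPlan(**i) for i in raw.get("introns", [])],
        repeats=[RepeatPlan(**r) for r in raw.get("repeats", [])],
        tandems=[TandemPlan(**t) for t in raw.get("tandems", [])],
        gc=raw.get("gc", 0.26),
        at_skew=raw.get("at_skew", -0.03),
        gc_skew=raw.get("gc_skew", 0.06),
        genome_id=raw.get("genome_id", "synthetic"),
        seed=raw.get("seed"),
    )


_TRNA_AA = [
    "A", "C", "D", "F", "G", "H", "I", "K", "L", "N", "P", "Q",
    "S", "T", "V", "W", "Y", "E", "E", "E", "M", "M", "M", "R", "R", "L", "S",
]


def default_spec(seed: int = 1) -> SyntheticSpec:
    """A 115 kb genome mirroring the architecture of a large Polyporales
    mitogenome: 15 core PCGs, 19 free-standing ORFs, 2 rRNAs, 27 tRNAs
    (with duplicated isoacceptors), rnpB, 24 group-I introns in
    cox1/cob/nad1/rnl, planted repeats and tandem arrays, GC 26%."""
    core = {
        "atp6": 780, "atp8": 147, "atp9": 225, "cob": 1179, "cox1": 1608,
        "cox2": 750, "cox3": 810, "nad1": 1086, "nad2": 1686, "nad3": 420,
        "nad4": 1476, "nad4L": 270, "nad5": 2016, "nad6": 654, "rps3": 1482,
    }
    genes: list[GenePlan] = []
    strands = ["+", "+", "-", "+", "+", "+", "-", "+", "+", "+", "+", "+", "+", "-", "+"]
    for (name, ln), st in zip(sorted(core.items()), strands):
        genes.append(GenePlan(name, "core_pcg", ln, st))
    genes.append(GenePlan("rnl", "rrna", 3500, "+"))
    genes.append(GenePlan("rns", "rrna", 1700, "+"))
    genes.append(GenePlan("rnpB", "rnpB", 329, "+"))
    orf_lengths = [879, 1176, 402, 735, 1164, 318, 636, 885, 444, 1005,
                   555, 726, 369, 810, 963, 489, 1338, 603, 876]
    for ln in orf_lengths:
        genes.append(GenePlan(f"orf{ln // 3 - 1}", "orf", ln, "+"))
    for k, aa in enumerate(_TRNA_AA):
        genes.append(GenePlan(f"trn{aa}", "trna", 72 + (k % 3) * 5, "+",
                              anticodon=f"ac{k:02d}"))
    introns = []
    cox1_sites = [(44, 0), (85, 1), (121, 0), (167, 2), (210, 0), (250, 2),
                  (291, 0), (345, 1), (398, 0), (430, 0), (462, 1), (500, 0)]
    for c, p in cox1_sites:
        introns.append(IntronPlan("cox1", c, p, 1400, "I", orf_length=600))
    for c, p in [(60, 0), (130, 0), (197, 1), (240, 0), (310, 2), (355, 0)]:
        introns.append(IntronPlan("cob", c, p, 1450, "I", orf_length=600))
    for c, p in [(101, 0), (220, 0)]:
        introns.append(IntronPlan("nad1", c, p, 1400, "I"))
    # rnl introns: codon here indexes the rRNA in nt/3 units for placement
    for c, p in [(300, 0), (500, 0), (700, 0), (900, 0)]:
        introns.append(IntronPlan("rnl", c, p, 1450, "I", orf_length=600))
    repeats = [
        RepeatPlan(902, "forward", 100.0),
        RepeatPlan(840, "forward", 98.0),
        RepeatPlan(300, "palindromic", 100.0),
        RepeatPlan(120, "reverse", 100.0),
        RepeatPlan(60, "complemented", 100.0),
    ]
    tandems = [TandemPlan(79, 2), TandemPlan(12, 6), TandemPlan(25, 3)]
    return SyntheticSpec(
        length=115_000, genes=genes, introns=introns, repeats=repeats,
        tandems=tandems, seed=seed, genome_id="Tcamp_like",
    )


# ---------------------------------------------------------------------------
# Sequence sampling


def _random_seq(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=probs)])


def _default_codon_weights(probs: np.ndarray, table: int = 4) -> dict[str, float]:
    """Codon weights proportional to the product of target base probabilities,
    renormalised over non-stop codons; yields the AT-rich usage (TTT, AAA,
    TTA dominating) characteristic of fungal mitogenomes at low GC."""
    ct = CodonTable.unambiguous_dna_by_id[table]
    stops = set(ct.stop_codons)
    w = {}
    for c in ct.forward_table:
        if c in stops:
            continue
        w[c] = float(np.prod([probs[_IDX[b]] for b in c]))
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


def _random_cds(length: int, weights: dict[str, float], rng: np.random.Generator) -> str:
    if length % 3 or length < 9:
        raise ValueError(f"CDS length {length} must be divisible by 3 and >= 9")
    codons = sorted(weights)
    p = np.array([weights[c] for c in codons])
    p = p / p.sum()
    body = rng.choice(len(codons), size=length // 3 - 2, p=p)
    return "ATG" + "".join(codons[i] for i in body) + "TAA"


# ---------------------------------------------------------------------------
# Component model (shared by generation and evolution)


@dataclass
class _IntronComponent:
    codon: int
    phase: int
    seq: str
    group_type: str = "I"
    orf_length: int = 0

    @property
    def offset(self) -> int:
        return 3 * self.codon if self.phase == 0 else 3 * (self.codon - 1) + self.phase


@dataclass
class _GeneComponent:
    name: str
    ftype: str
    strand: str
    seq: str  # transcript-orientation sequence (CDS for coding genes)
    anticodon: str | None = None
    introns: list[_IntronComponent] = field(default_factory=list)


@dataclass
class _Block:
    """A contiguous stretch of the assembled genome."""

    kind: str  # gene | gap | repeat | tandem
    seq: str = ""
    gene: _GeneComponent | None = None
    tag: dict | None = None


def _gene_block_seq(comp: _GeneComponent) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """Transcript-with-introns sequence plus exon/intron transcript intervals
    (0-based half-open, transcript orientation)."""
    introns = sorted(comp.introns, key=lambda i: i.offset)
    pieces = []
    exon_ivals = []
    intron_ivals = []
    prev = 0
    pos = 0
    for intr in introns:
        exon = comp.seq[prev : intr.offset]
        pieces.append(exon)
        exon_ivals.append((pos, pos + len(exon)))
        pos += len(exon)
        pieces.append(intr.seq)
        intron_ivals.append((pos, pos + len(intr.seq)))
        pos += len(intr.seq)
        prev = intr.offset
    tail = comp.seq[prev:]
    pieces.append(tail)
    exon_ivals.append((pos, pos + len(tail)))
    return "".join(pieces), exon_ivals, intron_ivals


def _transcript_to_genomic(ivals, block_start: int, block_len: int, strand: str):
    """Map 0-based half-open transcript intervals to 1-based genomic ones."""
    out = []
    for s, e in ivals:
        if e <= s:
            continue
        if strand == "+":
            out.append((block_start + s, block_start + e - 1))
        else:
            out.append((block_start + block_len - e, block_start + block_len - 1 - s + 0))
    return sorted(out)


def _assemble(blocks: list[_Block], genome_id: str) -> tuple[MitoGenome, dict]:
    """Lay blocks around the circle and realise features + manifest entries."""
    seq_parts: list[str] = []
    features: list[Feature] = []
    manifest: dict = {"repeats_raw": [], "tandems": [], "introns": [], "features": []}
    pos = 1  # 1-based start of next block
    for blk in blocks:
        if blk.kind == "gene":
            comp = blk.gene
            tseq, exon_t, intron_t = _gene_block_seq(comp)
            gseq = tseq if comp.strand == "+" else reverse_complement(tseq)
            exon_g = _transcript_to_genomic(exon_t, pos, len(tseq), comp.strand)
            feat = Feature(
                name=comp.name,
                ftype=comp.ftype,
                strand=comp.strand,
                intervals=exon_g,
                anticodon=comp.anticodon,
            )
            features.append(feat)
            introns_sorted = sorted(comp.introns, key=lambda i: i.offset)
            for ordinal, (intr, t_iv) in enumerate(
                zip(introns_sorted, intron_t), start=1
            ):
                g_iv = _transcript_to_genomic([t_iv], pos, len(tseq), comp.strand)[0]
                features.append(
                    Feature(
                        name=f"{comp.name}-i{ordinal}",
                        ftype="intron",
                        strand=comp.strand,
                        intervals=[g_iv],
                        host=comp.name,
                        group_type=intr.group_type,
                    )
                )
                manifest["introns"].append(
                    {
                        "host": comp.name, "codon": intr.codon, "phase": intr.phase,
                        "interval": list(g_iv), "ordinal": ordinal,
                    }
                )
                if intr.orf_length and intr.orf_length + 20 < (g_iv[1] - g_iv[0] + 1):
                    s = g_iv[0] + 10
                    features.append(
                        Feature(
                            name=f"orf{intr.orf_length // 3 - 1}.{comp.name}.{ordinal}",
                            ftype="intronic_orf",
                            strand=comp.strand,
                            intervals=[(s, s + intr.orf_length - 1)],
                            host=comp.name,
                        )
                    )
            seq_parts.append(gseq)
            pos += len(gseq)
        else:
            if blk.tag is not None:
                entry = dict(blk.tag)
                entry["interval"] = [pos, pos + len(blk.seq) - 1]
                if blk.kind == "repeat":
                    manifest["repeats_raw"].append(entry)
                elif blk.kind == "tandem":
                    manifest["tandems"].append(entry)
            seq_parts.append(blk.seq)
            pos += len(blk.seq)
    seq = "".join(seq_parts)
    genome = MitoGenome(id=genome_id, seq=seq, features=features, circular=True)
    # pair up repeat copies
    pairs: dict[int, list[dict]] = {}
    for entry in manifest.pop("repeats_raw"):
        pairs.setdefault(entry["pair"], []).append(entry)
    manifest["repeats"] = []
    for pid, copies in sorted(pairs.items()):
        a, b = sorted(copies, key=lambda e: e["interval"])
        manifest["repeats"].append(
            {
                "a": a["interval"], "b": b["interval"],
                "length": a["interval"][1] - a["interval"][0] + 1,
                "orientation": a["orientation"], "identity": a["identity"],
            }
        )
    manifest["features"] = [
        {
            "name": f.name, "ftype": f.ftype, "strand": f.strand,
            "intervals": [list(iv) for iv in f.intervals], "host": f.host,
        }
        for f in genome.features
    ]
    totals = {"coding": 0, "intronic": 0, "rna": 0, "intergenic": 0}
    painted = np.zeros(genome.length, dtype=np.int8)
    order = [("intronic", ("intron", "intronic_orf")), ("coding", ("core_pcg", "orf")),
             ("rna", ("trna", "rrna", "rnpB"))]
    for code, (cat, types) in enumerate(order, start=1):
        for f in genome.features:
            if f.ftype in types:
                for s, e in f.intervals:
                    painted[s - 1 : e] = code
    for code, (cat, _types) in enumerate(order, start=1):
        totals[cat] = int((painted == code).sum())
    totals["intergenic"] = int((painted == 0).sum())
    manifest["region_totals"] = totals
    manifest["length"] = genome.length
    manifest["id"] = genome.id
    return genome, manifest


def _mutate_copy(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Introduce uniform mismatches so the copy has ~identity% matches."""
    n_mut = round(len(seq) * (100.0 - identity) / 100.0)
    if n_mut == 0:
        return seq
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for s in sites:
        alts = [b for b in BASES if b != chars[s]]
        chars[s] = alts[rng.integers(3)]
    return "".join(chars)


def generate_genome(spec: SyntheticSpec) -> tuple[MitoGenome, dict]:
    """Realise a spec into an annotated genome plus its truth manifest.

    Deterministic given ``spec.seed``. Raises before emitting anything if the
    planned features cannot be packed into the requested length.
    """
    if spec.seed is None:
        raise ValueError("spec.seed is mandatory")
    rng = np.random.default_rng(spec.seed)
    probs = spec.base_probs()
    weights = spec.codon_weights or _default_codon_weights(probs)

    comps: dict[str, _GeneComponent] = {}
    for gp in spec.genes:
        if gp.ftype in ("core_pcg", "orf"):
            seq = _random_cds(gp.length, weights, rng)
        else:
            seq = _random_seq(gp.length, probs, rng)
        comps[gp.name] = _GeneComponent(gp.name, gp.ftype, gp.strand, seq, gp.anticodon)
    for ip in spec.introns:
        if ip.host not in comps:
            raise ValueError(f"intron host {ip.host!r} not in gene roster")
        host = comps[ip.host]
        off = 3 * ip.codon if ip.phase == 0 else 3 * (ip.codon - 1) + ip.phase
        if not (0 < off < len(host.seq)):
            raise ValueError(f"intron at codon {ip.codon} outside host {ip.host}")
        host.introns.append(
            _IntronComponent(ip.codon, ip.phase, _random_seq(ip.length, probs, rng),
                             ip.group_type, ip.orf_length)
        )

    extra_blocks: list[_Block] = []
    for pid, rp in enumerate(spec.repeats):
        unit = _random_seq(rp.length, probs, rng)
        copy_b = _mutate_copy(unit, rp.identity, rng)
        if rp.orientation == "palindromic":
            copy_b = reverse_complement(copy_b)
        elif rp.orientation == "reverse":
            copy_b = copy_b[::-1]
        elif rp.orientation == "complemented":
            copy_b = reverse_complement(copy_b)[::-1]
        for copy_seq in (unit, copy_b):
            extra_blocks.append(
                _Block("repeat", seq=copy_seq,
                       tag={"pair": pid, "orientation": rp.orientation,
                            "identity": rp.identity})
            )
    for tid, tp in enumerate(spec.tandems):
        unit = _random_seq(tp.unit_length, probs, rng)
        extra_blocks.append(
            _Block("tandem", seq=unit * tp.copies,
                   tag={"unit_length": tp.unit_length, "copies": tp.copies,
                        "unit": unit, "tandem_id": tid})
        )

    gene_blocks = [_Block("gene", gene=comps[gp.name]) for gp in spec.genes]
    content_len = sum(
        len(_gene_block_seq(b.gene)[0]) for b in gene_blocks
    ) + sum(len(b.seq) for b in extra_blocks)
    n_slots = len(gene_blocks) + len(extra_blocks)
    free = spec.length - content_len
    if free < n_slots:  # need at least ~1 nt spacer headroom per slot
        raise ValueError(
            f"planned content ({content_len} nt) does not fit in {spec.length} nt"
        )
    # interleave: scatter the repeat/tandem blocks among the gene blocks
    positions = sorted(rng.choice(len(gene_blocks) + 1, size=len(extra_blocks)))
    ordered: list[_Block] = []
    gi = 0
    for slot in range(len(gene_blocks) + 1):
        while positions and positions[0] == slot:
            positions.pop(0)
            ordered.append(extra_blocks.pop(0))
        if slot < len(gene_blocks):
            ordered.append(gene_blocks[slot])
    gap_lens = rng.multinomial(free, np.ones(len(ordered)) / len(ordered))
    blocks: list[_Block] = []
    for blk, gl in zip(ordered, gap_lens):
        blocks.append(_Block("gap", seq=_random_seq(int(gl), probs, rng)))
        blocks.append(blk)
    genome, manifest = _assemble(blocks, spec.genome_id)
    assert genome.length == spec.length
    manifest["seed"] = spec.seed
    manifest["gc_target"] = spec.gc
    manifest["codon_weights"] = weights
    return genome, manifest


# ---------------------------------------------------------------------------
# Divergence simulation


def parse_newick(text: str):
    """Parse a newick string into (children, label, branch_length) tuples."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> tuple:
        nonlocal pos
        children = []
        label = ""
        if text[pos] == "(":
            pos += 1
            while True:
                children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^,():;]*", text[pos:])
        label = m.group(0)
        pos += len(label)
        bl = 1.0
        if pos < len(text) and text[pos] == ":":
            m = re.match(r":([0-9.eE+-]+)", text[pos:])
            bl = float(m.group(1))
            pos += len(m.group(0))
        return (children, label or None, bl)

    return parse()


@dataclass
class DivergencePlan:
    """Branch-length-scaled substitution process and structural events.

    ``rate`` is the expected number of proposed substitutions per site per
    unit branch length; ``kappa`` the HKY-style transition/transversion rate
    ratio (the expected transition:transversion count ratio is kappa/2, since
    each base has one transition partner and two transversion partners).
    Per-gene
    dN/dS (``gene_dnds``, default ``default_dnds``) is enforced by acceptance
    sampling: synonymous proposals are accepted with probability
    ``min(1, 1/omega)`` and nonsynonymous ones with ``min(1, omega)``.
    ``intron_classes`` defines shared class sequences keyed by
    (host, codon, phase); ``intron_presence`` assigns each leaf its class
    complement (replacing the ancestor's introns of those host genes).
    ``rearrangements`` maps a leaf to segment moves applied to its gene
    order: (start index, segment length, destination index, invert flag).
    """

    rate: float = 0.05
    kappa: float = 2.0
    gene_dnds: dict[str, float] = field(default_factory=dict)
    default_dnds: float = 0.1
    intron_classes: dict[tuple[str, int, int], str] | None = None
    intron_presence: dict[str, list[tuple[str, int, int]]] | None = None
    intron_orf_length: int = 0
    rearrangements: dict[str, list[tuple[int, int, int, bool]]] | None = None
    table: int = 4

    def omega(self, gene: str) -> float:
        return self.gene_dnds.get(gene, self.default_dnds)


def mutate_noncoding(
    seq: str, t: float, rate: float, kappa: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """K2P-style substitution of a noncoding sequence; returns (seq, ts, tv)."""
    n = len(seq)
    if n == 0 or t <= 0 or rate <= 0:
        return seq, 0, 0
    p = 1.0 - math.exp(-rate * t)
    hits = np.flatnonzero(rng.random(n) < p)
    if hits.size == 0:
        return seq, 0, 0
    chars = list(seq)
    ts = tv = 0
    p_ts = kappa / (kappa + 2.0)
    for i in hits:
        base = chars[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < p_ts:
            chars[i] = _TRANSITION[base]
            ts += 1
        else:
            pool = [b for b in BASES if b != base and b != _TRANSITION[base]]
            chars[i] = pool[rng.integers(2)]
            tv += 1
    return "".join(chars), ts, tv


def mutate_cds(
    cds: str,
    t: float,
    rate: float,
    kappa: float,
    omega: float,
    rng: np.random.Generator,
    table: int = 4,
) -> tuple[str, int, int]:
    """Codon-aware substitution with dN/dS enforced by acceptance sampling.

    Start and stop codons are held fixed; proposals creating a stop codon are
    rejected. Returns (sequence, synonymous count, nonsynonymous count).
    """
    ct = CodonTable.unambiguous_dna_by_id[table]
    aa = ct.forward_table
    stops = set(ct.stop_codons)
    n = len(cds)
    if n < 9 or t <= 0 or rate <= 0:
        return cds, 0, 0
    chars = list(cds)
    n_prop = rng.poisson(rate * t * (n - 6))
    p_ts = kappa / (kappa + 2.0)
    m = max(1.0, omega)
    p_syn, p_non = 1.0 / m, omega / m
    syn = non = 0
    for _ in range(n_prop):
        i = int(rng.integers(3, n - 3))  # body positions only
        base = chars[i]
        if rng.random() < p_ts:
            alt = _TRANSITION[base]
        else:
            pool = [b for b in BASES if b != base and b != _TRANSITION[base]]
            alt = pool[rng.integers(2)]
        c0 = 3 * (i // 3)
        old = "".join(chars[c0 : c0 + 3])
        new = old[: i - c0] + alt + old[i - c0 + 1 :]
        if new in stops:
            continue
        if aa[old] == aa[new]:
            if rng.random() < p_syn:
                chars[i] = alt
                syn += 1
        else:
            if rng.random() < p_non:
                chars[i] = alt
                non += 1
    return "".join(chars), syn, non


def _evolve_components(
    comps: list[_GeneComponent],
    gaps: list[str],
    t: float,
    plan: DivergencePlan,
    rng: np.random.Generator,
) -> tuple[list[_GeneComponent], list[str], dict]:
    out_comps = []
    stats = {"syn": {}, "nonsyn": {}, "ts": 0, "tv": 0}
    for comp in comps:
        comp = copy.deepcopy(comp)
        if comp.ftype in ("core_pcg", "orf"):
            comp.seq, s, ns = mutate_cds(
                comp.seq, t, plan.rate, plan.kappa, plan.omega(comp.name), rng, plan.table
            )
            stats["syn"][comp.name] = s
            stats["nonsyn"][comp.name] = ns
        else:
            comp.seq, ts, tv = mutate_noncoding(comp.seq, t, plan.rate, plan.kappa, rng)
            stats["ts"] += ts
            stats["tv"] += tv
        for intr in comp.introns:
            intr.seq, ts, tv = mutate_noncoding(intr.seq, t, plan.rate, plan.kappa, rng)
            stats["ts"] += ts
            stats["tv"] += tv
        out_comps.append(comp)
    out_gaps = []
    for gseq in gaps:
        gseq, ts, tv = mutate_noncoding(gseq, t, plan.rate, plan.kappa, rng)
        stats["ts"] += ts
        stats["tv"] += tv
        out_gaps.append(gseq)
    return out_comps, out_gaps, stats


def _decompose(genome: MitoGenome) -> tuple[list[_GeneComponent], list[str]]:
    """Split a genome into gene components (transcript orientation, introns
    attached) and the intergenic gap sequences between consecutive genes."""
    comps: list[_GeneComponent] = []
    genes = sorted(genome.genes(), key=lambda f: f.start)
    introns = [f for f in genome.features if f.ftype == "intron"]
    intronic_orfs = [f for f in genome.features if f.ftype == "intronic_orf"]
    for f in genes:
        cds = genome.extract(f)
        comp = _GeneComponent(f.name, f.ftype, f.strand, cds, f.anticodon)
        mine = sorted(
            (i for i in introns if i.host == f.name), key=lambda i: i.start,
            reverse=(f.strand == "-"),
        )
        for intr in mine:
            if f.strand == "+":
                off = sum(e - s + 1 for s, e in f.intervals if e < intr.intervals[0][0])
            else:
                off = sum(e - s + 1 for s, e in f.intervals if s > intr.intervals[-1][1])
            phase = off % 3
            codon = off // 3 if phase == 0 else off // 3 + 1
            orf_len = 0
            lo, hi = intr.intervals[0][0], intr.intervals[-1][1]
            for orf in intronic_orfs:
                os_, oe = orf.span()
                if lo <= os_ and oe <= hi:
                    orf_len = orf.length
                    break
            comp.introns.append(
                _IntronComponent(codon, phase, genome.extract(intr),
                                 intr.group_type or "I", orf_len)
            )
        comps.append(comp)
    gaps: list[str] = []
    for i, f in enumerate(genes):
        e1 = f.span()[1]
        if i + 1 < len(genes):
            s2 = genes[i + 1].span()[0]
            gaps.append(genome.seq[e1 : s2 - 1])
        else:  # wrap past the origin back to the first gene
            gaps.append(genome.seq[e1:] + genome.seq[: genes[0].span()[0] - 1])
    return comps, gaps


def _apply_moves(order: list[int], moves, comps: list[_GeneComponent]) -> list[int]:
    order = list(order)
    for start, seg_len, dest, invert in moves:
        seg = order[start : start + seg_len]
        rest = order[:start] + order[start + seg_len :]
        if invert:
            seg = seg[::-1]
            for idx in seg:
                comps[idx].strand = "-" if comps[idx].strand == "+" else "+"
        dest = min(dest, len(rest))
        order = rest[:dest] + seg + rest[dest:]
    return order


def evolve_set(
    ancestor: MitoGenome,
    tree: str,
    plan: DivergencePlan,
    seed: int,
) -> tuple[GenomeSet, dict]:
    """Evolve an ancestor genome down a newick tree into a genome set.

    Substitutions accumulate per branch (scaled by branch length); at each
    leaf the genome is reassembled applying the leaf's planned intron
    complement and gene-order rearrangements. The manifest records per-branch
    realized substitution counts, the generating tree, per-leaf gene orders,
    the intron presence/absence matrix, and the plan's per-gene dN/dS.
    """
    rng = np.random.default_rng(seed)
    root = parse_newick(tree)
    comps0, gaps0 = _decompose(ancestor)
    class_seqs: dict[tuple[str, int, int], str] = {}
    if plan.intron_classes:
        class_seqs = dict(plan.intron_classes)

    leaves: list[tuple[str, list[_GeneComponent], list[str]]] = []
    branch_stats: dict[str, dict] = {}
    counter = {"n": 0}

    def walk(node, comps, gaps):
        children, label, _bl = node
        if not children:
            leaves.append((label, comps, gaps))
            return
        for child in children:
            c_children, c_label, c_bl = child
            counter["n"] += 1
            name = c_label or f"node{counter['n']}"
            new_comps, new_gaps, stats = _evolve_components(comps, gaps, c_bl, plan, rng)
            branch_stats[f"{name}"] = stats | {"branch_length": c_bl}
            walk(child, new_comps, new_gaps)

    walk(root, comps0, gaps0)

    genomes = []
    manifests = {}
    orders = {}
    intron_matrix: dict[str, dict[str, list]] = {}
    for leaf_id, comps, gaps in sorted(leaves):
        comps = [copy.deepcopy(c) for c in comps]
        if plan.intron_presence is not None and leaf_id in plan.intron_presence:
            wanted = plan.intron_presence[leaf_id]
            hosts_managed = {h for h, _c, _p in class_seqs} if class_seqs else {
                h for h, _c, _p in wanted
            }
            for comp in comps:
                if comp.name in hosts_managed:
                    comp.introns = []
            for host, codon, phase in wanted:
                comp = next(c for c in comps if c.name == host)
                base = class_seqs.get((host, codon, phase))
                if base is None:
                    base = _random_seq(1200, np.full(4, 0.25), rng)
                    class_seqs[(host, codon, phase)] = base
                # light per-leaf divergence so class members stay similar
                leaf_seq, _, _ = mutate_noncoding(base, 1.0, 0.02, plan.kappa, rng)
                comp.introns.append(
                    _IntronComponent(codon, phase, leaf_seq, "I", plan.intron_orf_length)
                )
            intron_matrix[leaf_id] = {}
            for host in sorted({h for h, _c, _p in wanted} | hosts_managed):
                intron_matrix[leaf_id][host] = sorted(
                    [c, p] for h, c, p in wanted if h == host
                )
        order = list(range(len(comps)))
        if plan.rearrangements is not None and leaf_id in plan.rearrangements:
            order = _apply_moves(order, plan.rearrangements[leaf_id], comps)
        blocks: list[_Block] = []
        for slot, idx in enumerate(order):
            blocks.append(_Block("gap", seq=gaps[slot % len(gaps)]))
            blocks.append(_Block("gene", gene=comps[idx]))
        genome, manifest = _assemble(blocks, leaf_id)
        genomes.append(genome)
        manifests[leaf_id] = manifest
        orders[leaf_id] = [
            (comps[idx].name, 1 if comps[idx].strand == "+" else -1) for idx in order
        ]
    gset = GenomeSet(genomes)
    manifest = {
        "tree": tree,
        "plan": {
            "rate": plan.rate, "kappa": plan.kappa,
            "gene_dnds": dict(plan.gene_dnds), "default_dnds": plan.default_dnds,
        },
        "branch_stats": branch_stats,
        "leaf_orders": orders,
        "intron_matrix": intron_matrix,
        "leaves": manifests,
        "seed": seed,
    }
    return gset, manifest
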