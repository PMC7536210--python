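"""Domain types and GenBank/FASTA IO for annotated circular mitochondrial genomes.

A fungal mitogenome is modelled as a circular DNA molecule carrying typed,
stranded, possibly multi-interval features: the 15 conserved protein-coding
genes (14 energy-metabolism genes plus *rps3*), free-standing and intronic
ORFs, tRNAs, the two rRNAs, the RNase P RNA gene *rnpB*, and group-I/II
introns. Coordinates are 1-based inclusive throughout, matching the GenBank
convention; circular arithmetic is modulo genome length and an interval that
crosses the replication origin is stored as two explicit segments with an
``origin_spanning`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CORE_PCGS",
    "Feature",
    "MitoGenome",
    "GenomeSet",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "spliced_cds",
    "rotate",
    "reverse_complement",
]

#: The 15 core protein-coding genes conserved across Basidiomycete mitogenomes.
CORE_PCGS = frozenset(
    {
        "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
    }
)

#: Default gene-name alias table (lowercased key -> canonical label).
DEFAULT_ALIASES = {
    "cytb": "cob",
    "cob": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad4l": "nad4L",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "rrnl": "rnl", "rrns": "rns",
    "rnl": "rnl", "rns": "rns",
    "rrn_l": "rnl", "rrn_s": "rns",
    "rnpb": "rnpB",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_TYPES = (
    "core_pcg", "orf", "intronic_orf", "trna", "rrna", "rnpB", "intron",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_gene_name(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map a raw annotation label to its canonical gene name (case-insensitive)."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    key = name.strip().lower()
    if key in table:
        return table[key]
    for core in CORE_PCGS:
        if key == core.lower():
            return core
    return name.strip()


@dataclass
class Feature:
    """A typed, stranded genome feature.

    ``intervals`` is an ordered list of 1-based inclusive ``(start, end)``
    segments with ``start <= end``; a multi-segment feature is either an
    intron-containing gene (segments = exons) or an origin-spanning feature
    after rotation (flagged).
    """

    name: str
    ftype: str
    strand: str
    intervals: list[tuple[int, int]]
    host: str | None = None
    anticodon: str | None = None
    group_type: str | None = None
    origin_spanning: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if s > e:
                raise ValueError(
                    f"feature {self.name!r}: interval {s}..{e} has start > end; "
                    "origin-spanning features must be stored as split segments"
                )

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def positions(self, genome_length: int | None = None) -> list[int]:
        """All 1-based positions covered by the feature's segments."""
        out: list[int] = []
        for s, e in self.intervals:
            out.extend(range(s, e + 1))
        return out

    def span(self) -> tuple[int, int]:
        """Overall extent (min start, max end) ignoring origin wrap."""
        return (min(s for s, _ in self.intervals), max(e for _, e in self.intervals))


@dataclass
class MitoGenome:
    """A circular mitochondrial genome: sequence plus ordered features."""

    id: str
    seq: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
        for f in self.features:
            for s, e in f.intervals:
                if not (1 <= s <= e <= len(self.seq)):
                    raise ValueError(
                        f"feature {f.name!r} interval {s}..{e} outside "
                        f"sequence of length {len(self.seq)}"
                    )
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.seq)

    def get(self, name: str, ftype: str | None = None) -> Feature:
        for f in self.features:
            if f.name == name and (ftype is None or f.ftype == ftype):
                return f
        raise KeyError(f"no feature named {name!r} in genome {self.id}")

    def by_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self.features if f.ftype in ftypes]

    def genes(self) -> list[Feature]:
        """Top-level features: everything except introns and intronic ORFs."""
        return [f for f in self.features if f.ftype not in ("intron", "intronic_orf")]

    def extract(self, feature: Feature) -> str:
        """Segment-concatenated, strand-applied sequence of a feature."""
        raw = "".join(self.seq[s - 1 : e] for s, e in feature.intervals)
        return reverse_complement(raw) if feature.strand == "-" else raw


@dataclass
class GenomeSet:
    """An ordered collection of genomes for multi-species comparison."""

    genomes: list[MitoGenome]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(ids) != len(set(ids)):
            raise ValueError("genome ids must be unique")
        for g in self.genomes:
            self.labels.setdefault(g.id, g.id)

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, gid: str) -> MitoGenome:
        for g in self.genomes:
            if g.id == gid:
                return g
        raise KeyError(gid)

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.genomes]


# ---------------------------------------------------------------------------
# GenBank reading


def _location_intervals(location) -> list[tuple[int, int]]:
    parts = location.parts if hasattr(location, "parts") else [location]
    ivals = [(int(p.start) + 1, int(p.end)) for p in parts]
    return sorted(ivals)


def _classify(sf: SeqFeature, name: str) -> str | None:
    """Apply the feature-typing rules; None means the key is skipped."""
    key = sf.type
    if key == "tRNA":
        return "trna"
    if key == "rRNA":
        return "rrna"
    if key == "intron":
        return "intron"
    if key in ("ncRNA", "misc_RNA"):
        return "rnpB" if name == "rnpB" else None
    if key == "CDS":
        if name in CORE_PCGS:
            return "core_pcg"
        return "orf"
    return None


def read_genbank(path, aliases: dict[str, str] | None = None) -> MitoGenome:
    """Parse an annotated GenBank flat file into a :class:`MitoGenome`.

    Feature typing follows the canonical rules: names in the 15-gene core set
    become ``core_pcg``; ``trn*`` -> tRNA; ``rnl``/``rns``/``rrn*`` -> rRNA;
    ``rnpB`` -> rnpB; other CDSs -> ``orf``; ORFs lying inside an intron span
    become ``intronic_orf`` with the intron's host recorded. Gaps between
    consecutive segments of a ``join()`` CDS become intron features unless an
    explicit intron annotation already covers them.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) <= {"N"}:
        raise ValueError(f"{path}: GenBank record has no usable sequence")

    features: list[Feature] = []
    explicit_intron_spans: list[tuple[int, int]] = []

    def add(feat: Feature) -> None:
        for s, e in feat.intervals:
            if not (1 <= s <= e <= len(seq)):
                raise ValueError(
                    f"{path}: feature {feat.name!r} interval {s}..{e} lies "
                    f"outside the {len(seq)} nt sequence"
                )
        features.append(feat)

    for sf in record.features:
        if sf.type in ("source", "gene", "misc_feature"):
            continue
        quals = sf.qualifiers
        raw_name = (
            quals.get("gene", [None])[0]
            or quals.get("locus_tag", [None])[0]
            or quals.get("product", [None])[0]
            or sf.type
        )
        name = canonical_gene_name(str(raw_name), aliases)
        ftype = _classify(sf, name)
        if ftype is None:
            warnings.warn(f"{path}: skipping unsupported feature key {sf.type!r}")
            continue
        strand = "-" if sf.location.strand == -1 else "+"
        ivals = _location_intervals(sf.location)
        anticodon = quals.get("anticodon", [None])[0]
        host = quals.get("host_gene", [None])[0] or quals.get("note", [None])[0]
        if ftype == "intron":
            gt = quals.get("intron_type", quals.get("group", ["unknown"]))[0]
            group_type = gt if gt in ("I", "II") else "unknown"
            host_gene = quals.get("gene", [None])[0] or host
            add(
                Feature(
                    name=name if name != "intron" else f"intron@{ivals[0][0]}",
                    ftype="intron",
                    strand=strand,
                    intervals=ivals,
                    host=canonical_gene_name(str(host_gene), aliases) if host_gene else None,
                    group_type=group_type,
                )
            )
            explicit_intron_spans.extend(ivals)
            continue
        add(
            Feature(
                name=name,
                ftype=ftype,
                strand=strand,
                intervals=ivals,
                anticodon=anticodon,
            )
        )

    # Derive introns from join() gaps of multi-segment CDSs and rRNAs.
    derived: list[Feature] = []
    for f in features:
        if f.ftype in ("core_pcg", "orf", "rrna") and len(f.intervals) > 1:
            ordinal = 0
            for (s1, e1), (s2, _e2) in zip(f.intervals, f.intervals[1:]):
                gap = (e1 + 1, s2 - 1)
                if gap[0] > gap[1]:
                    continue
                if any(s <= gap[0] and gap[1] <= e for s, e in explicit_intron_spans):
                    continue
                ordinal += 1
                derived.append(
                    Feature(
                        name=f"{f.name}-i{ordinal}",
                        ftype="intron",
                        strand=f.strand,
                        intervals=[gap],
                        host=f.name,
                        group_type="unknown",
                    )
                )
    features.extend(derived)

    # Reclassify ORFs nested inside intron spans as intronic ORFs.
    intron_spans = [
        (iv[0], iv[1], intron.host)
        for intron in features
        if intron.ftype == "intron"
        for iv in intron.intervals
    ]
    for f in features:
        if f.ftype == "orf":
            lo, hi = f.span()
            for s, e, host in intron_spans:
                if s <= lo and hi <= e:
                    f.ftype = "intronic_orf"
                    f.host = host
                    break

    circular = "circular" in str(record.annotations.get("topology", "circular"))
    return MitoGenome(id=record.id or record.name, seq=seq, features=features, circular=circular)


# ---------------------------------------------------------------------------
# Writers

_GB_KEYS = {
    "core_pcg": "CDS", "orf": "CDS", "intronic_orf": "CDS",
    "trna": "tRNA", "rrna": "rRNA", "rnpB": "ncRNA", "intron": "intron",
}


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a MitoGenome back to GenBank flat format (round-trip safe)."""
    record = SeqRecord(
        Seq(genome.seq),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        if f.ftype == "intron" and f.host:
            # introns derived from join() gaps are re-derivable; keep explicit
            # only those without a multi-segment host CDS in the record
            host = next(
                (
                    g
                    for g in genome.features
                    if g.name == f.host and g.ftype in ("core_pcg", "orf", "rrna")
                ),
                None,
            )
            if host is not None and len(host.intervals) > 1:
                continue
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s - 1, e, strand=strand) for s, e in f.intervals]
        if strand == -1:
            locs = locs[::-1] if len(locs) > 1 else locs
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        if f.ftype == "intron":
            quals["intron_type"] = [f.group_type or "unknown"]
            if f.host:
                quals["gene"] = [f.host]
                quals["note"] = [f.name]
        record.features.append(SeqFeature(loc, type=_GB_KEYS[f.ftype], qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


def read_fasta(path) -> MitoGenome:
    record = SeqIO.read(str(path), "fasta")
    return MitoGenome(id=record.id, seq=str(record.seq))


def write_fasta(genome: MitoGenome, path) -> None:
    SeqIO.write(SeqRecord(Seq(genome.seq), id=genome.id, description=""), str(path), "fasta")


# ---------------------------------------------------------------------------
# Operations


def spliced_cds(genome: MitoGenome, gene: str) -> str:
    """Concatenated exon sequence of a protein-coding gene, strand applied.

    Exon segments are concatenated in transcription order (for a minus-strand
    gene this is the reverse complement of the genomic-order concatenation).
    Emits a warning when a core gene's spliced length is not divisible by 3.
    """
    feat = None
    for f in genome.features:
        if f.name == gene and f.ftype in ("core_pcg", "orf", "intronic_orf"):
            feat = f
            break
    if feat is None:
        raise KeyError(f"no protein-coding gene {gene!r} in genome {genome.id}")
    cds = genome.extract(feat)
    if feat.ftype == "core_pcg" and len(cds) % 3:
        warnings.warn(
            f"{genome.id}:{gene}: spliced CDS length {len(cds)} not divisible by 3"
        )
    return cds


def rotate(genome: MitoGenome, offset: int) -> MitoGenome:
    """Rotate the circular genome so old position ``offset+1`` becomes position 1.

    All feature coordinates are renormalised modulo the length; a segment that
    crosses the new origin is split into two segments and the feature flagged
    ``origin_spanning``. All downstream composition, partition and gene-order
    statistics are invariant under this operation.
    """
    if not genome.circular:
        raise ValueError("rotate() requires a circular genome")
    n = genome.length
    offset %= n
    if offset == 0:
        return replace(genome, features=[replace(f) for f in genome.features])
    new_seq = genome.seq[offset:] + genome.seq[:offset]
    new_feats = []
    for f in genome.features:
        ivals: list[tuple[int, int]] = []
        spanning = f.origin_spanning
        for s, e in f.intervals:
            ns = (s - 1 - offset) % n + 1
            ne = (e - 1 - offset) % n + 1
            if ns <= ne:
                ivals.append((ns, ne))
            else:  # wraps the new origin
                ivals.append((ns, n))
                ivals.append((1, ne))
                spanning = True
        # re-merge segments that were split by the *old* origin and are now contiguous
        merged: list[tuple[int, int]] = []
        for iv in ivals:
            if merged and merged[-1][1] + 1 == iv[0]:
                merged[-1] = (merged[-1][0], iv[1])
            else:
                merged.append(iv)
        spanning = spanning and any(e == n for _, e in merged) and any(s == 1 for s, _ in merged)
        new_feats.append(replace(f, intervals=merged, origin_spanning=spanning))
    return MitoGenome(id=genome.id, seq=new_seq, features=new_feats, circular=True)
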