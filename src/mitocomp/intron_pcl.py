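"""Group-I intron extraction and position-class (Pcl) clustering.

Mobile group-I introns of fungal mitochondrial *cox1* and *cob* genes are
treated as orthologous when they interrupt the host coding sequence at the
same position. Each intron's insertion point is expressed as a (codon index,
phase) pair on the host CDS — phase 0 means the intron falls between two
codons, phases 1/2 inside a codon — then projected through a protein
alignment of the host onto a reference species' coordinate system, so that
the class key is comparable across species despite sequence divergence.
Introns sharing the exact projected (codon, phase) key form one Pcl; classes
are named from a user-supplied reference table when available (inheriting the
published letter / Roman-numeral schemes) and otherwise from coordinates
(e.g. ``cox1-c121p0``), with unmatched classes labelled ``UN-1, UN-2, ...``
in site order when a table is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from ._align import align_pair
from .genome_model import GenomeSet

__all__ = [
    "IntronRecord",
    "Pcl",
    "PclMatrix",
    "extract_introns",
    "map_insertion_site",
    "cluster_pcls",
    "load_reference_table",
]


@dataclass
class IntronRecord:
    species: str
    host: str
    ordinal: int  # 1-based, transcription order
    interval: tuple[int, int]
    sequence: str
    group_type: str = "unknown"
    cds_offset: int | None = None  # nt of spliced CDS preceding the intron
    insertion_site: int | None = None  # reference codon index (1-based)
    phase: int | None = None
    projected_through_gap: bool = False
    excluded: bool = False


@dataclass
class Pcl:
    host: str
    insertion_site: int
    phase: int
    name: str
    members: list[IntronRecord] = field(default_factory=list)

    @property
    def prevalence(self) -> int:
        return len({m.species for m in self.members})


@dataclass
class PclMatrix:
    host: str
    matrix: pd.DataFrame  # species x Pcl name, bool
    pcls: list[Pcl]
    rare: list[str]  # Pcl names present in <= 2 species
    common: list[str]  # present in > half the species

    @property
    def per_species_counts(self) -> pd.Series:
        return self.matrix.sum(axis=1)


def extract_introns(genomes: GenomeSet, host: str) -> list[IntronRecord]:
    """One record per intron of ``host`` per genome, in transcription order.

    Genomes lacking the host gene, or with an intronless copy, contribute no
    records (a note is emitted for missing genes). The intron's spliced-CDS
    offset (number of coding nucleotides transcribed before the intron) is
    computed from the exon structure, strand-aware.
    """
    records: list[IntronRecord] = []
    for g in genomes:
        try:
            gene = next(
                f for f in g.features
                if f.name == host and f.ftype in ("core_pcg", "orf", "rrna")
            )
        except StopIteration:
            warnings.warn(f"{g.id}: host gene {host!r} absent; skipped")
            continue
        introns = [f for f in g.features if f.ftype == "intron" and f.host == host]
        if not introns:
            continue
        # transcription order: genomic order for +, reversed for -
        introns.sort(key=lambda f: f.start, reverse=(gene.strand == "-"))
        for ordinal, intron in enumerate(introns, start=1):
            # coding nt upstream of the intron in transcription order
            if gene.strand == "+":
                offset = sum(
                    e - s + 1
                    for s, e in gene.intervals
                    if e < intron.intervals[0][0]
                )
            else:
                offset = sum(
                    e - s + 1
                    for s, e in gene.intervals
                    if s > intron.intervals[-1][1]
                )
            records.append(
                IntronRecord(
                    species=g.id,
                    host=host,
                    ordinal=ordinal,
                    interval=(intron.intervals[0][0], intron.intervals[-1][1]),
                    sequence=g.extract(intron),
                    group_type=intron.group_type or "unknown",
                    cds_offset=offset,
                )
            )
    return records


def offset_to_codon(offset: int) -> tuple[int, int]:
    """Spliced-CDS nucleotide offset -> (codon index, phase).

    Phase 0: the intron sits after a complete codon (offset = 3k -> codon k);
    phase 1/2: inside codon ``k+1`` after 1 or 2 of its nucleotides.
    """
    phase = offset % 3
    codon = offset // 3 if phase == 0 else offset // 3 + 1
    return codon, phase


def _translate(cds: str, table: int = 4) -> str:
    ct = CodonTable.unambiguous_dna_by_id[table]
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        c = cds[i : i + 3]
        if c in ct.stop_codons:
            out.append("*")
        else:
            out.append(ct.forward_table.get(c, "X"))
    return "".join(out).rstrip("*")


def map_insertion_site(
    record: IntronRecord,
    host_cds: str,
    reference_protein: str,
    table: int = 4,
) -> IntronRecord:
    """Project an intron's host-coordinate insertion point onto the reference.

    The host CDS is translated (code 4 by default) and globally aligned to
    the reference protein; the host codon index is mapped through the
    alignment to the reference codon index. A site landing in a reference
    gap is assigned the nearest preceding reference column and flagged. An
    untranslatable host CDS marks the record excluded.
    """
    codon, phase = offset_to_codon(record.cds_offset)
    host_prot = _translate(host_cds, table)
    if "*" in host_prot or not host_prot:
        record.excluded = True
        return record
    if host_prot == reference_protein:
        record.insertion_site, record.phase = codon, phase
        return record
    a_host, a_ref = align_pair(host_prot, reference_protein, kind="protein")
    host_idx = ref_idx = 0
    ref_site = 0
    in_gap = False
    for rh, rr in zip(a_host, a_ref):
        if rh != "-":
            host_idx += 1
        if rr != "-":
            ref_idx += 1
        if host_idx == codon and rh != "-":
            if rr == "-":
                ref_site = ref_idx  # nearest preceding reference column
                in_gap = True
            else:
                ref_site = ref_idx
            break
    else:
        ref_site = ref_idx
        in_gap = True
    record.insertion_site = ref_site
    record.phase = phase
    record.projected_through_gap = in_gap
    return record


def load_reference_table(path) -> dict[tuple[str, int, int], str]:
    """Read a TSV of (host, codon, phase, name) rows into a naming table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    table: dict[tuple[str, int, int], str] = {}
    for _, row in df.iterrows():
        key = (str(row["host"]), int(row["codon"]), int(row["phase"]))
        if key in table and table[key] != str(row["name"]):
            raise ValueError(f"conflicting reference names for site {key}")
        table[key] = str(row["name"])
    return table


def cluster_pcls(
    introns: list[IntronRecord],
    species: list[str] | None = None,
    reference_table: dict[tuple[str, int, int], str] | None = None,
    similarity_check: bool = False,
) -> PclMatrix:
    """Group mapped introns into position classes and build the Pcl matrix.

    Clustering is a pure grouping by the exact (reference codon, phase) key
    and is deterministic and independent of input order. With a reference
    table, classes matching a (host, codon, phase) entry inherit its name and
    the rest become ``UN-1, UN-2, ...`` in site order; without a table names
    are synthesised from coordinates. Rarity: a class in <= 2 species;
    commonness: in more than half of the species.
    """
    usable = [r for r in introns if not r.excluded and r.insertion_site is not None]
    if not usable:
        raise ValueError("no mapped introns to cluster")
    hosts = {r.host for r in usable}
    if len(hosts) > 1:
        raise ValueError(f"cluster_pcls expects a single host gene, got {sorted(hosts)}")
    host = hosts.pop()
    if species is None:
        species = sorted({r.species for r in usable})
    groups: dict[tuple[int, int], list[IntronRecord]] = {}
    for r in sorted(usable, key=lambda r: (r.insertion_site, r.phase, r.species, r.ordinal)):
        groups.setdefault((r.insertion_site, r.phase), []).append(r)

    pcls: list[Pcl] = []
    un_counter = 0
    for (site, phase) in sorted(groups):
        if reference_table is not None:
            name = reference_table.get((host, site, phase))
            if name is None:
                un_counter += 1
                name = f"UN-{un_counter}"
        else:
            name = f"{host}-c{site}p{phase}"
        pcls.append(Pcl(host=host, insertion_site=site, phase=phase, name=name, members=groups[(site, phase)]))

    matrix = pd.DataFrame(False, index=list(species), columns=[p.name for p in pcls])
    for p in pcls:
        for m in p.members:
            matrix.loc[m.species, p.name] = True

    if similarity_check:
        for p in pcls:
            idents = []
            seqs = [m.sequence for m in p.members]
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    a, b = align_pair(seqs[i], seqs[j], kind="dna")
                    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
                    idents.append(100.0 * same / max(len(a), 1))
            p.within_identity = sum(idents) / len(idents) if idents else float("nan")  # type: ignore[attr-defined]

    half = len(species) / 2
    rare = [p.name for p in pcls if p.prevalence <= 2]
    common = [p.name for p in pcls if p.prevalence > half]
    return PclMatrix(host=host, matrix=matrix, pcls=pcls, rare=rare, common=common)
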