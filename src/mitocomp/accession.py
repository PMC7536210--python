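"""Replication checks against published mitogenome records.

Runs the full single-genome and multi-genome analysis stack on user-supplied
GenBank records and reports the quantities published for the *Taiwanofungus
camphoratus* mitogenome and its Polyporales comparison set: genome length,
GC content, tRNA count, region proportions, rnpB length, gene overlaps,
longest intergenic spacer, and the cross-species intron census. The records
themselves are not distributed with the package; download them once from
GenBank (the focal accession is MH745717) and point these functions at the
local files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition import composition_summary, detect_overlaps, partition_regions
from .genome_model import GenomeSet, MitoGenome, read_genbank
from .intron_pcl import extract_introns

#: Published values for the focal genome, used for side-by-side reporting.
PUBLISHED = {
    "length": 114_922,
    "gc_percent": 26.01,
    "trna_count": 27,
    "rrna_count": 2,
    "rnpB_length": 329,
    "intergenic_total": 41_887,
    "percent_intergenic": 36.45,
    "percent_intronic": 29.94,
    "percent_coding": 27.56,
    "percent_rna": 6.05,
    "n_overlaps": 1,
    "overlap_pair": ("nad4L", "nad5"),
    "overlap_nt": 1,
    "longest_spacer": 2903,
    "longest_spacer_flanks": ("trnW", "orf292"),
    "set_total_introns": 271,
    "cox1_intron_share_percent": 47.97,
}


@dataclass
class ReplicationReport:
    computed: dict = field(default_factory=dict)
    published: dict = field(default_factory=lambda: dict(PUBLISHED))

    def rows(self):
        for key, pub in self.published.items():
            yield key, self.computed.get(key), pub


def replication_report(
    focal_path, comparison_paths: list | None = None
) -> ReplicationReport:
    """Recompute the published quantities from local GenBank records.

    ``focal_path`` is the focal genome record; ``comparison_paths`` (optional)
    are the remaining genomes of the 12-species comparison set, enabling the
    cross-species intron totals.
    """
    genome = read_genbank(focal_path)
    rep = ReplicationReport()
    c = rep.computed
    comp = composition_summary(genome.seq)
    part = partition_regions(genome)
    overlaps = detect_overlaps(genome)
    c["length"] = genome.length
    c["gc_percent"] = round(comp.gc_percent, 2)
    c["trna_count"] = len(genome.by_type("trna"))
    c["rrna_count"] = len(genome.by_type("rrna"))
    try:
        c["rnpB_length"] = genome.get("rnpB").length
    except KeyError:
        c["rnpB_length"] = None
    c["intergenic_total"] = part.totals["intergenic"]
    c["percent_intergenic"] = round(part.percents["intergenic"], 2)
    c["percent_intronic"] = round(part.percents["intronic"], 2)
    c["percent_coding"] = round(part.percents["coding"], 2)
    c["percent_rna"] = round(part.percents["rna"], 2)
    c["n_overlaps"] = len(overlaps)
    if overlaps:
        top = max(overlaps, key=lambda o: o.overlap)
        c["overlap_pair"] = tuple(sorted((top.gene_a, top.gene_b)))
        c["overlap_nt"] = top.overlap
    longest = part.longest_spacer
    if longest:
        c["longest_spacer"] = longest[2]
        c["longest_spacer_flanks"] = (longest[0], longest[1])
    if comparison_paths:
        genomes = GenomeSet([genome] + [read_genbank(p) for p in comparison_paths])
        total = 0
        by_host: dict[str, int] = {}
        for g in genomes:
            for f in g.features:
                if f.ftype == "intron":
                    total += 1
                    by_host[f.host or "?"] = by_host.get(f.host or "?", 0) + 1
        c["set_total_introns"] = total
        if total:
            c["cox1_intron_share_percent"] = round(
                100.0 * by_host.get("cox1", 0) / total, 2
            )
    return rep
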