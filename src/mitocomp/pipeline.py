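"""End-to-end orchestration: run every analysis stage and write a report bundle.

Mirrors the structure of a comparative mitogenomics results section: a
genome-summary table, composition/partition report, codon usage tables,
repeat tables, intron Pcl matrices, an evolution-rate (K2P/Ka/Ks) table, a
gene-order distance matrix and a newick tree, plus a machine-readable run
log with thresholds and seeds. Multi-species stages are skipped with a note
when only one genome is supplied; a failing stage is recorded and the
independent stages continue.
"""

from __future__ import annotations

import json
import logging
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import codon_usage, composition_summary, detect_overlaps, partition_regions
from .gene_order import extract_order, order_distance
from .genome_model import GenomeSet, read_genbank
from .intron_pcl import cluster_pcls, extract_introns, load_reference_table, map_insertion_site
from .molevol import per_gene_means, selection_screen
from .phylo_lite import bootstrap_support, build_supermatrix
from .genome_model import spliced_cds
from .intron_pcl import _translate

log = logging.getLogger("mitocomp")


@dataclass
class RunConfig:
    inputs: list
    out_dir: str = "mitocomp_out"
    min_repeat_len: int = 28
    min_repeat_identity: float = 74.0
    tandem_min_total: int = 24
    pcl_hosts: tuple[str, ...] = ("cox1", "cob")
    pcl_reference_table: str | None = None
    genes: list[str] | None = None
    collapse_trna: bool = False
    bootstrap: int = 100
    seed: int = 1
    stages: tuple[str, ...] = (
        "summary", "composition", "repeats", "pcl", "evolve", "geneorder", "phylo",
    )


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns {stage: status} and writes files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = GenomeSet([read_genbank(p) for p in config.inputs])
    multi = len(genomes) >= 2
    status: dict[str, str] = {}

    def stage(name):
        return name in config.stages

    if stage("summary"):
        try:
            rows = []
            for g in genomes:
                comp = composition_summary(g.seq)
                rows.append(
                    {
                        "id": g.id, "length": g.length,
                        "gc_percent": round(comp.gc_percent, 2),
                        "at_skew": round(comp.at_skew, 4),
                        "gc_skew": round(comp.gc_skew, 4),
                        "core_pcgs": len(g.by_type("core_pcg")),
                        "orfs": len(g.by_type("orf")),
                        "intronic_orfs": len(g.by_type("intronic_orf")),
                        "trnas": len(g.by_type("trna")),
                        "rrnas": len(g.by_type("rrna")),
                        "introns": len(g.by_type("intron")),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "genome_summary.tsv", sep="\t", index=False)
            status["summary"] = "ok"
        except Exception as exc:  # noqa: BLE001 - independent stages continue
            status["summary"] = f"failed: {exc}"
            log.error(traceback.format_exc())

    if stage("composition"):
        try:
            rows = []
            spacer_rows = []
            overlap_rows = []
            for g in genomes:
                part = partition_regions(g)
                row = {"id": g.id}
                row.update({f"{k}_nt": v for k, v in part.totals.items()})
                row.update({f"{k}_percent": round(v, 2) for k, v in part.percents.items()})
                rows.append(row)
                for left, right, ln in part.spacers:
                    spacer_rows.append({"id": g.id, "left": left, "right": right, "length": ln})
                for o in detect_overlaps(g):
                    overlap_rows.append(
                        {"id": g.id, "gene_a": o.gene_a, "gene_b": o.gene_b, "overlap_nt": o.overlap}
                    )
            pd.DataFrame(rows).to_csv(out / "region_partition.tsv", sep="\t", index=False)
            pd.DataFrame(spacer_rows).to_csv(out / "intergenic_spacers.tsv", sep="\t", index=False)
            pd.DataFrame(overlap_rows).to_csv(out / "gene_overlaps.tsv", sep="\t", index=False)
            table = codon_usage(genomes)
            pd.DataFrame(
                sorted(table.counts.items()), columns=["codon", "count"]
            ).assign(rscu=lambda df: df["codon"].map(table.rscu).round(3)).to_csv(
                out / "codon_usage.tsv", sep="\t", index=False
            )
            status["composition"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["composition"] = f"failed: {exc}"
            log.error(traceback.format_exc())

    if stage("repeats"):
        try:
            from .repeats import find_interspersed, find_tandem, repeat_fraction

            rows, trows = [], []
            for g in genomes:
                hits = find_interspersed(
                    g, min_len=config.min_repeat_len, min_identity=config.min_repeat_identity
                )
                for h in hits:
                    rows.append(
                        {
                            "id": g.id, "a_start": h.a[0], "a_end": h.a[1],
                            "b_start": h.b[0], "b_end": h.b[1], "length": h.length,
                            "identity": round(h.identity, 2), "orientation": h.orientation,
                        }
                    )
                for t in find_tandem(g, min_total=config.tandem_min_total):
                    trows.append(
                        {
                            "id": g.id, "start": t.start, "end": t.end,
                            "unit_length": t.unit_length, "copies": t.copy_number,
                            "consensus": t.consensus,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "interspersed_repeats.tsv", sep="\t", index=False)
            pd.DataFrame(trows).to_csv(out / "tandem_repeats.tsv", sep="\t", index=False)
            status["repeats"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["repeats"] = f"failed: {exc}"
            log.error(traceback.format_exc())

    if stage("pcl"):
        if not multi:
            status["pcl"] = "skipped: needs >= 2 genomes"
        else:
            try:
                ref_table = (
                    load_reference_table(config.pcl_reference_table)
                    if config.pcl_reference_table
                    else None
                )
                for host in config.pcl_hosts:
                    records = extract_introns(genomes, host)
                    if not records:
                        continue
                    ref_genome = genomes.genomes[0]
                    try:
                        ref_prot = _translate(spliced_cds(ref_genome, host))
                    except KeyError:
                        continue
                    for r in records:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            host_cds = spliced_cds(genomes[r.species], host)
                        map_insertion_site(r, host_cds, ref_prot)
                    pm = cluster_pcls(records, species=genomes.ids, reference_table=ref_table)
                    pm.matrix.astype(int).to_csv(out / f"pcl_matrix_{host}.tsv", sep="\t")
                status["pcl"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["pcl"] = f"failed: {exc}"
                log.error(traceback.format_exc())

    if stage("evolve"):
        if not multi:
            status["evolve"] = "skipped: needs >= 2 genomes"
        else:
            try:
                table = selection_screen(genomes, genes=config.genes)
                table.to_csv(out / "pairwise_evolution.tsv", sep="\t", index=False)
                per_gene_means(table).to_csv(out / "per_gene_means.tsv", sep="\t")
                status["evolve"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["evolve"] = f"failed: {exc}"
                log.error(traceback.format_exc())

    if stage("geneorder"):
        if not multi:
            status["geneorder"] = "skipped: needs >= 2 genomes"
        else:
            try:
                orders = [
                    extract_order(g, include_trna=not config.collapse_trna) for g in genomes
                ]
                with open(out / "gene_orders.txt", "w") as fh:
                    for o in orders:
                        fh.write(f"{o.species}\t{o.as_text()}\n")
                ids = [o.species for o in orders]
                mat = pd.DataFrame(0, index=ids, columns=ids)
                for i in range(len(orders)):
                    for j in range(i + 1, len(orders)):
                        d = order_distance(orders[i], orders[j])
                        mat.iloc[i, j] = mat.iloc[j, i] = d.breakpoints
                mat.to_csv(out / "breakpoint_matrix.tsv", sep="\t")
                status["geneorder"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["geneorder"] = f"failed: {exc}"
                log.error(traceback.format_exc())

    if stage("phylo"):
        if not multi or len(genomes) < 4:
            status["phylo"] = "skipped: needs >= 4 genomes"
        else:
            try:
                sm = build_supermatrix(genomes, genes=config.genes)
                sm.to_fasta(out / "supermatrix.fasta")
                sm.to_phylip(out / "supermatrix.phy")
                sm.write_partitions(out / "partitions.txt")
                tree, support = bootstrap_support(sm, config.bootstrap, config.seed)
                (out / "nj_tree.nwk").write_text(tree.newick(support) + "\n")
                status["phylo"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["phylo"] = f"failed: {exc}"
                log.error(traceback.format_exc())

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_repeat_len": config.min_repeat_len,
            "min_repeat_identity": config.min_repeat_identity,
            "tandem_min_total": config.tandem_min_total,
            "bootstrap": config.bootstrap,
        },
        "inputs": [str(p) for p in config.inputs],
        "stages": status,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return status
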