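"""Intron extraction, insertion-site mapping and Pcl clustering."""

import warnings

import numpy as np
import pytest

from mitocomp.genome_model import Feature, GenomeSet, MitoGenome, spliced_cds
from mitocomp.intron_pcl import (
    _translate,
    cluster_pcls,
    extract_introns,
    load_reference_table,
    map_insertion_site,
    offset_to_codon,
)
from mitocomp.synthetic import DivergencePlan, evolve_set, generate_genome, mutate_cds
from conftest import small_spec


def test_offset_to_codon_arithmetic():
    assert offset_to_codon(363) == (121, 0)
    assert offset_to_codon(364) == (122, 1)
    assert offset_to_codon(365) == (122, 2)
    assert offset_to_codon(3) == (1, 0)


def test_extract_introns_planted_ordinals(planted):
    genome, manifest = planted
    gset = GenomeSet([genome])
    records = extract_introns(gset, "cox1")
    planted_introns = sorted(
        (i for i in manifest["introns"] if i["host"] == "cox1"),
        key=lambda i: i["ordinal"],
    )
    assert len(records) == len(planted_introns) == 3
    for rec, plant in zip(sorted(records, key=lambda r: r.ordinal), planted_introns):
        assert rec.ordinal == plant["ordinal"]
        assert list(rec.interval) == plant["interval"]
        assert offset_to_codon(rec.cds_offset) == (plant["codon"], plant["phase"])


def test_intronless_gene_yields_empty():
    genome = MitoGenome(
        id="x", seq="ATG" + "AAA" * 100 + "TAA" + "C" * 100,
        features=[Feature("cob", "core_pcg", "+", [(1, 306)])],
    )
    assert extract_introns(GenomeSet([genome]), "cob") == []


def test_single_annotated_intron_yields_one_record():
    seq = "ATG" + "AAA" * 40 + "G" * 50 + "AAA" * 40 + "TAA" + "C" * 100
    gene = Feature("cob", "core_pcg", "+", [(1, 123), (174, 296)])
    intron = Feature("cob-i1", "intron", "+", [(124, 173)], host="cob", group_type="I")
    genome = MitoGenome(id="y", seq=seq, features=[gene, intron])
    records = extract_introns(GenomeSet([genome]), "cob")
    assert len(records) == 1
    assert records[0].cds_offset == 123


def test_map_insertion_site_with_divergence(planted):
    genome, manifest = planted
    gset = GenomeSet([genome])
    rng = np.random.default_rng(8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cds = spliced_cds(genome, "cox1")
    # reference = a ~5%-diverged relative of the host protein
    diverged = mutate_cds(cds, 1.0, 0.1, 1.0, 0.3, rng)[0]
    ref_prot = _translate(diverged)
    for rec in extract_introns(gset, "cox1"):
        plant = next(
            i for i in manifest["introns"]
            if i["host"] == "cox1" and i["ordinal"] == rec.ordinal
        )
        map_insertion_site(rec, cds, ref_prot)
        assert (rec.insertion_site, rec.phase) == (plant["codon"], plant["phase"])


def test_cluster_two_species_same_site():
    from mitocomp.intron_pcl import IntronRecord

    recs = []
    for sp in ("A", "B"):
        recs.append(
            IntronRecord(
                species=sp, host="cox1", ordinal=1, interval=(10, 60),
                sequence="ACGT" * 20, cds_offset=363,
                insertion_site=121, phase=0,
            )
        )
    pm = cluster_pcls(recs)
    assert pm.matrix.shape == (2, 1)
    assert pm.pcls[0].prevalence == 2
    assert pm.pcls[0].name == "cox1-c121p0"


def test_cluster_deterministic_under_input_order():
    from mitocomp.intron_pcl import IntronRecord

    rng = np.random.default_rng(2)
    recs = []
    for sp in "ABCDEF":
        for site in rng.choice([50, 121, 200, 250], size=2, replace=False):
            recs.append(
                IntronRecord(
                    species=sp, host="cox1", ordinal=1, interval=(1, 10),
                    sequence="ACGTACGT", cds_offset=int(site) * 3,
                    insertion_site=int(site), phase=0,
                )
            )
    pm1 = cluster_pcls(recs)
    pm2 = cluster_pcls(list(reversed(recs)))
    assert pm1.matrix.equals(pm2.matrix)
    assert sum(p.prevalence for p in pm1.pcls) == len(recs)


def test_rarity_and_commonness_flags():
    from mitocomp.intron_pcl import IntronRecord

    species = [f"S{i}" for i in range(12)]
    recs = []
    for sp in species[:10]:  # common class, 10 of 12
        recs.append(IntronRecord(sp, "cox1", 1, (1, 5), "ACGTA", cds_offset=300,
                                 insertion_site=100, phase=0))
    recs.append(IntronRecord("S0", "cox1", 2, (9, 13), "ACGTA", cds_offset=600,
                             insertion_site=200, phase=0))  # rare, 1 species
    pm = cluster_pcls(recs, species=species)
    assert "cox1-c100p0" in pm.common
    assert "cox1-c200p0" in pm.rare


def test_reference_table_naming_and_un_labels(tmp_path):
    from mitocomp.intron_pcl import IntronRecord

    table_path = tmp_path / "pcls.tsv"
    table_path.write_text("host\tcodon\tphase\tname\ncox1\t100\t0\tP\n")
    table = load_reference_table(table_path)
    recs = [
        IntronRecord("A", "cox1", 1, (1, 5), "ACGTA", cds_offset=300,
                     insertion_site=100, phase=0),
        IntronRecord("A", "cox1", 2, (9, 13), "ACGTA", cds_offset=600,
                     insertion_site=200, phase=0),
    ]
    pm = cluster_pcls(recs, reference_table=table)
    assert set(pm.matrix.columns) == {"P", "UN-1"}

    conflict = tmp_path / "bad.tsv"
    conflict.write_text("host\tcodon\tphase\tname\ncox1\t100\t0\tP\ncox1\t100\t0\tQ\n")
    with pytest.raises(ValueError, match="conflict"):
        load_reference_table(conflict)


def test_evolved_set_recovers_planted_presence():
    anc, _ = generate_genome(small_spec(seed=31))
    classes = {("cox1", 44, 0): None, ("cox1", 121, 0): None, ("cox1", 300, 1): None}
    rng = np.random.default_rng(6)
    classes = {
        k: "".join(np.array(list("ACGT"))[rng.integers(0, 4, 350)]) for k in classes
    }
    presence = {
        "A": [("cox1", 44, 0), ("cox1", 121, 0)],
        "B": [("cox1", 121, 0), ("cox1", 300, 1)],
        "C": [("cox1", 44, 0)],
    }
    plan = DivergencePlan(rate=0.02, intron_classes=classes, intron_presence=presence)
    gset, man = evolve_set(anc, "((A:1,B:1):0.5,C:1)r;", plan, seed=3)
    records = extract_introns(gset, "cox1")
    ref_prot = _translate(spliced_cds(gset.genomes[0], "cox1"))
    for r in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            map_insertion_site(r, spliced_cds(gset[r.species], "cox1"), ref_prot)
    pm = cluster_pcls(records, species=gset.ids)
    for sp, wanted in presence.items():
        got = {
            (pm.pcls[i].insertion_site, pm.pcls[i].phase)
            for i, present in enumerate(pm.matrix.loc[sp]) if present
        }
        assert got == {(c, p) for _h, c, p in wanted}
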