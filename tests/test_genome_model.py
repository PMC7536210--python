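"""Genome model: GenBank parsing, splicing, rotation, round trips."""

import warnings

import pytest

from mitocomp.composition import composition_summary, partition_regions
from mitocomp.genome_model import (
    Feature,
    MitoGenome,
    read_genbank,
    reverse_complement,
    rotate,
    spliced_cds,
    write_genbank,
)

MINIMAL_GB = """\
LOCUS       testmito                1000 bp    DNA     circular     23-SEP-2026
DEFINITION  minimal two-gene fixture.
FEATURES             Location/Qualifiers
     source          1..1000
     CDS             101..250
                     /gene="atp9"
     tRNA            complement(301..372)
                     /gene="trnA"
                     /anticodon="tgc"
ORIGIN
{origin}
//
"""

JOIN_GB = """\
LOCUS       joinmito                1000 bp    DNA     circular     23-SEP-2026
DEFINITION  join-location fixture.
FEATURES             Location/Qualifiers
     source          1..1000
     CDS             join(100..300,501..800)
                     /gene="cox2"
ORIGIN
{origin}
//
"""


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        spaced = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {spaced}")
    return "\n".join(lines)


@pytest.fixture
def write_gb(tmp_path):
    def _write(template, seq, name="fix.gb"):
        path = tmp_path / name
        path.write_text(template.format(origin=_origin_block(seq.lower())))
        return path

    return _write


def test_minimal_two_gene_fixture(write_gb):
    seq = "ACGT" * 250
    g = read_genbank(write_gb(MINIMAL_GB, seq))
    assert g.length == 1000
    assert len(g.features) == 2
    atp9 = g.get("atp9")
    assert atp9.ftype == "core_pcg" and atp9.strand == "+"
    assert atp9.intervals == [(101, 250)]
    trna = g.get("trnA")
    assert trna.ftype == "trna" and trna.strand == "-"


def test_join_cds_yields_intron_with_host(write_gb):
    seq = "ACGT" * 250
    g = read_genbank(write_gb(JOIN_GB, seq))
    cox2 = g.get("cox2")
    assert cox2.ftype == "core_pcg"
    assert cox2.intervals == [(100, 300), (501, 800)]
    introns = g.by_type("intron")
    assert len(introns) == 1
    assert introns[0].intervals == [(301, 500)]
    assert introns[0].host == "cox2"


def test_spliced_cds_strands():
    seq = "A" * 50 + "ATGAAATTTTAA" + "A" * 38  # gene at 51..62
    plus = MitoGenome(
        id="p", seq=seq,
        features=[Feature("g", "orf", "+", [(51, 62)])],
    )
    assert spliced_cds(plus, "g") == "ATGAAATTTTAA"
    minus = MitoGenome(
        id="m", seq=seq,
        features=[Feature("g", "orf", "-", [(40, 45), (51, 62)])],
    )
    expected = reverse_complement(seq[39:45] + seq[50:62])
    assert spliced_cds(minus, "g") == expected


def test_spliced_cds_recovers_planted_sequence(planted):
    genome, manifest = planted
    # reconstruct the planted CDS from the recorded exon intervals
    feat = genome.get("cox1")
    raw = "".join(genome.seq[s - 1 : e] for s, e in feat.intervals)
    assert spliced_cds(genome, "cox1") == (
        raw if feat.strand == "+" else reverse_complement(raw)
    )
    with pytest.raises(KeyError):
        spliced_cds(genome, "not_a_gene")


def test_rotate_identity_and_inverse(planted):
    genome, _ = planted
    same = rotate(genome, 0)
    assert same.seq == genome.seq
    k = 7321
    back = rotate(rotate(genome, k), genome.length - k)
    assert back.seq == genome.seq
    orig = sorted((f.name, f.ftype, tuple(f.intervals)) for f in genome.features)
    round_ = sorted((f.name, f.ftype, tuple(f.intervals)) for f in back.features)
    assert orig == round_


def test_rotate_preserves_statistics(planted):
    genome, _ = planted
    rot = rotate(genome, 13_017)
    c0, c1 = composition_summary(genome.seq), composition_summary(rot.seq)
    assert c0.gc_percent == pytest.approx(c1.gc_percent)
    assert c0.at_skew == pytest.approx(c1.at_skew)
    assert partition_regions(genome).totals == partition_regions(rot).totals


def test_feature_length_sum_matches_manifest(planted):
    genome, manifest = planted
    by_name = {
        (f["name"], f["ftype"]): sum(e - s + 1 for s, e in f["intervals"])
        for f in manifest["features"]
    }
    for f in genome.features:
        assert f.length == by_name[(f.name, f.ftype)]


def test_genbank_round_trip(planted, tmp_path):
    genome, _ = planted
    path = tmp_path / "rt.gb"
    write_genbank(genome, path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reread = read_genbank(path)
    assert reread.seq == genome.seq
    key = lambda f: (f.name, f.ftype, f.strand, tuple(f.intervals), f.host)
    assert sorted(map(key, reread.features)) == sorted(map(key, genome.features))


def test_feature_outside_sequence_is_hard_error():
    with pytest.raises(ValueError, match="outside"):
        MitoGenome(id="x", seq="ACGT" * 10, features=[Feature("g", "orf", "+", [(30, 50)])])


def test_missing_sequence_is_hard_error(tmp_path):
    path = tmp_path / "noseq.gb"
    path.write_text(
        "LOCUS       x  4 bp DNA circular 23-SEP-2026\n"
        "FEATURES             Location/Qualifiers\n"
        "     source          1..4\nORIGIN\n        1 nnnn\n//\n"
    )
    with pytest.raises(ValueError, match="sequence"):
        read_genbank(path)
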