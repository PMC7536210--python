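"""Generator contracts: determinism, packing, targets, evolution."""

import warnings

import numpy as np
import pytest

from mitocomp.composition import composition_summary
from mitocomp.genome_model import read_genbank, write_genbank
from mitocomp.synthetic import (
    DivergencePlan,
    GenePlan,
    SyntheticSpec,
    default_spec,
    evolve_set,
    generate_genome,
    mutate_noncoding,
    parse_newick,
)
from conftest import small_spec


def test_same_seed_byte_identical(tmp_path):
    spec = small_spec(seed=9)
    g1, m1 = generate_genome(spec)
    g2, m2 = generate_genome(small_spec(seed=9))
    assert g1.seq == g2.seq
    assert m1 == m2
    p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
    write_genbank(g1, p1)
    write_genbank(g2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_feature_counts_match_spec(planted):
    genome, _ = planted
    spec = small_spec()
    by_type = lambda t: len(genome.by_type(t))
    assert by_type("core_pcg") == sum(1 for g in spec.genes if g.ftype == "core_pcg")
    assert by_type("trna") == sum(1 for g in spec.genes if g.ftype == "trna")
    assert by_type("rrna") == 2
    assert by_type("intron") == len(spec.introns)
    assert genome.length == spec.length


def test_default_spec_realises_study_architecture():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g, man = generate_genome(default_spec(seed=2))
    assert len(g.by_type("core_pcg")) == 15
    assert len(g.by_type("trna")) == 27
    assert len(g.by_type("rrna")) == 2
    assert len(g.by_type("intron")) == 24
    comp = composition_summary(g.seq)
    assert comp.gc_percent == pytest.approx(26.0, abs=0.5)
    assert comp.at_skew < 0 and comp.gc_skew > 0


def test_generated_genbank_reparses_to_manifest(planted, tmp_path):
    genome, manifest = planted
    path = tmp_path / "g.gb"
    write_genbank(genome, path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reread = read_genbank(path)
    mf = {
        (f["name"], f["ftype"], f["strand"], tuple(tuple(iv) for iv in f["intervals"]))
        for f in manifest["features"]
    }
    got = {
        (f.name, f.ftype, f.strand, tuple(f.intervals)) for f in reread.features
    }
    assert got == mf


def test_infeasible_packing_raises_before_output():
    spec = SyntheticSpec(
        length=1000,
        genes=[GenePlan("cox1", "core_pcg", 1608, "+")],
        seed=1,
    )
    with pytest.raises(ValueError, match="fit"):
        generate_genome(spec)


def test_seed_mandatory():
    spec = small_spec()
    spec.seed = None
    with pytest.raises(ValueError, match="seed"):
        generate_genome(spec)


def test_zero_rate_descendants_identical():
    anc, _ = generate_genome(small_spec(seed=13))
    plan = DivergencePlan(rate=0.0)
    gset, man = evolve_set(anc, "(A:1,B:1,C:1)r;", plan, seed=4)
    seqs = {g.id: g.seq for g in gset}
    assert seqs["A"] == seqs["B"] == seqs["C"]
    # same gene content as ancestor (coordinates may rotate with layout)
    anc_genes = sorted((f.name, f.ftype, f.length) for f in anc.features)
    for g in gset:
        assert sorted((f.name, f.ftype, f.length) for f in g.features) == anc_genes


def test_branch_stats_recorded():
    anc, _ = generate_genome(small_spec(seed=17))
    plan = DivergencePlan(rate=0.05)
    gset, man = evolve_set(anc, "(A:1,B:2)r;", plan, seed=4)
    sa, sb = man["branch_stats"]["A"], man["branch_stats"]["B"]
    assert sa["ts"] + sa["tv"] > 0
    # branch twice as long accumulates roughly twice the changes
    assert (sb["ts"] + sb["tv"]) > (sa["ts"] + sa["tv"])


def test_mutate_noncoding_rate_calibration():
    rng = np.random.default_rng(20)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20000)])
    out, ts, tv = mutate_noncoding(seq, 1.0, 0.05, 4.0, rng)
    observed = sum(1 for a, b in zip(seq, out) if a != b)
    expected = 20000 * (1 - np.exp(-0.05))
    assert observed == pytest.approx(expected, rel=0.15)
    # HKY-style kappa: expected transition:transversion count ratio is kappa/2
    assert ts / max(tv, 1) == pytest.approx(2.0, rel=0.35)


def test_parse_newick_topology_and_lengths():
    tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3)root;")
    children, label, _ = tree
    assert label == "root"
    (ab, c) = children
    assert c[1] == "C" and c[2] == pytest.approx(0.3)
    names = sorted(ch[1] for ch in ab[0])
    assert names == ["A", "B"]
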