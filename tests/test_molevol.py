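"""K2P and NG86 against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq

from mitocomp.genome_model import GenomeSet
from mitocomp.molevol import codon_align, k2p, ng86_kaks, selection_screen
from mitocomp.synthetic import DivergencePlan, evolve_set, generate_genome, mutate_cds
from conftest import small_spec

# ---------------------------------------------------------------------------
# Independent oracles (naive, per-pair, no caching)

_CT4 = CodonTable.unambiguous_dna_by_id[4]


def _aa(codon):
    if codon in _CT4.stop_codons:
        return "*"
    return str(Seq(codon).translate(table=4))


def oracle_k2p(s1, s2):
    pairs = [(a, b) for a, b in zip(s1, s2) if a in "ACGT" and b in "ACGT"]
    n = len(pairs)
    ts = sum(1 for a, b in pairs if a != b and {a, b} in ({"A", "G"}, {"C", "T"}))
    tv = sum(1 for a, b in pairs if a != b and {a, b} not in ({"A", "G"}, {"C", "T"}))
    P, Q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def oracle_syn_sites(codon):
    """Fraction-of-3 synonymous sites; changes to stops are nonsynonymous."""
    syn = 0
    for i in range(3):
        for alt in "ACGT":
            if alt == codon[i]:
                continue
            neighbor = codon[:i] + alt + codon[i + 1 :]
            if _aa(neighbor) != "*" and _aa(neighbor) == _aa(codon):
                syn += 1
    return syn / 3.0


def oracle_path_counts(c1, c2):
    """Pathway-averaged (syn, nonsyn) steps, stop-passing pathways excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid = []
    for order in itertools.permutations(diff):
        cur, steps, ok = c1, [], True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            valid.append(steps)
    pool = valid
    if not pool:  # all routes blocked: average over every route
        pool = []
        for order in itertools.permutations(diff):
            cur, steps = c1, []
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            pool.append(steps)
    sd = nd = 0.0
    for steps in pool:
        for a, b in steps:
            if _aa(a) != "*" and _aa(a) == _aa(b):
                sd += 1
            else:
                nd += 1
    return sd / len(pool), nd / len(pool)


def oracle_ng86(cds1, cds2):
    ncod = len(cds1) // 3
    s1 = s2 = sd = nd = 0.0
    for i in range(ncod):
        c1, c2 = cds1[3 * i : 3 * i + 3], cds2[3 * i : 3 * i + 3]
        s1 += oracle_syn_sites(c1)
        s2 += oracle_syn_sites(c2)
        d = oracle_path_counts(c1, c2)
        sd += d[0]
        nd += d[1]
    S = (s1 + s2) / 2
    N = 3 * ncod - S
    jc = lambda p: 0.0 if p == 0 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(nd / N), jc(sd / S)


def _random_cds_pair(rng, ncod=50):
    sense = [c for c in _CT4.forward_table if c not in _CT4.stop_codons]
    c1 = [sense[i] for i in rng.integers(0, len(sense), ncod)]
    c2 = list(c1)
    for i in rng.integers(0, ncod, max(3, ncod // 5)):  # sprinkle differences
        c2[i] = sense[rng.integers(0, len(sense))]
    return "".join(c1), "".join(c2)


# ---------------------------------------------------------------------------


def test_k2p_trivial_and_closed_form():
    assert k2p("ACGTACGT", "ACGTACGT").distance == pytest.approx(0.0)
    s1 = "A" * 100
    s2 = "G" * 10 + "C" * 5 + "A" * 85  # P = 0.1, Q = 0.05
    expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
    assert k2p(s1, s2).distance == pytest.approx(0.17018, abs=1e-5)
    assert k2p(s1, s2).distance == pytest.approx(expected)


def test_k2p_symmetry_and_saturation():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        b = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        ra, rb = k2p(a, b), k2p(b, a)
        if ra.saturated:
            assert rb.saturated
        else:
            assert ra.distance == pytest.approx(rb.distance)
    sat = k2p("A" * 10, "G" * 10)  # P = 1 saturates the log argument
    assert sat.saturated and math.isnan(sat.distance)
    with pytest.raises(ValueError):
        k2p("---", "---")


def test_k2p_matches_per_site_oracle():
    rng = np.random.default_rng(17)
    for _ in range(30):
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        b = list(a)
        for i in rng.integers(0, 200, 20):
            b[i] = "ACGT"[rng.integers(0, 4)]
        b = "".join(b)
        assert k2p(a, b).distance == pytest.approx(oracle_k2p(a, b), abs=1e-12)


def test_ng86_identical_and_single_synonymous_change():
    res = ng86_kaks("TTT" * 30, "TTT" * 30)
    assert res.ka == 0.0 and res.ks == 0.0
    res = ng86_kaks("TTT" * 30, "TTC" + "TTT" * 29)
    assert res.ka == 0.0
    # TTT has exactly one synonymous neighbour (TTC) -> 1/3 site per codon
    assert res.s_sites == pytest.approx(10.0)
    assert res.ks == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3))


def test_ng86_matches_bruteforce_oracle_on_100_random_pairs():
    rng = np.random.default_rng(23)
    for _ in range(100):
        c1, c2 = _random_cds_pair(rng)
        res = ng86_kaks(c1, c2)
        oka, oks = oracle_ng86(c1, c2)
        assert res.ka == pytest.approx(oka, abs=1e-10)
        assert res.ks == pytest.approx(oks, abs=1e-10)


def test_ng86_internal_stop_is_error():
    with pytest.raises(ValueError, match="codon 2"):
        ng86_kaks("ATGTAAAAA", "ATGAAAAAA")


def test_ng86_gap_codons_excluded_pairwise():
    full = ng86_kaks("TTTAAA", "TTCAAA")
    gapped = ng86_kaks("TTTAAA---", "TTCAAAGGG")
    assert gapped.codons == 2
    assert gapped.sd == full.sd


def test_kaks_bias_shrinks_with_length():
    rng = np.random.default_rng(4)
    errs = {}
    for ncod in (100, 1000):
        e = []
        for _ in range(30):
            anc = mutate_cds("ATG" + "GCT" * (ncod - 2) + "TAA", 0, 0, 1, 1, rng)[0]
            sense = [c for c in _CT4.forward_table if c not in _CT4.stop_codons]
            anc = "ATG" + "".join(sense[i] for i in rng.integers(0, len(sense), ncod - 2)) + "TAA"
            a = mutate_cds(anc, 1.0, 0.2, 1.0, 0.5, rng)[0]
            b = mutate_cds(anc, 1.0, 0.2, 1.0, 0.5, rng)[0]
            res = ng86_kaks(a[:-3], b[:-3])
            e.append(res.ratio - 0.5)
        errs[ncod] = abs(np.mean(e))
    assert errs[1000] <= errs[100] + 0.05


def test_selection_screen_identical_genomes():
    genome, _ = generate_genome(small_spec(seed=77))
    twin, _ = generate_genome(small_spec(seed=77))
    twin.id = "twin"
    table = selection_screen(GenomeSet([genome, twin]))
    assert not table.empty
    assert (table["k2p"] == 0).all()
    assert (table["ka"] == 0).all()
    assert not table["positive_selection"].any()


def test_selection_screen_flags_only_planted_gene():
    anc, _ = generate_genome(small_spec(seed=55))
    plan = DivergencePlan(rate=0.12, kappa=1.0, default_dnds=0.05, gene_dnds={"rps3": 2.0})
    gset, _ = evolve_set(anc, "((A:1,B:1):0.3,(C:1,D:1):0.3)r;", plan, seed=9)
    table = selection_screen(gset)
    flagged = set(table.loc[table["positive_selection"], "gene"])
    assert flagged == {"rps3"}
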