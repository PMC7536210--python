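"""Supermatrix construction and neighbor-joining correctness."""

import numpy as np
import pytest

from mitocomp.genome_model import Feature, GenomeSet, MitoGenome
from mitocomp.phylo_lite import (
    Supermatrix,
    bootstrap_support,
    build_supermatrix,
    k2p_matrix,
    nj_tree,
)


def _toy_set():
    genomes = []
    for sp, mut in (("A", "A"), ("B", "C"), ("C", "G")):
        g1 = "ATGAAATTT" + "TAA"  # 12 nt
        g2 = "ATG" + mut * 3 + "TAA"  # 9 nt
        seq = g1 + "TT" + g2 + "TTTT"
        genomes.append(
            MitoGenome(
                id=sp, seq=seq,
                features=[
                    Feature("atp9", "core_pcg", "+", [(1, 12)]),
                    Feature("nad3", "core_pcg", "+", [(15, 23)]),
                ],
            )
        )
    return GenomeSet(genomes)


def test_supermatrix_widths_and_partitions():
    sm = build_supermatrix(_toy_set(), genes=["atp9", "nad3"])
    assert sm.width == 21
    assert sm.partitions == [("atp9", 1, 12), ("nad3", 13, 21)]
    assert set(sm.species) == {"A", "B", "C"}


def test_supermatrix_width_matches_manifest():
    from mitocomp.synthetic import generate_genome
    from conftest import small_spec

    g, man = generate_genome(small_spec(seed=71))
    twin, _ = generate_genome(small_spec(seed=71))
    twin.id = "twin"
    genes = ["cox1", "cob", "rnl"]
    sm = build_supermatrix(GenomeSet([g, twin]), genes=genes)
    expected = sum(
        sum(e - s + 1 for s, e in f["intervals"])
        for f in man["features"]
        if f["name"] in genes and f["ftype"] in ("core_pcg", "rrna")
    )
    assert sm.width == expected


def test_nj_three_taxa_closed_form():
    ids = ["A", "B", "C"]
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
    tree = nj_tree(ids, d)
    lengths = {c.label: bl for c, bl in tree.children}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(3.0)
    assert lengths["C"] == pytest.approx(5.0)


def test_nj_recovers_additive_four_taxon_tree():
    ids = ["A", "B", "C", "D"]
    # tree ((A:1,B:2):1,C:3,D:4) pendant to internal node chain
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(ids, d)
    assert tree.splits() == {
        frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
    }
    assert "A:1.000000" in tree.newick() and "B:2.000000" in tree.newick()


def _random_tree_matrix(rng, n_taxa):
    """Random additive matrix via random binary tree with edge lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start with each taxon a cluster; record distance of every leaf to the
    # cluster root; on merge, add edges
    clusters = [({l}, {l: 0.0}) for l in labels]
    dist = {}
    splits = set()
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (sa, da), (sb, db) = clusters[i], clusters[j]
        bla, blb = rng.uniform(0.05, 1.0, size=2)
        for la, va in da.items():
            for lb, vb in db.items():
                dist[frozenset((la, lb))] = va + bla + vb + blb
        if 1 < len(sa) < n_taxa - 1:
            splits.add(frozenset({frozenset(sa), frozenset(set(labels) - sa)}))
        if 1 < len(sb) < n_taxa - 1:
            splits.add(frozenset({frozenset(sb), frozenset(set(labels) - sb)}))
        merged = {l: v + bla for l, v in da.items()} | {l: v + blb for l, v in db.items()}
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((sa | sb, merged))
    n = len(labels)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, m, splits


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(99)
    for rep in range(50):
        n_taxa = int(rng.integers(6, 11))
        ids, m, true_splits = _random_tree_matrix(rng, n_taxa)
        tree = nj_tree(ids, m)
        assert tree.splits() == true_splits, f"replicate {rep} failed"


def test_nj_invariant_to_taxon_input_order():
    rng = np.random.default_rng(5)
    ids, m, _ = _random_tree_matrix(rng, 7)
    t1 = nj_tree(ids, m)
    perm = list(rng.permutation(len(ids)))
    ids2 = [ids[p] for p in perm]
    m2 = m[np.ix_(perm, perm)]
    t2 = nj_tree(ids2, m2)
    assert t1.splits() == t2.splits()
    assert t1.newick() == t2.newick()


def test_nj_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(31)
    ids, m, _ = _random_tree_matrix(rng, 8)
    ours = nj_tree(ids, m).splits()
    sk_tree = sk_nj(DistanceMatrix(m, ids))
    theirs = set()
    all_l = frozenset(ids)
    for node in sk_tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(ids) - 1:
            theirs.add(frozenset({side, all_l - side}))
    assert ours == theirs


def test_nonfinite_distance_is_error():
    d = np.array([[0, np.nan], [np.nan, 0]])
    with pytest.raises(ValueError, match="non-finite"):
        nj_tree(["A", "B"], d)


def test_bootstrap_support_on_clean_signal():
    rng = np.random.default_rng(7)
    base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])

    def mutate(seq, n):
        chars = list(seq)
        for i in rng.choice(len(chars), size=n, replace=False):
            chars[i] = "ACGT"[(("ACGT".index(chars[i])) + 1) % 4]
        return "".join(chars)

    inner = mutate(base, 200)
    rows = {
        "A": mutate(base, 20), "B": mutate(base, 20),
        "C": mutate(inner, 20), "D": mutate(inner, 20),
    }
    sm = Supermatrix(species=list(rows), rows=rows, partitions=[("all", 1, 2000)])
    tree, support = bootstrap_support(sm, n_replicates=50, seed=1)
    ab = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
    assert support[ab] >= 90.0
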