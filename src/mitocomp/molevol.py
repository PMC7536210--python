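"""Pairwise substitution distances and selection screening for core genes.

Implements the Kimura two-parameter (K2P) distance

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over pairwise-kept
sites, and the Nei-Gojobori (1986) method for synonymous (Ks) and
nonsynonymous (Ka) substitution rates: per-codon synonymous site fractions
averaged over the two sequences, pathway-averaged difference counts for
multi-hit codons (pathways passing through a stop codon are excluded; weights
uniform over the surviving pathways), and the Jukes-Cantor correction
``d = -3/4 * ln(1 - 4p/3)`` applied to the proportions pS and pN.

The genetic code defaults to translation table 4 (mold mitochondrial,
TGA = Trp), the code under which fungal mitochondrial protein genes are
translated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable

from .genome_model import CORE_PCGS, GenomeSet, spliced_cds
from ._align import align_pair

__all__ = [
    "K2PResult",
    "KaKsResult",
    "k2p",
    "ng86_kaks",
    "codon_align",
    "selection_screen",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


@dataclass
class K2PResult:
    distance: float  # nan when saturated
    p: float  # transition proportion
    q: float  # transversion proportion
    sites: int
    saturated: bool = False

    def __float__(self) -> float:
        return self.distance


def k2p(seq1: str, seq2: str) -> K2PResult:
    """Kimura two-parameter distance with pairwise deletion of gap/N columns."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    ts = tv = n = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no retained sites after pairwise deletion")
    p, q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return K2PResult(float("nan"), p, q, n, saturated=True)
    d = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return K2PResult(d, p, q, n)


# ---------------------------------------------------------------------------
# NG86


@lru_cache(maxsize=4)
def _code_tables(table: int):
    ct = CodonTable.unambiguous_dna_by_id[table]
    aa = dict(ct.forward_table)
    stops = set(ct.stop_codons)
    return aa, stops


@lru_cache(maxsize=4)
def _site_table(table: int) -> dict[str, float]:
    """Synonymous sites per codon: each codon contributes 3 sites total.

    At each position the synonymous fraction is (# synonymous single-base
    changes)/3; a change creating a stop codon counts as nonsynonymous.
    """
    aa, stops = _code_tables(table)
    out: dict[str, float] = {}
    for codon in aa:
        syn = 0
        for i, base in enumerate(codon):
            for alt in BASES:
                if alt == base:
                    continue
                neighbor = codon[:i] + alt + codon[i + 1 :]
                if neighbor not in stops and aa[neighbor] == aa[codon]:
                    syn += 1
        out[codon] = syn / 3.0
    return out


@lru_cache(maxsize=4)
def _diff_table(table: int) -> dict[tuple[str, str], tuple[float, float]]:
    """(codon1, codon2) -> pathway-averaged (synonymous, nonsynonymous) counts."""
    aa, stops = _code_tables(table)

    def step_class(c1: str, c2: str) -> str:
        return "syn" if aa[c1] == aa[c2] else "non"

    out: dict[tuple[str, str], tuple[float, float]] = {}
    codons = list(aa)
    for c1 in codons:
        for c2 in codons:
            if c1 == c2:
                out[(c1, c2)] = (0.0, 0.0)
                continue
            diff = [i for i in range(3) if c1[i] != c2[i]]
            paths = []
            for order in itertools.permutations(diff):
                cur = c1
                steps = []
                ok = True
                for i in order:
                    nxt = cur[:i] + c2[i] + cur[i + 1 :]
                    if nxt in stops and nxt != c2:
                        ok = False
                        break
                    steps.append((cur, nxt))
                    cur = nxt
                if ok:
                    paths.append(steps)
            if not paths:  # every route blocked by a stop: fall back to all routes
                for order in itertools.permutations(diff):
                    cur = c1
                    steps = []
                    for i in order:
                        nxt = cur[:i] + c2[i] + cur[i + 1 :]
                        steps.append((cur, nxt))
                        cur = nxt
                    paths.append(steps)
                sd = nd = 0.0
                for steps in paths:
                    for a, b in steps:
                        if a in stops or b in stops or aa.get(a) != aa.get(b):
                            nd += 1
                        else:
                            sd += 1
                w = len(paths)
                out[(c1, c2)] = (sd / w, nd / w)
                continue
            sd = nd = 0.0
            for steps in paths:
                for a, b in steps:
                    if step_class(a, b) == "syn":
                        sd += 1
                    else:
                        nd += 1
            w = len(paths)
            out[(c1, c2)] = (sd / w, nd / w)
    return out


@dataclass
class KaKsResult:
    ka: float
    ks: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    codons: int

    @property
    def ratio(self) -> float:
        """Ka/Ks; +inf (flagged by ``ks == 0``) when Ks is zero but Ka > 0."""
        if math.isnan(self.ka) or math.isnan(self.ks):
            return float("nan")
        if self.ks == 0.0:
            return float("inf") if self.ka > 0 else float("nan")
        return self.ka / self.ks


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds1: str, cds2: str, table: int = 4) -> KaKsResult:
    """Nei-Gojobori (1986) Ka and Ks for a codon-aligned CDS pair.

    Codons containing gaps or ambiguity codes are excluded pairwise. An
    internal stop codon in either sequence raises with the offending codon
    position (terminal stops should be stripped by the caller).
    """
    if len(cds1) != len(cds2):
        raise ValueError("CDSs must be codon-aligned to equal length")
    if len(cds1) % 3:
        raise ValueError("aligned length not divisible by 3")
    aa, stops = _code_tables(table)
    sites = _site_table(table)
    diffs = _diff_table(table)
    cds1, cds2 = cds1.upper(), cds2.upper()
    s1 = s2 = sd = nd = 0.0
    kept = 0
    ncod = len(cds1) // 3
    for idx in range(ncod):
        c1 = cds1[3 * idx : 3 * idx + 3]
        c2 = cds2[3 * idx : 3 * idx + 3]
        if not (set(c1) <= set(BASES) and set(c2) <= set(BASES)):
            continue
        for tag, c in (("first", c1), ("second", c2)):
            if c in stops:
                raise ValueError(
                    f"internal stop codon {c} at codon {idx + 1} of {tag} sequence"
                )
        kept += 1
        s1 += sites[c1]
        s2 += sites[c2]
        d = diffs[(c1, c2)]
        sd += d[0]
        nd += d[1]
    if kept == 0:
        raise ValueError("no analyzable codons after pairwise deletion")
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * kept - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        ka=_jc(pn), ks=_jc(ps), s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd, codons=kept
    )


def codon_align(cds1: str, cds2: str, table: int = 4) -> tuple[str, str]:
    """Codon-aware alignment: protein-align then back-thread the nucleotides.

    Equal-length CDS pairs encoding gapless-alignable proteins pass through
    unchanged; otherwise the proteins are globally aligned and each protein
    gap becomes a codon gap ('---') in the nucleotide alignment.
    """
    aa, stops = _code_tables(table)

    def translate(cds: str) -> str:
        prot = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            c = cds[i : i + 3]
            if c in stops:
                prot.append("*")
            else:
                prot.append(aa.get(c, "X"))
        return "".join(prot)

    if len(cds1) % 3 or len(cds2) % 3:
        raise ValueError("CDS lengths must be divisible by 3")
    p1, p2 = translate(cds1), translate(cds2)
    if len(p1) == len(p2):
        return cds1, cds2
    a1, a2 = align_pair(p1.replace("*", "X"), p2.replace("*", "X"), kind="protein")
    out1, out2 = [], []
    i = j = 0
    for r1, r2 in zip(a1, a2):
        if r1 == "-":
            out1.append("---")
        else:
            out1.append(cds1[3 * i : 3 * i + 3])
            i += 1
        if r2 == "-":
            out2.append("---")
        else:
            out2.append(cds2[3 * j : 3 * j + 3])
            j += 1
    return "".join(out1), "".join(out2)


def _strip_terminal_stop(cds: str, table: int) -> str:
    _aa, stops = _code_tables(table)
    if len(cds) >= 3 and cds[-3:] in stops:
        return cds[:-3]
    return cds


def selection_screen(
    genomes: GenomeSet,
    genes: list[str] | None = None,
    table: int = 4,
) -> pd.DataFrame:
    """All pairwise K2P / Ka / Ks per core gene across a genome set.

    Returns a tidy DataFrame with one row per (gene, species pair) holding
    ``k2p``, ``ka``, ``ks``, ``ka_ks`` and a ``positive_selection`` flag
    (Ka/Ks > 1). Genes absent from a genome are skipped for the pairs
    involving it; a gene present in fewer than two genomes is skipped with a
    warning.
    """
    if genes is None:
        genes = sorted(CORE_PCGS)
    rows = []
    for gene in genes:
        carriers = []
        for g in genomes:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cds = _strip_terminal_stop(spliced_cds(g, gene), table)
                carriers.append((g.id, cds))
            except KeyError:
                continue
        if len(carriers) < 2:
            warnings.warn(f"gene {gene}: present in fewer than 2 genomes; skipped")
            continue
        for (id1, cds1), (id2, cds2) in itertools.combinations(carriers, 2):
            ac1, ac2 = codon_align(cds1, cds2, table)
            dist = k2p(ac1, ac2)
            try:
                kk = ng86_kaks(ac1, ac2, table)
                ka, ks, ratio = kk.ka, kk.ks, kk.ratio
            except ValueError:
                ka = ks = ratio = float("nan")
            rows.append(
                {
                    "gene": gene,
                    "sp1": id1,
                    "sp2": id2,
                    "k2p": dist.distance,
                    "ka": ka,
                    "ks": ks,
                    "ka_ks": ratio,
                    "positive_selection": bool(ratio > 1.0) if not math.isnan(ratio) else False,
                }
            )
    return pd.DataFrame(rows)


def per_gene_means(pairwise: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean K2P, Ka and Ks over all species pairs (ignoring NaNs)."""
    return (
        pairwise.groupby("gene")[["k2p", "ka", "ks"]]
        .mean()
        .sort_values("k2p", ascending=False)
    )
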