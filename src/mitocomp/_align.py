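"""Shared pairwise-alignment helpers (Biopython PairwiseAligner wrappers)."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=1)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


@lru_cache(maxsize=1)
def dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -2
    aligner.mode = "global"
    return aligner


def align_pair(a: str, b: str, kind: str = "protein") -> tuple[str, str]:
    """Globally align two sequences; returns the gapped row strings."""
    aligner = protein_aligner() if kind == "protein" else dna_aligner()
    # X (unknown residue) is absent from BLOSUM62's alphabet subset handling
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])
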