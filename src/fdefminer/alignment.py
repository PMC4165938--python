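"""Pairwise peptide alignment (affine gaps) shared by scanning and classification.

Thin wrapper over biotite's optimal-alignment kernel.  A gap of length L
costs ``gap_open + (L - 1) * gap_extend``.  Unknown residues are mapped to
the substitution matrix's X wildcard.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .errors import ValidationError

_MATRICES = {"BLOSUM62": balign.SubstitutionMatrix.std_protein_matrix()}
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX")


@dataclass
class PairwiseAlignment:
    score: int
    aligned_a: str
    aligned_b: str

    @property
    def identity(self) -> float:
        """Identical columns / total alignment columns."""
        matches = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        return matches / len(self.aligned_a)


def get_matrix(name: str = "BLOSUM62") -> balign.SubstitutionMatrix:
    try:
        return _MATRICES[name]
    except KeyError:
        raise ValidationError(f"unknown substitution matrix {name!r}")


@lru_cache(maxsize=4096)
def as_protein(seq: str) -> bseq.ProteinSequence:
    """Convert to a biotite ProteinSequence, wildcarding unknown residues."""
    if not seq:
        raise ValidationError("empty peptide")
    seq = seq.upper()
    if not set(seq) <= _ALPHABET:
        seq = "".join(c if c in _ALPHABET else "X" for c in seq)
    return bseq.ProteinSequence(seq)


def _align(a, b, matrix, gap_open, gap_extend, local):
    if gap_open <= 0 or gap_extend <= 0:
        raise ValidationError("gap penalties must be positive costs")
    pa = a if isinstance(a, bseq.ProteinSequence) else as_protein(a)
    pb = b if isinstance(b, bseq.ProteinSequence) else as_protein(b)
    aln = balign.align_optimal(
        pa, pb, get_matrix(matrix),
        gap_penalty=(-gap_open, -gap_extend),
        local=local, max_number=1,
    )[0]
    ga, gb = aln.get_gapped_sequences()
    return PairwiseAlignment(int(aln.score), ga, gb)


def smith_waterman(
    a: str, b: str, matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1
) -> PairwiseAlignment:
    """Optimal local alignment (Smith–Waterman, affine gaps)."""
    return _align(a, b, matrix, gap_open, gap_extend, local=True)


def needleman_wunsch(
    a: str, b: str, matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1
) -> PairwiseAlignment:
    """Optimal global alignment (Needleman–Wunsch, affine gaps, terminal gaps penalized)."""
    return _align(a, b, matrix, gap_open, gap_extend, local=False)


def local_score(a, b, matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith–Waterman score only (cheaper call path for scanning)."""
    return _align(a, b, matrix, gap_open, gap_extend, local=True).score
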