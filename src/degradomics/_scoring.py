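"""Shared amino-acid scoring tables.

Every module scores proteins with the same 22-symbol table: the 20 standard
residues from BLOSUM62, plus 'X' (ambiguous translation of N-containing
codons) scoring 0 against everything and '*' (stop) scoring -10 against
everything.  Gaps are affine: a run of length L costs GAP_OPEN + L *
GAP_EXTEND (the BLAST 11/1 convention).
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X*"
X_INDEX = len(AA20)
STOP_INDEX = len(AA20) + 1
GAP_OPEN = 11
GAP_EXTEND = 1
GAP_CHAR = "-"

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def _build_matrix() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int16)
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            m[i, j] = int(b62[a, b])
    m[STOP_INDEX, :] = -10
    m[:, STOP_INDEX] = -10
    m[X_INDEX, :] = 0
    m[:, X_INDEX] = 0
    return m


#: 22x22 integer substitution matrix indexed by :data:`ALPHABET` positions.
MATRIX = _build_matrix()


def biopython_matrix() -> substitution_matrices.Array:
    """The same table as a Biopython Array, for PairwiseAligner."""
    arr = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            arr[a, b] = float(MATRIX[i, j])
    return arr


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int8 indices; unknown letters become 'X'."""
    return np.fromiter(
        (_INDEX.get(c, X_INDEX) for c in seq), dtype=np.int8, count=len(seq)
    )


def pair_score(a: str, b: str) -> int:
    return int(MATRIX[_INDEX.get(a, X_INDEX), _INDEX.get(b, X_INDEX)])


def score_alignment(a: str, b: str, gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND) -> int:
    """Re-score a gapped alignment pair under the shared scheme.

    Each maximal gap run of length L costs ``gap_open + L * gap_extend``.
    Columns with gaps in both rows are rejected.
    """
    if len(a) != len(b):
        raise ValueError("alignment rows differ in length")
    score = 0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(a, b):
        if ca == GAP_CHAR and cb == GAP_CHAR:
            raise ValueError("column gapped in both rows")
        if ca == GAP_CHAR:
            score -= gap_extend + (0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == GAP_CHAR:
            score -= gap_extend + (0 if in_gap_b else gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += pair_score(ca, cb)
            in_gap_a = in_gap_b = False
    return score
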