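"""Global pairwise alignment shared by structure reconciliation and clustering.

Uses Needleman-Wunsch with BLOSUM62 and affine gaps (open 10, extend 0.5),
the defaults of the EMBOSS Needle tool.  Residues outside the BLOSUM62
alphabet are mapped to 'X' before scoring.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=4)
def _aligner(open_gap: float, extend_gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def _sanitize(seq: str, alphabet: frozenset) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def global_align_blocks(
    a: str, b: str, open_gap: float = 10.0, extend_gap: float = 0.5
) -> list[tuple[int, int, int]]:
    """Globally align ``a`` and ``b``; return aligned blocks.

    Each block is ``(a_start, b_start, length)`` over 0-based ungapped
    coordinates.  The first optimal alignment reported by the dynamic
    program is used, so the result is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(open_gap, extend_gap)
    alphabet = frozenset(str(aligner.substitution_matrix.alphabet))
    alignment = aligner.align(_sanitize(a, alphabet), _sanitize(b, alphabet))[0]
    blocks = []
    for (a0, a1), (b0, _b1) in zip(*alignment.aligned):
        blocks.append((int(a0), int(b0), int(a1 - a0)))
    return blocks
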