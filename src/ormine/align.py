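"""Shared protein alignment engine.

Global (end-gap-free) pairwise protein alignment with BLOSUM62 and affine
gaps backs reference selection, family/subfamily assignment and
cross-species clustering. Percent identity is identical columns over
aligned columns, terminal-gap columns excluded.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

OPEN_GAP = -10.0
EXTEND_GAP = -0.5


@lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = OPEN_GAP
    aligner.extend_gap_score = EXTEND_GAP
    # end gaps are charged: with free end gaps on both sequences, "global"
    # alignment degenerates to a best-common-substring match and two
    # unrelated ORs score spuriously high identity over their shared motifs
    aligner.mode = "global"
    return aligner


def _sanitize(seq: str) -> str:
    """Restrict to the BLOSUM62 alphabet (unknowns become X)."""
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in allowed else "X" for c in seq.upper())


def align_pair(a: str, b: str):
    """Best global alignment of two protein strings (first of the co-optimal
    set, which Biopython enumerates deterministically)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _aligner().align(_sanitize(a), _sanitize(b))[0]


def identity_from_alignment(alignment) -> tuple[float, int]:
    """(percent identity, aligned length) with terminal-gap columns excluded.

    Internal gap columns count in the denominator and are never identical.
    """
    ta, qa = alignment[0], alignment[1]
    n = len(ta)
    lo = 0
    while lo < n and (ta[lo] == "-" or qa[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (ta[hi - 1] == "-" or qa[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols <= 0:
        return 0.0, 0
    ident = sum(1 for i in range(lo, hi) if ta[i] == qa[i] and ta[i] != "-")
    return 100.0 * ident / cols, cols


def percent_identity(a: str, b: str) -> float:
    """Percent identity between two proteins under global alignment."""
    pid, _ = identity_from_alignment(align_pair(a, b))
    return pid
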