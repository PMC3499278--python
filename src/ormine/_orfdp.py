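"""Frameshift-aware protein-to-DNA alignment.

A local dynamic program aligns a reference OR protein against candidate
region DNA where each reference residue normally consumes one 3-bp codon
but may consume 2 or 4 bp at a frameshift penalty. This recovers the
coding path of intact genes and of pseudogenes whose reading frame is
broken by small indels, in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

from .genome_io import CODON_TABLE

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

GAP_REF = -11.0   # extra codon in the DNA
GAP_DNA = -11.0   # reference residue with no codon
FS_PENALTY = -12.0

# step codes written by the DP
STEP_CODON = 1    # 3-bp codon
STEP_FS2 = 2      # frameshift, residue consumes 2 bp
STEP_FS4 = 3      # frameshift, residue consumes 4 bp
STEP_DEL = 4      # reference residue skipped
STEP_INS = 5      # unmatched codon in DNA


def _build_tables():
    mat = substitution_matrices.load("BLOSUM62")
    order = {c: i for i, c in enumerate(mat.alphabet)}
    sub = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.float64)
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            sub[_AA_INDEX[a], _AA_INDEX[b]] = mat[order[a], order[b]]
    codon_aa = np.full(125, _AA_INDEX["X"], dtype=np.int64)
    for b0, n0 in _NT_INDEX.items():
        for b1, n1 in _NT_INDEX.items():
            for b2, n2 in _NT_INDEX.items():
                aa = CODON_TABLE.get(b0 + b1 + b2, "X")
                codon_aa[n0 * 25 + n1 * 5 + n2] = _AA_INDEX[aa]
    return sub, codon_aa


_SUBMAT, _CODON_AA = _build_tables()


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _AA_INDEX["X"]) for c in seq.upper()],
                    dtype=np.int64)


def encode_dna(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(c, 4) for c in seq.upper()],
                    dtype=np.int64)


@njit(cache=True)
def _fill(ref, dna, codon_aa, submat, gap_ref, gap_dna, fs_pen):
    R = ref.shape[0]
    L = dna.shape[0]
    S = np.zeros((R + 1, L + 1), dtype=np.float64)
    P = np.zeros((R + 1, L + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, R + 1):
        a = ref[i - 1]
        for j in range(1, L + 1):
            s = 0.0
            p = 0
            if j >= 3:
                c = codon_aa[dna[j - 3] * 25 + dna[j - 2] * 5 + dna[j - 1]]
                v = S[i - 1, j - 3] + submat[a, c]
                if v > s:
                    s = v
                    p = STEP_CODON
                v = S[i, j - 3] + gap_ref
                if v > s:
                    s = v
                    p = STEP_INS
            if j >= 2:
                v = S[i - 1, j - 2] + fs_pen
                if v > s:
                    s = v
                    p = STEP_FS2
            if j >= 4:
                c = codon_aa[dna[j - 3] * 25 + dna[j - 2] * 5 + dna[j - 1]]
                v = S[i - 1, j - 4] + submat[a, c] + fs_pen
                if v > s:
                    s = v
                    p = STEP_FS4
            v = S[i - 1, j] + gap_dna
            if v > s:
                s = v
                p = STEP_DEL
            S[i, j] = s
            P[i, j] = p
            if s > best:
                best = s
                bi = i
                bj = j
    return S, P, best, bi, bj


@dataclass(frozen=True)
class PathStep:
    ref_index: int        # 0-based residue index in the reference, -1 for INS
    dna_start: int        # half-open bp interval consumed
    dna_end: int
    kind: int             # STEP_* code


@dataclass(frozen=True)
class FsAlignment:
    score: float
    steps: list  # PathStep, N-to-C order

    @property
    def codon_steps(self) -> list:
        return [s for s in self.steps
                if s.kind in (STEP_CODON, STEP_FS2, STEP_FS4)]


def align_protein_to_dna(ref_aa: str, dna: str) -> FsAlignment:
    """Best local alignment path of a protein against DNA with frameshifts."""
    ref = encode_protein(ref_aa)
    d = encode_dna(dna)
    if ref.size == 0 or d.size < 3:
        return FsAlignment(0.0, [])
    S, P, best, bi, bj = _fill(ref, d, _CODON_AA, _SUBMAT,
                               GAP_REF, GAP_DNA, FS_PENALTY)
    steps: list[PathStep] = []
    i, j = bi, bj
    while i > 0 and j >= 0:
        p = P[i, j]
        if p == 0:
            break
        if p == STEP_CODON:
            steps.append(PathStep(i - 1, j - 3, j, STEP_CODON))
            i, j = i - 1, j - 3
        elif p == STEP_FS2:
            steps.append(PathStep(i - 1, j - 2, j, STEP_FS2))
            i, j = i - 1, j - 2
        elif p == STEP_FS4:
            steps.append(PathStep(i - 1, j - 4, j, STEP_FS4))
            i, j = i - 1, j - 4
        elif p == STEP_DEL:
            steps.append(PathStep(i - 1, j, j, STEP_DEL))
            i = i - 1
        else:  # STEP_INS
            steps.append(PathStep(-1, j - 3, j, STEP_INS))
            j = j - 3
    steps.reverse()
    return FsAlignment(float(best), steps)
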