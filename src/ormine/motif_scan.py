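"""Degenerate scanning for the four conserved OR motifs.

OR proteins carry short diagnostic peptides — GN (TM2/3 boundary),
MAYDRYVAIC (TM3), KAFSTCASH (TM6) and PMLNPFIY (TM7). Their degenerate
occurrences (Hamming mismatch fraction strictly below ``motif_max_diff``)
in six-frame translations seed candidate OR regions: windows of ~2 kb
holding at least two distinct TM motifs on one strand in the canonical
TM3 < TM6 < TM7 order along the direction of translation.

GN is recorded for reporting but is too short (2 aa) to be informative and
never counts toward region qualification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import FrameTranslation, GenomeSequence
from .params import PipelineParams


@dataclass(frozen=True)
class Motif:
    name: str
    aa: str


MOTIFS: dict[str, Motif] = {
    "GN": Motif("GN", "GN"),
    "TM3": Motif("TM3", "MAYDRYVAIC"),
    "TM6": Motif("TM6", "KAFSTCASH"),
    "TM7": Motif("TM7", "PMLNPFIY"),
}

#: Motifs that may count toward the >=2-motif region rule.
QUALIFYING = ("TM3", "TM6", "TM7")

#: Canonical N-to-C order of the TM motifs in an OR protein.
_ORDER = {"TM3": 0, "TM6": 1, "TM7": 2}


@dataclass(frozen=True)
class MotifHit:
    contig_id: str
    frame: int
    aa_start: int
    motif_name: str
    n_mismatch: int
    genomic_start: int
    genomic_end: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class CandidateRegion:
    contig_id: str
    genomic_start: int
    genomic_end: int
    strand: str
    hits: list[MotifHit]
    seq: str  # forward-strand DNA of the window

    @property
    def name(self) -> str:
        return (f"{self.contig_id}:{self.genomic_start}-"
                f"{self.genomic_end}({self.strand})")

    def oriented_seq(self) -> str:
        """Window DNA read along the region's strand."""
        if self.strand == "+":
            return self.seq
        from Bio.Seq import Seq
        return str(Seq(self.seq).reverse_complement())


def motif_distance(window: str, motif: Motif) -> float:
    """Hamming mismatch fraction between a window and a motif consensus.

    'X' (ambiguous translation) and '*' (stop) always count as mismatches.
    """
    if len(window) != len(motif.aa):
        raise ValueError(f"window length {len(window)} != motif "
                         f"length {len(motif.aa)}")
    n = sum(1 for a, b in zip(window, motif.aa) if a != b or a in "X*")
    return n / len(motif.aa)


def _scan_one(aa_seq: str, motif: Motif, max_diff: float) -> list[tuple[int, int]]:
    """Vectorised Hamming scan: (window start, mismatch count) pairs with
    mismatch fraction strictly below max_diff."""
    k = len(motif.aa)
    if len(aa_seq) < k:
        return []
    arr = np.frombuffer(aa_seq.encode("ascii"), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    mot = np.frombuffer(motif.aa.encode("ascii"), dtype=np.uint8)
    mism = (win != mot) | (win == ord("X")) | (win == ord("*"))
    counts = mism.sum(axis=1)
    limit = max_diff * k  # strict '<'
    idx = np.nonzero(counts < limit)[0]
    return [(int(i), int(counts[i])) for i in idx]


def scan_frames(frames: list[FrameTranslation],
                params: PipelineParams | None = None) -> list[MotifHit]:
    """Report every degenerate motif occurrence in a set of frame translations."""
    params = params or PipelineParams()
    hits: list[MotifHit] = []
    for ft in frames:
        for motif in MOTIFS.values():
            for aa_start, nm in _scan_one(ft.aa_seq, motif,
                                          params.motif_max_diff):
                gs, ge = ft.genomic_span(aa_start, len(motif.aa))
                hits.append(MotifHit(ft.contig_id, ft.frame, aa_start,
                                     motif.name, nm, gs, ge))
    hits.sort(key=lambda h: (h.contig_id, h.genomic_start, h.frame,
                             h.motif_name))
    return hits


def _ordered_pair(a: MotifHit, b: MotifHit, strand: str) -> bool:
    """True when two distinct TM hits appear in canonical order along the
    translation direction."""
    if a.motif_name == b.motif_name:
        return False
    first, second = (a, b) if a.genomic_start <= b.genomic_start else (b, a)
    if strand == "-":
        first, second = second, first
    return _ORDER[first.motif_name] < _ORDER[second.motif_name]


def build_candidate_regions(hits: list[MotifHit],
                            genome: list[GenomeSequence],
                            params: PipelineParams | None = None
                            ) -> list[CandidateRegion]:
    """Merge qualifying motif hits into ~2-kb candidate regions.

    A pair of distinct TM3/TM6/TM7 hits on one contig and strand, within
    ``region_len_bp`` of each other and in canonical order along the
    translation direction, seeds a region: 1 kb each side of the hit-span
    midpoint, clipped at contig edges. Overlapping same-strand regions merge,
    keeping the union of their hits (GN hits inside the span are attached
    for reporting).
    """
    params = params or PipelineParams()
    contigs = {g.id: g for g in genome}
    regions: list[CandidateRegion] = []

    groups: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        groups.setdefault((h.contig_id, h.strand), []).append(h)

    for (contig_id, strand), ghits in sorted(groups.items()):
        tm = sorted((h for h in ghits if h.motif_name in QUALIFYING),
                    key=lambda h: h.genomic_start)
        gn = [h for h in ghits if h.motif_name == "GN"]
        # qualifying seed intervals from ordered pairs within one window
        seeds: list[tuple[int, int, set[int]]] = []  # (span lo, span hi, hit idx)
        for i in range(len(tm)):
            for j in range(i + 1, len(tm)):
                a, b = tm[i], tm[j]
                if b.genomic_start - a.genomic_start > params.region_len_bp:
                    break
                if _ordered_pair(a, b, strand):
                    lo = min(a.genomic_start, b.genomic_start)
                    hi = max(a.genomic_end, b.genomic_end)
                    seeds.append((lo, hi, {i, j}))
        if not seeds:
            continue
        # expand each seed to a window, then merge overlapping windows
        length = contigs[contig_id].length
        windows = []
        for lo, hi, idx in seeds:
            mid = (lo + hi) // 2
            ws = max(0, mid - params.flank_bp)
            we = min(length, mid + params.flank_bp)
            windows.append([ws, we, set(idx)])
        windows.sort(key=lambda w: w[0])
        merged = [windows[0]]
        for ws, we, idx in windows[1:]:
            if ws <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], we)
                merged[-1][2] |= idx
            else:
                merged.append([ws, we, idx])
        for ws, we, idx in merged:
            rhits = sorted((tm[i] for i in idx), key=lambda h: h.genomic_start)
            rhits += [h for h in gn if ws <= h.genomic_start < we]
            rhits.sort(key=lambda h: h.genomic_start)
            regions.append(CandidateRegion(
                contig_id, ws, we, strand, rhits,
                contigs[contig_id].seq[ws:we]))
    regions.sort(key=lambda r: (r.contig_id, r.genomic_start, r.strand))
    return regions
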