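"""ORF reconstruction and functional/pseudogene/partial classification.

Each ~2-kb candidate region is compared against a reference OR protein set;
the best reference guides reconstruction of the coding sequence (start ATG,
terminal stop, frameshifts, premature stops). A locus is *functional* when
its reconstructed model is at least ``min_functional_aa`` residues with an
intact ORF, a *pseudogene* when the model spans that length but the ORF is
disrupted, and *partial* when the model is shorter.

Pseudogene length is measured on the reference-spanned model — the protein
the locus would encode if undamaged — because a premature stop would
otherwise shrink every pseudogene below the length floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._orfdp import (STEP_CODON, STEP_FS2, STEP_FS4, align_protein_to_dna)
from .align import align_pair, identity_from_alignment
from .genome_io import CODON_TABLE, STOP_CODONS, translate_dna
from .motif_scan import MOTIFS, CandidateRegion, _scan_one
from .params import PipelineParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceProtein:
    id: str
    aa_seq: str
    species: str = "unknown"
    family: int | None = None
    class_label: str | None = None
    odorant: str | None = None
    percept: str | None = None


@dataclass(frozen=True)
class Disruption:
    kind: str        # "premature_stop" | "frameshift"
    cds_offset: int  # bp offset from CDS start


@dataclass
class ORGene:
    gene_id: str
    contig_id: str
    genomic_start: int
    genomic_end: int
    strand: str
    cds: str                      # coding-strand DNA
    protein: str                  # reconstructed model translation
    model_length: int             # reference-spanned model length (aa)
    disruptions: list[Disruption]
    flags: list[str]
    best_ref_id: str
    best_ref_identity: float
    status: str = "unclassified"
    motif_profile: dict = field(default_factory=dict)

    @property
    def is_disrupted(self) -> bool:
        # an ORF without a recoverable start or terminal stop is not intact
        return bool(self.disruptions) or "no_start" in self.flags \
            or "no_stop" in self.flags


def select_reference(region: CandidateRegion,
                     refs: list[ReferenceProtein]
                     ) -> tuple[ReferenceProtein, float]:
    """Best reference for a region by percent identity over any of the three
    reading frames of the region's strand.

    Ties break toward the longer alignment, then the lexicographically
    smaller reference id.
    """
    if not refs:
        raise ValueError("empty reference set")
    oriented = region.oriented_seq()
    frames = [translate_dna(oriented[f:]) for f in range(3)]
    best: tuple[float, int, str] | None = None
    best_ref = None
    for ref in refs:
        for frame_aa in frames:
            if not frame_aa:
                continue
            pid, ncols = identity_from_alignment(
                align_pair(frame_aa, ref.aa_seq))
            key = (pid, ncols, ref.id)
            if (best is None or key[0] > best[0]
                    or (key[0] == best[0] and key[1] > best[1])
                    or (key[0] == best[0] and key[1] == best[1]
                        and key[2] < best[2])):
                best = key
                best_ref = ref
    return best_ref, best[0]


def _find_start(oriented: str, s0: int, ref_offset: int,
                max_codons: int) -> tuple[int | None, int]:
    """In-frame ATG nearest the reference-projected N terminus.

    s0 is the first aligned codon start, ref_offset the reference residue it
    aligns to; the expected start is s0 - 3*ref_offset. Offsets are tried in
    order 0, -1, +1, -2, +2, ... codons (ties prefer upstream).
    """
    expected = s0 - 3 * ref_offset
    for k in range(max_codons + 1):
        for off in ((0,) if k == 0 else (-k, k)):
            p = expected + 3 * off
            if 0 <= p <= len(oriented) - 3 and p <= s0 \
                    and oriented[p:p + 3] == "ATG":
                return p, expected
    return None, expected


def reconstruct_orf(region: CandidateRegion, best_ref: ReferenceProtein,
                    best_identity: float,
                    params: PipelineParams | None = None) -> ORGene:
    """Rebuild the coding sequence of a candidate region along its best
    reference and record every ORF disruption."""
    params = params or PipelineParams()
    oriented = region.oriented_seq()
    aln = align_protein_to_dna(best_ref.aa_seq, oriented)
    codons = aln.codon_steps
    if not codons:
        raise ValueError(f"{region.name}: reference does not align")

    flags: list[str] = []
    disruptions: list[Disruption] = []

    first, last = codons[0], codons[-1]
    s0 = first.dna_start
    start, _ = _find_start(oriented, s0, first.ref_index,
                           params.start_search_codons)
    if start is None:
        start = s0
        flags.append("no_start")

    # terminal stop: first in-frame stop at/after the aligned C terminus
    e0 = last.dna_end
    stop_at = None
    p = e0
    while p + 3 <= len(oriented):
        if oriented[p:p + 3] in STOP_CODONS:
            stop_at = p
            break
        p += 3
    if stop_at is None:
        flags.append("no_stop")
        cds_end = e0
    else:
        cds_end = stop_at + 3

    cds = oriented[start:cds_end]

    # leading codons between the chosen start and the first aligned codon
    protein_parts: list[str] = []
    lead = oriented[start:s0]
    protein_parts.append(translate_dna(lead))
    n_lead = len(lead) // 3
    for c in codons:
        if c.kind == STEP_CODON:
            protein_parts.append(CODON_TABLE.get(
                oriented[c.dna_start:c.dna_end], "X"))
        elif c.kind == STEP_FS4:
            protein_parts.append(CODON_TABLE.get(
                oriented[c.dna_end - 3:c.dna_end], "X"))
            disruptions.append(Disruption("frameshift", c.dna_start - start))
        else:  # STEP_FS2
            protein_parts.append("X")
            disruptions.append(Disruption("frameshift", c.dna_start - start))
    protein = "".join(protein_parts)

    # premature stops anywhere in the model before the terminal stop
    for i, aa in enumerate(protein):
        if aa == "*":
            disruptions.append(Disruption("premature_stop", _model_offset(
                i, n_lead, codons, start)))
    disruptions.sort(key=lambda d: d.cds_offset)

    model_length = n_lead + len(codons)
    # identity of the stitched model (frameshift-repaired) to its reference:
    # fairer than single-frame identity for disrupted loci, and the quantity
    # the non-OR floor is applied to
    model_identity, _ = identity_from_alignment(
        align_pair(protein, best_ref.aa_seq)) if protein else (0.0, 0)
    gs, ge = _to_forward(region, start, cds_end)
    return ORGene(
        gene_id=f"{region.contig_id}:{gs}-{ge}({region.strand})",
        contig_id=region.contig_id,
        genomic_start=gs,
        genomic_end=ge,
        strand=region.strand,
        cds=cds,
        protein=protein,
        model_length=model_length,
        disruptions=disruptions,
        flags=flags,
        best_ref_id=best_ref.id,
        best_ref_identity=max(best_identity, model_identity),
    )


def _model_offset(protein_index: int, n_lead: int, codons, start: int) -> int:
    """CDS bp offset of the codon encoding model residue ``protein_index``."""
    if protein_index < n_lead:
        return 3 * protein_index
    return codons[protein_index - n_lead].dna_start - start


def _to_forward(region: CandidateRegion, lo: int, hi: int) -> tuple[int, int]:
    """Map a region-strand half-open interval to forward-strand genome
    coordinates."""
    if region.strand == "+":
        return region.genomic_start + lo, region.genomic_start + hi
    return region.genomic_end - hi, region.genomic_end - lo


def classify_gene(g: ORGene, params: PipelineParams | None = None) -> str:
    """functional / pseudogene / partial trichotomy on the reconstructed model.

    >= min_functional_aa with an intact ORF -> functional; >= the floor but
    disrupted (premature stop, frameshift, or unrecoverable start) ->
    pseudogene; shorter than the floor -> partial.
    """
    params = params or PipelineParams()
    if g.model_length < params.min_functional_aa:
        status = "partial"
    elif g.is_disrupted:
        status = "pseudogene"
    else:
        status = "functional"
    g.status = status
    return status


def motif_presence(g: ORGene,
                   params: PipelineParams | None = None) -> dict[str, bool]:
    """Presence of each conserved motif in the reconstructed protein
    (best-window mismatch fraction below motif_max_diff).

    GN is recorded but is never used for filtering.
    """
    params = params or PipelineParams()
    profile = {}
    for name, motif in MOTIFS.items():
        profile[name] = bool(_scan_one(g.protein, motif,
                                       params.motif_max_diff))
    g.motif_profile = profile
    return profile


def motif_profile_summary(genes: list[ORGene]) -> dict:
    """Across a gene set: how many carry all three TM motifs, and which
    single motif is missing otherwise."""
    summary = {"n": len(genes), "all_three": 0,
               "missing": {"TM3": 0, "TM6": 0, "TM7": 0}, "other": 0}
    for g in genes:
        prof = g.motif_profile or motif_presence(g)
        present = [m for m in ("TM3", "TM6", "TM7") if prof.get(m)]
        if len(present) == 3:
            summary["all_three"] += 1
        elif len(present) == 2:
            missing = next(m for m in ("TM3", "TM6", "TM7")
                           if m not in present)
            summary["missing"][missing] += 1
        else:
            summary["other"] += 1
    if summary["n"]:
        summary["pct_all_three"] = 100.0 * summary["all_three"] / summary["n"]
    return summary


def dedupe_candidates(genes: list[ORGene],
                      params: PipelineParams | None = None
                      ) -> tuple[list[ORGene], list[tuple[ORGene, str]]]:
    """Drop non-OR models and collapse overlapping same-strand models.

    Returns (kept, removed) where each removed entry carries a reason.
    Models whose best reference identity is below ``non_or_floor`` are
    treated as non-OR GPCR look-alikes; overlapping models on one strand
    collapse to the highest-identity one.
    """
    params = params or PipelineParams()
    removed: list[tuple[ORGene, str]] = []
    kept: list[ORGene] = []
    for g in genes:
        if g.best_ref_identity < params.non_or_floor:
            removed.append((g, "non_or_identity_floor"))
            logger.info("dropping %s: best identity %.1f%% below floor",
                        g.gene_id, g.best_ref_identity)
        else:
            kept.append(g)

    kept.sort(key=lambda g: (g.contig_id, g.strand, g.genomic_start))
    result: list[ORGene] = []
    for g in kept:
        if (result and result[-1].contig_id == g.contig_id
                and result[-1].strand == g.strand
                and g.genomic_start < result[-1].genomic_end):
            if g.best_ref_identity > result[-1].best_ref_identity:
                removed.append((result[-1], "overlap_lower_identity"))
                result[-1] = g
            else:
                removed.append((g, "overlap_lower_identity"))
        else:
            result.append(g)
    result.sort(key=lambda g: (g.contig_id, g.genomic_start))
    return result, removed
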