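"""Synthetic genomes with planted OR genes and a truth manifest.

The generator emulates the statistical structure the mining pipeline
assumes: intronless OR genes of >=310 codons carrying the four conserved
motifs at their canonical positions (GN ~60, TM3 ~121, TM6 ~239, TM7 ~284),
point mutations, pseudogenizing premature stops and +-1 bp frameshifts,
sub-length partial fragments, and byte-identical duplicated segments —
embedded in random intergenic DNA across several contigs, on both strands.

Default generation parameters are the benchmark conditions used throughout
the test suite: 100 planted genes, 15% pseudogenes, 10% partials, 2%
amino-acid mutation rate, and five duplicate pairs plus one triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CODON_TABLE, GenomeSequence, revcomp
from .motif_scan import MOTIFS
from .orf_model import ORGene, ReferenceProtein

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: canonical motif anchor positions (0-based) in the template protein
MOTIF_POSITIONS = {"GN": 59, "TM3": 120, "TM6": 238, "TM7": 283}

_STOPS = ("TAA", "TAG", "TGA")

_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for v in _SYNONYMS.values():
    v.sort()


@dataclass(frozen=True)
class DupSpec:
    """One planted duplication group: ``copies`` byte-identical CDS copies
    inside identical segments of ``segment_bp`` total length; ``inter``
    places copies on different contigs."""
    copies: int = 2
    segment_bp: int = 4_000
    inter: bool = False


DEFAULT_DUP_SPEC = (
    DupSpec(2, 3_000, False),
    DupSpec(2, 4_000, False),
    DupSpec(2, 5_000, False),
    DupSpec(2, 6_000, False),
    DupSpec(2, 4_500, True),
    DupSpec(3, 5_000, False),
)


@dataclass
class SyntheticGenome:
    genome: list[GenomeSequence]
    manifest: pd.DataFrame
    references: list[ReferenceProtein]


def make_or_template(class_label: str, rng: np.random.Generator,
                     length: int | None = None) -> str:
    """Random OR-like protein template: starts with M, carries the four
    conserved motifs verbatim at their canonical positions, >=310 aa."""
    n = int(length if length is not None else rng.integers(310, 331))
    if n < 310:
        raise ValueError("template must be at least 310 aa")
    aas = list(rng.choice(list(AA20), size=n))
    aas[0] = "M"
    for name, pos in MOTIF_POSITIONS.items():
        motif = MOTIFS[name].aa
        aas[pos:pos + len(motif)] = list(motif)
    return "".join(aas)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codon for each residue."""
    return "".join(_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))]
                   for aa in protein)


def _mutate_protein(protein: str, rate: float,
                    rng: np.random.Generator) -> str:
    """Point substitutions at ``rate`` per site; the initial methionine is
    kept (start-codon conservation)."""
    aas = list(protein)
    for i in range(1, len(aas)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != aas[i]]
            aas[i] = choices[rng.integers(len(choices))]
    return "".join(aas)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _plant_disruptions(cds: str, n_dis: int, rng: np.random.Generator
                       ) -> tuple[str, list[tuple[str, int]]]:
    """Apply 1-3 premature stops / +-1 bp frameshifts to an intact CDS.

    Returns the damaged CDS and the list of (kind, cds_offset) in the
    coordinates of the damaged sequence. Edits are applied back-to-front so
    earlier offsets stay valid.
    """
    n_codons = len(cds) // 3
    lo, hi = 30, n_codons - 30
    positions = sorted(rng.choice(np.arange(lo, hi), size=n_dis,
                                  replace=False).tolist(), reverse=True)
    seq = cds
    events: list[tuple[str, int]] = []
    for codon_i in positions:
        off = 3 * codon_i
        if rng.random() < 0.5:
            stop = _STOPS[rng.integers(3)]
            seq = seq[:off] + stop + seq[off + 3:]
            events.append(("premature_stop", off))
        else:
            if rng.random() < 0.5:  # delete 1 bp
                seq = seq[:off] + seq[off + 1:]
            else:                   # insert 1 bp
                seq = seq[:off] + "ACGT"[rng.integers(4)] + seq[off:]
            events.append(("frameshift", off))
    events.reverse()
    return seq, events


def plant_genome(n_genes: int = 100,
                 frac_pseudo: float = 0.15,
                 frac_partial: float = 0.10,
                 aa_mut_rate: float = 0.02,
                 dup_spec: tuple[DupSpec, ...] | None = DEFAULT_DUP_SPEC,
                 intergenic_bp: tuple[int, int] = (2_000, 8_000),
                 n_contigs: int = 4,
                 n_families: int = 5,
                 rng_seed: int = 0) -> SyntheticGenome:
    """Build a synthetic genome with a fully specified truth manifest.

    The manifest has one row per planted gene copy: coordinates (0-based,
    half-open, forward strand), strand, status, disruption list, family and
    template labels, and duplicate group id. The ungarbled templates are
    returned as a labelled reference protein set.
    """
    if not 0 <= frac_pseudo + frac_partial <= 1:
        raise ValueError("status fractions must sum to at most 1")
    rng = np.random.default_rng(rng_seed)
    dup_spec = tuple(dup_spec or ())

    n_class1 = max(1, n_families // 5)
    templates: list[ReferenceProtein] = []
    for i in range(n_families):
        class_label = "I" if i < n_class1 else "II"
        templates.append(ReferenceProtein(
            id=f"ref{i + 1:03d}",
            aa_seq=make_or_template(class_label, rng),
            species="reference",
            family=i + 1,
            class_label=class_label,
        ))

    n_pseudo = int(round(frac_pseudo * n_genes))
    n_partial = int(round(frac_partial * n_genes))
    n_functional = n_genes - n_pseudo - n_partial
    if n_functional < len([d for d in dup_spec]):
        raise ValueError("not enough functional genes for the duplication spec")
    statuses = (["functional"] * n_functional + ["pseudogene"] * n_pseudo
                + ["partial"] * n_partial)
    rng.shuffle(statuses)

    # build every gene copy first, then lay contigs out
    @dataclass
    class _Planted:
        name: str
        status: str
        family: int
        template_id: str
        cds: str
        disruptions: list = field(default_factory=list)
        dup_group: str = ""
        segment: str | None = None   # identical segment for duplicates
        cds_in_segment: int = 0
        force_contig: int | None = None

    planted: list[_Planted] = []
    for i, status in enumerate(statuses):
        t = templates[rng.integers(len(templates))]
        protein = _mutate_protein(t.aa_seq, aa_mut_rate, rng)
        cds = reverse_translate(protein, rng) + _STOPS[rng.integers(3)]
        disruptions: list[tuple[str, int]] = []
        if status == "pseudogene":
            cds, disruptions = _plant_disruptions(cds, int(rng.integers(1, 4)),
                                                  rng)
        elif status == "partial":
            k = int(rng.integers(250, 300))
            cds = cds[:3 * k]
        planted.append(_Planted(f"g{i + 1:04d}", status, t.family, t.id,
                                cds, disruptions))

    # duplication groups: each spec entry clones one functional gene
    functional_idx = [i for i, p in enumerate(planted)
                      if p.status == "functional"]
    chosen = rng.choice(np.array(functional_idx), size=len(dup_spec),
                        replace=False)
    dup_members: list[_Planted] = []
    for gi, (idx, spec) in enumerate(zip(chosen.tolist(), dup_spec)):
        base = planted[idx]
        group = f"dup{gi + 1:02d}"
        base.dup_group = group
        pad = spec.segment_bp - len(base.cds)
        if pad < 0:
            raise ValueError("duplication segment shorter than the CDS")
        left = _random_dna(pad // 2, rng)
        right = _random_dna(pad - pad // 2, rng)
        segment = left + base.cds + right
        contigs = (rng.permutation(n_contigs)[:spec.copies].tolist()
                   if spec.inter else
                   [int(rng.integers(n_contigs))] * spec.copies)
        members = [base]
        for c in range(spec.copies - 1):
            clone = _Planted(f"{base.name}.{c + 2}", base.status, base.family,
                             base.template_id, base.cds,
                             list(base.disruptions), group)
            members.append(clone)
            dup_members.append(clone)
        for member, contig in zip(members, contigs):
            member.segment = segment
            member.cds_in_segment = len(left)
            member.force_contig = int(contig)
    planted.extend(dup_members)

    # contig layout
    order = rng.permutation(len(planted)).tolist()
    pieces: dict[int, list[str]] = {c: [] for c in range(n_contigs)}
    cursor: dict[int, int] = {c: 0 for c in range(n_contigs)}
    rows = []
    # distinct boundary bases per duplicate-group member stop flank extension
    dup_counter: dict[str, int] = {}
    for oi in order:
        p = planted[oi]
        contig = (p.force_contig if p.force_contig is not None
                  else int(rng.integers(n_contigs)))
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(intergenic_bp[0], intergenic_bp[1] + 1))
        spacer = _random_dna(gap, rng)
        block = p.segment if p.segment is not None else p.cds
        cds_off = p.cds_in_segment
        if p.dup_group:
            k = dup_counter.get(p.dup_group, 0)
            dup_counter[p.dup_group] = k + 1
            # force divergence immediately outside the identical segment so
            # duplication spans equal segment_bp exactly; the boundary base
            # is distinct per copy in coding-strand orientation
            b = "ACGT"[k]
            boundary = b if strand == "+" else revcomp(b)
            spacer = spacer[:-1] + boundary
            tail = boundary
        else:
            tail = ""
        oriented_block = block if strand == "+" else revcomp(block)
        start = cursor[contig] + len(spacer)
        pieces[contig].extend([spacer, oriented_block, tail])
        cursor[contig] += len(spacer) + len(oriented_block) + len(tail)
        if strand == "+":
            cds_start = start + cds_off
            cds_end = cds_start + len(p.cds)
        else:
            cds_end = start + len(block) - cds_off
            cds_start = cds_end - len(p.cds)
        rows.append({
            "gene": p.name, "contig": f"chr{contig + 1}",
            "start": cds_start, "end": cds_end, "strand": strand,
            "status": p.status, "family": p.family,
            "template": p.template_id,
            "disruptions": ";".join(f"{k}:{o}" for k, o in p.disruptions),
            "dup_group": p.dup_group,
            "segment_bp": len(block) if p.segment is not None else 0,
        })

    for c in range(n_contigs):
        pieces[c].append(_random_dna(
            int(rng.integers(intergenic_bp[0], intergenic_bp[1] + 1)), rng))
    genome = [GenomeSequence(f"chr{c + 1}", "".join(pieces[c]))
              for c in range(n_contigs)]
    manifest = pd.DataFrame(rows).sort_values(
        ["contig", "start"]).reset_index(drop=True)
    return SyntheticGenome(genome, manifest, templates)


def write_synthetic(syn: SyntheticGenome, out_dir) -> dict:
    """Write genome FASTA, labelled reference FASTA and manifest TSV."""
    from pathlib import Path
    from .genome_io import write_fasta
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genome": out / "genome.fa", "refs": out / "references.faa",
             "manifest": out / "manifest.tsv"}
    write_fasta(paths["genome"], ((g.id, g.seq) for g in syn.genome))
    write_fasta(paths["refs"],
                ((f"{r.id} species={r.species} family={r.family} "
                  f"class={r.class_label}", r.aa_seq)
                 for r in syn.references))
    syn.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def score_recovery(manifest: pd.DataFrame,
                   predicted: list[ORGene]) -> dict:
    """Match predictions to planted genes (reciprocal >=50% overlap, same
    contig and strand) and score per-status precision/recall plus exact
    status recall."""
    truth = manifest.to_dict("records")
    used: set[int] = set()
    matches: list[tuple[dict, ORGene]] = []
    for t in truth:
        best, best_j = None, None
        for j, g in enumerate(predicted):
            if j in used or g.contig_id != t["contig"] \
                    or g.strand != t["strand"]:
                continue
            ov = _overlap(t["start"], t["end"], g.genomic_start,
                          g.genomic_end)
            if ov < 0.5 * (t["end"] - t["start"]) \
                    or ov < 0.5 * (g.genomic_end - g.genomic_start):
                continue
            if best is None or ov > best:
                best, best_j = ov, j
        if best_j is not None:
            used.add(best_j)
            matches.append((t, predicted[best_j]))

    statuses = ("functional", "pseudogene", "partial")
    confusion = pd.DataFrame(0, index=list(statuses) + ["missed"],
                             columns=list(statuses))
    matched_names = {t["gene"] for t, _ in matches}
    for t, g in matches:
        confusion.loc[g.status, t["status"]] += 1
    for t in truth:
        if t["gene"] not in matched_names:
            confusion.loc["missed", t["status"]] += 1

    out = {"confusion": confusion, "n_truth": len(truth),
           "n_predicted": len(predicted)}
    exact = sum(1 for t, g in matches if g.status == t["status"])
    out["status_exact_recall"] = exact / len(truth) if truth else 1.0
    for s in statuses:
        n_true = sum(1 for t in truth if t["status"] == s)
        n_pred = sum(1 for g in predicted if g.status == s)
        tp = sum(1 for t, g in matches
                 if t["status"] == s and g.status == s)
        out[f"recall_{s}"] = tp / n_true if n_true else 1.0
        out[f"precision_{s}"] = tp / n_pred if n_pred else 1.0
    return out
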