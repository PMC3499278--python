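"""Genome and reference-protein I/O, six-frame translation, output writers.

Internal coordinates are 0-based, half-open, on the forward strand
everywhere in the package; conversion to 1-based inclusive happens only
when writing GFF3.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

# Standard genetic code; stops rendered '*'; any codon containing an
# ambiguous base translates to 'X'.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def revcomp(self) -> str:
        return str(Seq(self.seq).reverse_complement())


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a genome FASTA into GenomeSequence records.

    Lowercase input is uppercased; symbols outside {A,C,G,T,N} are replaced
    by N with a warning. Empty files and duplicate record ids are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = re.sub(r"[^ACGTN]", "N", seq)
        n_repl = sum(a != b for a, b in zip(seq, cleaned))
        if n_repl:
            logger.warning("%s: replaced %d non-ACGTN symbols with N",
                           rec.id, n_repl)
        out.append(GenomeSequence(rec.id, cleaned))
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_dna(dna: str) -> str:
    """Translate a DNA string codon-by-codon (trailing partial codon dropped)."""
    return "".join(CODON_TABLE.get(dna[i:i + 3], "X")
                   for i in range(0, len(dna) - len(dna) % 3, 3))


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six reading-frame translations of a contig.

    frame is +1/+2/+3 (forward strand, 0/1/2 bp shift) or -1/-2/-3 (reverse
    complement, shift from the 3' end of the forward strand). Coordinates
    reported by the offset map always refer to the forward strand.
    """

    contig_id: str
    frame: int
    aa_seq: str
    contig_length: int

    @property
    def shift(self) -> int:
        return abs(self.frame) - 1

    def aa_to_genomic(self, aa_index: int) -> int:
        """Forward-strand coordinate of the first base (in reading direction)
        of the codon encoding ``aa_seq[aa_index]``."""
        if not 0 <= aa_index < len(self.aa_seq):
            raise IndexError(aa_index)
        if self.frame > 0:
            return self.shift + 3 * aa_index
        return self.contig_length - 1 - self.shift - 3 * aa_index

    def genomic_span(self, aa_start: int, aa_len: int = 1) -> tuple[int, int]:
        """Forward-strand half-open interval covered by ``aa_len`` codons."""
        if self.frame > 0:
            s = self.shift + 3 * aa_start
            return s, s + 3 * aa_len
        e = self.contig_length - self.shift - 3 * aa_start
        return e - 3 * aa_len, e

    def genomic_to_aa(self, pos: int) -> int:
        """Inverse of aa_to_genomic (codon-first-base coordinates only)."""
        if self.frame > 0:
            off = pos - self.shift
        else:
            off = self.contig_length - 1 - self.shift - pos
        if off % 3 or not 0 <= off // 3 < len(self.aa_seq):
            raise ValueError(f"{pos} is not a codon start in frame {self.frame}")
        return off // 3


def six_frame_translate(g: GenomeSequence) -> list[FrameTranslation]:
    """Translate a contig in all six frames (empty frames for tiny contigs)."""
    rc = g.revcomp()
    out = []
    for frame in FRAMES:
        shift = abs(frame) - 1
        src = g.seq if frame > 0 else rc
        out.append(FrameTranslation(g.id, frame, translate_dna(src[shift:]),
                                    g.length))
    return out


def read_reference_proteins(path: str | Path):
    """Read a reference OR protein FASTA.

    Optional ``key=value`` tokens in the description are parsed into the
    record's annotation: species=..., family=<int>, class_label=<I|II>,
    odorant=..., percept=... (underscores in values stand for spaces).
    """
    from .orf_model import ReferenceProtein  # cycle-free at call time

    refs: list[ReferenceProtein] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate reference id {rec.id!r}")
        seen.add(rec.id)
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v.replace("_", " ")
        family = int(meta["family"]) if "family" in meta else None
        refs.append(ReferenceProtein(
            id=rec.id,
            aa_seq=str(rec.seq).upper(),
            species=meta.get("species", "unknown"),
            family=family,
            class_label=meta.get("class", meta.get("class_label")),
            odorant=meta.get("odorant"),
            percept=meta.get("percept"),
        ))
    if not refs:
        raise ValueError(f"{path}: no reference proteins")
    return refs


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_outputs(genes: Sequence, out_dir: str | Path,
                  assignments: dict | None = None) -> dict[str, Path]:
    """Write GFF3 + BED + protein/CDS FASTA + summary TSV for a gene set.

    ``assignments`` maps gene_id -> Assignment; when given, systematic names
    key the FASTA records and appear in the tables. Empty gene sets produce
    headers-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignments = assignments or {}

    def name_of(g) -> str:
        a = assignments.get(g.gene_id)
        return a.name if a is not None else g.gene_id

    paths = {k: out_dir / f"or_genes.{ext}" for k, ext in
             [("gff3", "gff3"), ("bed", "bed"), ("protein", "faa"),
              ("cds", "fna"), ("summary", "tsv")]}

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (f"ID={name_of(g)};status={g.status};"
                     f"best_ref={g.best_ref_id};identity={g.best_ref_identity:.1f}")
            fh.write("\t".join([
                g.contig_id, "ormine", "gene",
                str(g.genomic_start + 1), str(g.genomic_end), ".",
                g.strand, ".", attrs]) + "\n")

    with open(paths["bed"], "w") as fh:
        for g in genes:
            fh.write(f"{g.contig_id}\t{g.genomic_start}\t{g.genomic_end}"
                     f"\t{name_of(g)}\n")

    write_fasta(paths["protein"], ((name_of(g), g.protein) for g in genes))
    write_fasta(paths["cds"], ((name_of(g), g.cds) for g in genes))

    with open(paths["summary"], "w") as fh:
        fh.write("name\tcontig\tstart\tend\tstrand\tstatus\tmodel_aa\t"
                 "disruptions\tbest_ref\tidentity\n")
        for g in genes:
            dis = ";".join(f"{d.kind}:{d.cds_offset}" for d in g.disruptions)
            fh.write(f"{name_of(g)}\t{g.contig_id}\t{g.genomic_start}\t"
                     f"{g.genomic_end}\t{g.strand}\t{g.status}\t"
                     f"{g.model_length}\t{dis}\t{g.best_ref_id}\t"
                     f"{g.best_ref_identity:.1f}\n")
    return paths
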