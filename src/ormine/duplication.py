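"""Exact OR gene duplications.

Genes whose coding sequences are byte-identical on the coding strand form
one duplication event (a group of >=2 copies). Events are intra- or
inter-chromosomal (or mixed, for groups straddling both); the extent of the
duplicated segment around each copy pair is measured by greedy outward
extension while the flanking genome sequence stays identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classify import genome_order_key
from .genome_io import GenomeSequence, revcomp
from .orf_model import ORGene

logger = logging.getLogger(__name__)


@dataclass
class DuplicationEvent:
    group_id: str
    members: list[ORGene]        # genome order
    kind: str = ""               # intra | inter | mixed
    spans: dict = field(default_factory=dict)  # (id_a, id_b) -> span bp

    @property
    def copy_count(self) -> int:
        return len(self.members)


def find_identical_cds(genes: list[ORGene]) -> list[DuplicationEvent]:
    """Group genes by exact coding-strand CDS equality; groups of >=2 become
    events, ordered and numbered by the genome position of their first
    member."""
    groups: dict[str, list[ORGene]] = {}
    for g in genes:
        groups.setdefault(g.cds, []).append(g)
    events = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=genome_order_key)
        events.append(members)
    events.sort(key=lambda ms: genome_order_key(ms[0]))
    return [DuplicationEvent(f"dup{i + 1:03d}", ms)
            for i, ms in enumerate(events)]


def classify_event(e: DuplicationEvent) -> str:
    """intra: one contig; inter: all contigs distinct; mixed otherwise."""
    contigs = [g.contig_id for g in e.members]
    if len(set(contigs)) == 1:
        kind = "intra"
    elif len(set(contigs)) == len(contigs):
        kind = "inter"
    else:
        kind = "mixed"
    e.kind = kind
    return kind


def _oriented_flanks(g: ORGene, genome: dict[str, GenomeSequence]
                     ) -> tuple[str, str]:
    """(upstream, downstream) genome sequence around the CDS, read along the
    coding strand; upstream is reversed so both read outward from the CDS."""
    seq = genome[g.contig_id].seq
    left = seq[:g.genomic_start]
    right = seq[g.genomic_end:]
    if g.strand == "-":
        left, right = revcomp(right), revcomp(left)
    # read outward: upstream right-to-left, downstream left-to-right
    return left[::-1], right


def duplication_span(e: DuplicationEvent,
                     genome: list[GenomeSequence]) -> dict:
    """Identical-segment length for every member pair: CDS length plus the
    maximal outward extension over which the flanks stay identical
    (stopping at N or a contig edge)."""
    gmap = {g.id: g for g in genome}
    flanks = {g.gene_id: _oriented_flanks(g, gmap) for g in e.members}
    spans = {}
    cds_len = len(e.members[0].cds)
    for i, a in enumerate(e.members):
        for b in e.members[i + 1:]:
            ext = 0
            for fa, fb in zip(flanks[a.gene_id], flanks[b.gene_id]):
                for ca, cb in zip(fa, fb):
                    if ca != cb or ca == "N":
                        break
                    ext += 1
                else:
                    logger.info("%s/%s: extension clipped at contig edge",
                                a.gene_id, b.gene_id)
            spans[(a.gene_id, b.gene_id)] = cds_len + ext
    e.spans = spans
    return spans


def analyze_duplications(genes: list[ORGene],
                         genome: list[GenomeSequence] | None = None
                         ) -> list[DuplicationEvent]:
    events = find_identical_cds(genes)
    for e in events:
        classify_event(e)
        if genome is not None:
            duplication_span(e, genome)
    return events


def duplication_summary(events: list[DuplicationEvent]) -> dict:
    """Event/copy bookkeeping across a set of duplication events.

    Counts follow the event = identical-CDS-group convention: an event with
    k members contributes k duplicated genes. Functional/pseudogene splits
    use the members' status labels.
    """
    n_events = len(events)
    kinds = pd.Series([e.kind for e in events]).value_counts().to_dict() \
        if events else {}
    func_genes = sum(e.copy_count for e in events
                     if all(g.status == "functional" for g in e.members))
    pseudo_genes = sum(e.copy_count for e in events
                       if any(g.status == "pseudogene" for g in e.members))
    pair_copies = sum(e.copy_count for e in events if e.copy_count == 2
                      and all(g.status == "functional" for g in e.members))
    return {
        "n_events": n_events,
        "by_kind": kinds,
        "duplicated_genes": sum(e.copy_count for e in events),
        "duplicated_functional_genes": func_genes,
        "duplicated_pseudogenes": pseudo_genes,
        "functional_pair_copies": pair_copies,
        "max_copy_count": max((e.copy_count for e in events), default=0),
    }


def events_table(events: list[DuplicationEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "group_id": e.group_id,
            "members": ",".join(g.gene_id for g in e.members),
            "copy_count": e.copy_count,
            "kind": e.kind,
            "spans": ";".join(f"{a}|{b}:{s}"
                              for (a, b), s in sorted(e.spans.items())),
        })
    return pd.DataFrame(rows)
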