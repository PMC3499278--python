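"""Family/subfamily assignment and systematic OR nomenclature.

Families and subfamilies are percent-identity groupings: a gene inherits
family and class (I/II) from its best labelled reference at >=40% identity;
genes matching no reference are grouped among themselves by single linkage
at 40% into novel families. Within each family, single linkage at 60%
defines subfamilies. Systematic names follow the `<prefix>OR<family>
<subfamily letter(s)><member>` scheme, with a terminal P for pseudogenes
and A/B/C suffixes distinguishing byte-identical duplicates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .align import percent_identity
from .orf_model import ORGene, ReferenceProtein
from .params import PipelineParams


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two protein sequences (global alignment,
    affine gaps, terminal-gap columns excluded)."""
    if not a or not b:
        raise ValueError("empty sequence")
    return percent_identity(a, b)


def identity_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix (diagonal 100)."""
    ids = list(seqs)
    m = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pid = pairwise_identity(seqs[a], seqs[b])
            m.loc[a, b] = m.loc[b, a] = pid
    return m


@dataclass
class Assignment:
    gene_id: str
    class_label: str | None
    family: int
    subfamily: str = ""
    member_index: int = 0
    name: str = ""
    duplicate_suffix: str | None = None


def natural_key(contig: str):
    return tuple(int(p) if p.isdigit() else p
                 for p in re.split(r"(\d+)", contig))


def genome_order_key(g: ORGene):
    return (natural_key(g.contig_id), g.genomic_start)


def subfamily_letters(i: int) -> str:
    """0 -> A ... 25 -> Z, 26 -> AA, 27 -> AB, ... (bijective base 26)."""
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def _single_linkage(ids: list[str], ident, threshold: float) -> list[set[str]]:
    """Connected components of the >=threshold identity graph."""
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if ident(a, b) >= threshold:
                g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def assign_taxonomy(genes: list[ORGene], refs: list[ReferenceProtein],
                    params: PipelineParams | None = None
                    ) -> dict[str, Assignment]:
    """Assign class, family and subfamily to every gene.

    Subfamily letters go by decreasing subfamily size, ties broken by the
    genome order of the first member. Novel families (no reference at or
    above the family threshold) are numbered after the largest reference
    family, ordered by the genome position of their first member.
    """
    params = params or PipelineParams()
    labelled = [r for r in refs if r.family is not None]
    genes = sorted(genes, key=genome_order_key)

    best_ref: dict[str, tuple[ReferenceProtein | None, float]] = {}
    for g in genes:
        best, best_pid = None, -1.0
        for r in labelled:
            pid = pairwise_identity(g.protein, r.aa_seq)
            if pid > best_pid:
                best, best_pid = r, pid
        best_ref[g.gene_id] = (best, best_pid)

    assignments: dict[str, Assignment] = {}
    novel: list[ORGene] = []
    for g in genes:
        ref, pid = best_ref[g.gene_id]
        if ref is not None and pid >= params.family_threshold:
            assignments[g.gene_id] = Assignment(g.gene_id, ref.class_label,
                                                ref.family)
        else:
            novel.append(g)

    if novel:
        seqs = {g.gene_id: g.protein for g in novel}
        cache: dict[frozenset, float] = {}

        def ident(a, b):
            key = frozenset((a, b))
            if key not in cache:
                cache[key] = pairwise_identity(seqs[a], seqs[b])
            return cache[key]

        comps = _single_linkage(list(seqs), ident, params.family_threshold)
        order = {g.gene_id: i for i, g in enumerate(genes)}
        comps.sort(key=lambda c: min(order[i] for i in c))
        next_family = max((r.family for r in labelled), default=0) + 1
        for comp in comps:
            for gid in sorted(comp, key=lambda i: order[i]):
                ref, _ = best_ref[gid]
                assignments[gid] = Assignment(
                    gid, ref.class_label if ref else None, next_family)
            next_family += 1

    # subfamilies: single linkage at the subfamily threshold within a family
    by_family: dict[int, list[ORGene]] = {}
    for g in genes:
        by_family.setdefault(assignments[g.gene_id].family, []).append(g)
    order = {g.gene_id: i for i, g in enumerate(genes)}
    for family, members in by_family.items():
        seqs = {g.gene_id: g.protein for g in members}
        cache = {}

        def ident(a, b):
            key = frozenset((a, b))
            if key not in cache:
                cache[key] = pairwise_identity(seqs[a], seqs[b])
            return cache[key]

        comps = _single_linkage(list(seqs), ident, params.subfamily_threshold)
        comps.sort(key=lambda c: (-len(c), min(order[i] for i in c)))
        for i, comp in enumerate(comps):
            letters = subfamily_letters(i)
            for gid in comp:
                assignments[gid].subfamily = letters
    return assignments


def assign_names(assignments: dict[str, Assignment], genes: list[ORGene],
                 species_prefix: str = "s",
                 duplicate_groups: list[list[str]] | None = None
                 ) -> dict[str, Assignment]:
    """Fill member indices and systematic names.

    Member indices run in genome order within each (family, subfamily);
    members of one exact-duplicate group share an index and take suffixes
    A, B, C... in genome order; pseudogenes take a terminal P before any
    duplicate suffix.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    group_of: dict[str, int] = {}
    for gi, grp in enumerate(duplicate_groups or []):
        for gid in grp:
            group_of[gid] = gi

    by_subfam: dict[tuple[int, str], list[ORGene]] = {}
    for g in genes:
        a = assignments[g.gene_id]
        by_subfam.setdefault((a.family, a.subfamily), []).append(g)

    for _, members in sorted(by_subfam.items()):
        members.sort(key=genome_order_key)
        index = 0
        seen_groups: dict[int, tuple[int, int]] = {}  # group -> (index, count)
        for g in members:
            a = assignments[g.gene_id]
            grp = group_of.get(g.gene_id)
            if grp is not None and grp in seen_groups:
                idx, count = seen_groups[grp]
                a.member_index = idx
                a.duplicate_suffix = subfamily_letters(count)
                seen_groups[grp] = (idx, count + 1)
            else:
                index += 1
                a.member_index = index
                if grp is not None:
                    a.duplicate_suffix = "A"
                    seen_groups[grp] = (index, 1)
            pseudo = "P" if gene_by_id[g.gene_id].status == "pseudogene" \
                else ""
            a.name = (f"{species_prefix}OR{a.family}{a.subfamily}"
                      f"{a.member_index}{pseudo}{a.duplicate_suffix or ''}")
    return assignments


def assignments_table(assignments: dict[str, Assignment],
                      genes: list[ORGene]) -> pd.DataFrame:
    rows = []
    for g in sorted(genes, key=genome_order_key):
        a = assignments[g.gene_id]
        rows.append({"gene_id": g.gene_id, "name": a.name,
                     "class": a.class_label, "family": a.family,
                     "subfamily": a.subfamily,
                     "member_index": a.member_index,
                     "status": g.status, "contig": g.contig_id,
                     "start": g.genomic_start, "end": g.genomic_end,
                     "strand": g.strand})
    return pd.DataFrame(rows)


def export_nj_tree(seqs: dict[str, str]) -> str:
    """Unrooted neighbour-joining tree (newick) on 100-identity distances.

    For inspection only; taxonomy is always assigned by the identity
    thresholds, never from this tree.
    """
    from Bio.Phylo.TreeConstruction import (DistanceMatrix,
                                            DistanceTreeConstructor)
    from io import StringIO
    from Bio import Phylo

    ids = list(seqs)
    m = identity_matrix(seqs)
    lower = [[float(100.0 - m.loc[a, b]) for b in ids[:i + 1]]
             for i, a in enumerate(ids)]
    for i in range(len(ids)):
        lower[i][i] = 0.0
    tree = DistanceTreeConstructor().nj(DistanceMatrix(ids, lower))
    buf = StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()
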