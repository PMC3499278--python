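"""Cross-species OR repertoire comparison.

Proteins from several species are clustered by connected components of the
>=60%-identity graph (species-blind); cluster composition yields
species-sharing tables and species-specific gene counts. Receptors with
annotated odorant specificity transfer their annotation to the
best-matching query gene when identity reaches the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .classify import pairwise_identity
from .params import PipelineParams


@dataclass
class CrossCluster:
    cluster_id: str
    members: list[tuple[str, str]]   # (species, gene id)

    @property
    def species_set(self) -> frozenset:
        return frozenset(s for s, _ in self.members)


@dataclass(frozen=True)
class SpecificityMatch:
    receptor_id: str
    receptor_species: str
    query_id: str | None
    identity: float
    odorant: str | None
    percept: str | None
    shared: bool


def cross_cluster(proteins: dict[str, dict[str, str]],
                  params: PipelineParams | None = None
                  ) -> list[CrossCluster]:
    """Cluster proteins from several species at the cross-species identity
    threshold.

    ``proteins`` maps species -> {gene id -> protein}; gene ids must be
    unique across species. Singletons form their own clusters. Clusters are
    ordered by size (largest first), then first member id.
    """
    params = params or PipelineParams()
    nodes: dict[str, tuple[str, str]] = {}
    for species, genes in proteins.items():
        for gid, seq in genes.items():
            if gid in nodes:
                raise ValueError(f"duplicate gene id across species: {gid}")
            nodes[gid] = (species, seq)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    ids = list(nodes)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if pairwise_identity(nodes[a][1], nodes[b][1]) \
                    >= params.crossref_threshold:
                g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [CrossCluster(f"xc{i + 1:04d}",
                         [(nodes[gid][0], gid) for gid in comp])
            for i, comp in enumerate(comps)]


def sharing_table(clusters: list[CrossCluster]) -> pd.DataFrame:
    """Per species-combination gene counts.

    One row per observed species combination; for each species column, the
    number of that species' genes lying in clusters whose species set equals
    the combination. Single-species rows are the species-specific counts.
    """
    species = sorted({s for c in clusters for s, _ in c.members})
    rows: dict[frozenset, dict] = {}
    for c in clusters:
        combo = c.species_set
        row = rows.setdefault(combo, {sp: 0 for sp in species})
        for sp, _ in c.members:
            row[sp] += 1
    out = []
    for combo in sorted(rows, key=lambda c: (-len(c), sorted(c))):
        rec = {"combination": "+".join(sorted(combo)),
               "n_species": len(combo)}
        rec.update(rows[combo])
        out.append(rec)
    return pd.DataFrame(out)


def species_specific_counts(clusters: list[CrossCluster]) -> dict[str, int]:
    """Genes confined to single-species clusters, per species."""
    counts: dict[str, int] = {}
    for c in clusters:
        if len(c.species_set) == 1:
            sp = next(iter(c.species_set))
            counts[sp] = counts.get(sp, 0) + len(c.members)
    return counts


def transfer_specificity(queries: dict[str, str], annotated,
                         params: PipelineParams | None = None
                         ) -> list[SpecificityMatch]:
    """Best query match for each specificity-annotated receptor.

    ``annotated`` is a list of ReferenceProtein records carrying odorant /
    percept fields. Every receptor is reported with its best-identity query
    gene; matches at or above the cross-species threshold are flagged as
    shared specificity, sub-threshold best hits stay listed unflagged.
    """
    params = params or PipelineParams()
    out: list[SpecificityMatch] = []
    for ref in annotated:
        best_id, best_pid = None, -1.0
        for qid, seq in queries.items():
            pid = pairwise_identity(seq, ref.aa_seq)
            if pid > best_pid or (pid == best_pid and qid < best_id):
                best_id, best_pid = qid, pid
        out.append(SpecificityMatch(
            receptor_id=ref.id, receptor_species=ref.species,
            query_id=best_id, identity=max(best_pid, 0.0),
            odorant=ref.odorant, percept=ref.percept,
            shared=best_pid >= params.crossref_threshold))
    out.sort(key=lambda m: -m.identity)
    return out


def specificity_table(matches: list[SpecificityMatch]) -> pd.DataFrame:
    return pd.DataFrame([{
        "receptor": m.receptor_id, "species": m.receptor_species,
        "query": m.query_id, "identity": round(m.identity),
        "odorant": m.odorant, "percept": m.percept, "shared": m.shared,
    } for m in matches])
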