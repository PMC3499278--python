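"""Positional OR gene clusters (1-Mb rule) and repertoire statistics.

Consecutive OR coding sequences on one contig belong to the same cluster
while the gap between the end of one CDS and the start of the next is at
most ``cluster_gap_bp`` (1 Mb by default; a strictly larger gap splits).
Clusters are named ``<chromosome>-<Mb offset of the cluster start>``.
Partial genes are excluded from clustering and repertoire statistics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .classify import Assignment, natural_key
from .orf_model import ORGene
from .params import PipelineParams


@dataclass
class GeneCluster:
    contig_id: str
    genes: list[ORGene]          # ordered by start
    name: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.genomic_start for g in self.genes),
                max(g.genomic_end for g in self.genes))

    @property
    def n_functional(self) -> int:
        return sum(1 for g in self.genes if g.status == "functional")

    @property
    def n_pseudo(self) -> int:
        return sum(1 for g in self.genes if g.status == "pseudogene")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to nearest with ties away from zero (table-style percentages)."""
    factor = 10 ** ndigits
    y = math.floor(abs(x) * factor + 0.5) / factor
    y = math.copysign(y, x)
    return y if ndigits > 0 else int(y)


def percent(numerator: float, denominator: float, ndigits: int = 0):
    """Percentage with half-away-from-zero rounding; 0 when denominator is 0."""
    if denominator == 0:
        return round_half_away(0.0, ndigits)
    return round_half_away(100.0 * numerator / denominator, ndigits)


def cluster_by_position(genes: list[ORGene],
                        params: PipelineParams | None = None
                        ) -> list[GeneCluster]:
    """Group non-partial genes into positional clusters per contig."""
    params = params or PipelineParams()
    kept = [g for g in genes if g.status != "partial"]
    by_contig: dict[str, list[ORGene]] = {}
    for g in kept:
        by_contig.setdefault(g.contig_id, []).append(g)

    clusters: list[GeneCluster] = []
    for contig in sorted(by_contig, key=natural_key):
        ordered = sorted(by_contig[contig], key=lambda g: g.genomic_start)
        current = [ordered[0]]
        for g in ordered[1:]:
            if g.genomic_start - current[-1].genomic_end \
                    > params.cluster_gap_bp:
                clusters.append(GeneCluster(contig, current))
                current = [g]
            else:
                current.append(g)
        clusters.append(GeneCluster(contig, current))

    names: dict[str, int] = {}
    for c in clusters:
        base = name_cluster(c)
        if base in names:
            names[base] += 1
            c.name = f"{base}.{names[base]}"
        else:
            names[base] = 1
            c.name = base
    return clusters


def name_cluster(c: GeneCluster) -> str:
    """``<chromosome>-<Mb>``: chromosome identifier (a leading "chr" prefix
    is stripped) plus the Mb floor of the cluster start."""
    label = re.sub(r"^chr(?=.)", "", c.contig_id, flags=re.IGNORECASE)
    return f"{label}-{c.span[0] // 1_000_000}"


def _is_placed(contig_id: str) -> bool:
    """Contigs that look like chromosomes count as placed; everything else
    is pooled under the unplaced label 'U'."""
    label = re.sub(r"^chr(?=.)", "", contig_id, flags=re.IGNORECASE)
    return bool(re.fullmatch(r"\d+|[XYZW]", label))


def chromosome_label(contig_id: str) -> str:
    if not _is_placed(contig_id):
        return "U"
    return re.sub(r"^chr(?=.)", "", contig_id, flags=re.IGNORECASE)


def per_chromosome_table(genes: list[ORGene],
                         assignments: dict[str, Assignment] | None = None
                         ) -> pd.DataFrame:
    """Per-chromosome functional/pseudogene counts, pseudogene percentage
    and subfamily counts; unplaced contigs pool under 'U'."""
    rows: dict[str, dict] = {}
    for g in genes:
        if g.status == "partial":
            continue
        label = chromosome_label(g.contig_id)
        r = rows.setdefault(label, {"chromosome": label, "functional": 0,
                                    "pseudogenes": 0, "subfamilies": set()})
        if g.status == "functional":
            r["functional"] += 1
        else:
            r["pseudogenes"] += 1
        if assignments and g.gene_id in assignments:
            a = assignments[g.gene_id]
            r["subfamilies"].add((a.family, a.subfamily))
    out = []
    for label in sorted(rows, key=natural_key):
        r = rows[label]
        total = r["functional"] + r["pseudogenes"]
        out.append({"chromosome": label, "functional": r["functional"],
                    "pseudogenes": r["pseudogenes"],
                    "pseudo_pct": percent(r["pseudogenes"], total),
                    "total": total, "subfamilies": len(r["subfamilies"])})
    return pd.DataFrame(out)


def stats_from_counts(functional: int, pseudo: int) -> dict:
    """Repertoire-level percentages from raw counts."""
    total = functional + pseudo
    return {"functional": functional, "pseudogenes": pseudo, "total": total,
            "functional_pct": percent(functional, total),
            "pseudo_pct": percent(pseudo, total)}


def cluster_composition_stats(clusters_per_subfamily: pd.Series,
                              subfamilies_per_cluster: pd.Series) -> dict:
    """Cross-tabulation summaries of the subfamily/cluster incidence.

    ``clusters_per_subfamily`` maps each subfamily to the number of distinct
    positional clusters its genes occupy; ``subfamilies_per_cluster`` maps
    each cluster to its number of distinct subfamilies.
    """
    n_subfam = len(clusters_per_subfamily)
    n_clusters = len(subfamilies_per_cluster)
    single_cluster = int((clusters_per_subfamily == 1).sum())
    single_subfam = int((subfamilies_per_cluster == 1).sum())
    return {
        "n_subfamilies": n_subfam,
        "n_clusters": n_clusters,
        "single_cluster_subfamilies": single_cluster,
        "single_cluster_subfamily_pct":
            percent(single_cluster, n_subfam, 1),
        "single_subfamily_clusters": single_subfam,
        "single_subfamily_cluster_pct": percent(single_subfam, n_clusters),
        "multi_subfamily_clusters": n_clusters - single_subfam,
        "multi_subfamily_cluster_pct":
            percent(n_clusters - single_subfam, n_clusters),
    }


def repertoire_stats(genes: list[ORGene], clusters: list[GeneCluster],
                     assignments: dict[str, Assignment]) -> dict:
    """Full repertoire summary: per-chromosome table, per-cluster
    histograms, subfamily/cluster incidence and overall percentages."""
    kept = [g for g in genes if g.status != "partial"]
    per_chrom = per_chromosome_table(kept, assignments)

    func_per_cluster = pd.Series(
        [c.n_functional for c in clusters],
        index=[c.name for c in clusters], dtype=int)
    cluster_of: dict[str, str] = {}
    for c in clusters:
        for g in c.genes:
            cluster_of[g.gene_id] = c.name

    subfam_clusters: dict[tuple[int, str], set[str]] = {}
    for g in kept:
        a = assignments[g.gene_id]
        if g.gene_id in cluster_of:
            subfam_clusters.setdefault((a.family, a.subfamily),
                                       set()).add(cluster_of[g.gene_id])
    clusters_per_subfamily = pd.Series(
        {k: len(v) for k, v in sorted(subfam_clusters.items())}, dtype=int)
    subfamilies_per_cluster = pd.Series(
        {c.name: len({(assignments[g.gene_id].family,
                       assignments[g.gene_id].subfamily)
                      for g in c.genes}) for c in clusters}, dtype=int)

    n_functional = sum(1 for g in kept if g.status == "functional")
    n_pseudo = sum(1 for g in kept if g.status == "pseudogene")
    mapped = sum(1 for g in kept if _is_placed(g.contig_id))

    return {
        "per_chromosome": per_chrom,
        "functional_per_cluster": func_per_cluster,
        "clusters_per_subfamily": clusters_per_subfamily,
        "subfamilies_per_cluster": subfamilies_per_cluster,
        "overall": stats_from_counts(n_functional, n_pseudo),
        "composition": cluster_composition_stats(
            clusters_per_subfamily, subfamilies_per_cluster)
        if len(clusters_per_subfamily) else {},
        "mapped_genes": mapped,
        "unplaced_genes": len(kept) - mapped,
        "n_clusters": len(clusters),
        "n_chromosomes_with_genes": int(
            (per_chrom["chromosome"] != "U").sum()) if len(per_chrom) else 0,
    }


def clusters_table(clusters: list[GeneCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        lo, hi = c.span
        rows.append({"name": c.name, "contig": c.contig_id, "start": lo,
                     "end": hi, "n_genes": len(c.genes),
                     "n_functional": c.n_functional,
                     "n_pseudo": c.n_pseudo})
    return pd.DataFrame(rows)
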