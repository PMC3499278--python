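"""One-shot OR mining pipeline: scan -> annotate -> classify -> clusters ->
duplicates, with a stage-by-stage funnel report.

The funnel mirrors how a repertoire shrinks from raw candidate regions to
the final gene set: candidate regions found, low-confidence regions set
aside, non-OR and redundant models removed, partial fragments excluded, and
the functional/pseudogene totals that remain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import (assign_names, assign_taxonomy, assignments_table,
                       genome_order_key)
from .duplication import analyze_duplications, duplication_summary, events_table
from .genome_io import (GenomeSequence, read_genome, read_reference_proteins,
                        six_frame_translate, write_fasta, write_outputs)
from .genome_clusters import (cluster_by_position, clusters_table,
                              repertoire_stats)
from .motif_scan import build_candidate_regions, scan_frames
from .orf_model import (ORGene, ReferenceProtein, classify_gene,
                        dedupe_candidates, motif_presence,
                        motif_profile_summary, reconstruct_orf,
                        select_reference)
from .params import PipelineParams

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_path: str | Path
    ref_proteins_path: str | Path
    out_dir: str | Path
    species_prefix: str = "s"
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        for p in (self.genome_path, self.ref_proteins_path):
            if not Path(p).is_file():
                raise FileNotFoundError(f"input does not exist: {p}")


@dataclass
class AnalysisResult:
    genome: list[GenomeSequence]
    refs: list[ReferenceProtein]
    hits: list
    regions: list
    genes: list[ORGene]          # final non-partial set, genome order
    partials: list[ORGene]
    removed: list
    assignments: dict
    clusters: list
    events: list
    stats: dict
    funnel: dict


def analyze(genome: list[GenomeSequence], refs: list[ReferenceProtein],
            params: PipelineParams | None = None,
            species_prefix: str = "s") -> AnalysisResult:
    """Run the full analysis in memory."""
    params = params or PipelineParams()
    funnel: dict[str, int] = {}

    frames = [f for g in genome for f in six_frame_translate(g)]
    hits = scan_frames(frames, params)
    funnel["motif_hits"] = len(hits)

    regions = build_candidate_regions(hits, genome, params)
    funnel["candidate_regions"] = len(regions)

    models: list[ORGene] = []
    low_conf = 0
    for region in regions:
        ref, pid = select_reference(region, refs)
        if pid < params.min_ref_identity:
            low_conf += 1
            logger.info("%s: best identity %.1f%% below reconstruction "
                        "floor, skipped", region.name, pid)
            continue
        gene = reconstruct_orf(region, ref, pid, params)
        classify_gene(gene, params)
        motif_presence(gene, params)
        models.append(gene)
    funnel["low_confidence_skipped"] = low_conf
    funnel["reconstructed_models"] = len(models)

    kept, removed = dedupe_candidates(models, params)
    funnel["removed_non_or"] = sum(1 for _, r in removed
                                   if r == "non_or_identity_floor")
    funnel["removed_overlap"] = sum(1 for _, r in removed
                                    if r == "overlap_lower_identity")

    partials = [g for g in kept if g.status == "partial"]
    genes = [g for g in kept if g.status != "partial"]
    genes.sort(key=genome_order_key)
    funnel["partial_excluded"] = len(partials)
    funnel["or_genes"] = len(genes)
    funnel["functional"] = sum(1 for g in genes if g.status == "functional")
    funnel["pseudogenes"] = sum(1 for g in genes if g.status == "pseudogene")

    assignments = assign_taxonomy(genes, refs, params)
    events = analyze_duplications(genes, genome)
    assign_names(assignments, genes, species_prefix,
                 [[g.gene_id for g in e.members] for e in events])
    clusters = cluster_by_position(genes, params)
    stats = repertoire_stats(genes, clusters, assignments)
    stats["motif_profiles"] = motif_profile_summary(genes)
    stats["duplication"] = duplication_summary(events)

    return AnalysisResult(genome, refs, hits, regions, genes, partials,
                          removed, assignments, clusters, events, stats,
                          funnel)


def hits_table(hits) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": h.contig_id, "frame": h.frame, "motif": h.motif_name,
        "aa_start": h.aa_start, "mismatches": h.n_mismatch,
        "start": h.genomic_start, "end": h.genomic_end,
    } for h in hits])


def regions_table(regions) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": r.name, "contig": r.contig_id, "start": r.genomic_start,
        "end": r.genomic_end, "strand": r.strand,
        "motifs": ",".join(sorted({h.motif_name for h in r.hits})),
    } for r in regions])


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    """Run the pipeline from files and persist every stage's outputs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = read_genome(cfg.genome_path)
    refs = read_reference_proteins(cfg.ref_proteins_path)
    res = analyze(genome, refs, cfg.params, cfg.species_prefix)

    hits_table(res.hits).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    regions_table(res.regions).to_csv(out / "candidate_regions.tsv",
                                      sep="\t", index=False)
    write_fasta(out / "candidate_regions.fa",
                ((r.name, r.seq) for r in res.regions))

    write_outputs(res.genes, out, res.assignments)
    if res.partials:
        write_outputs(res.partials, out / "partials")
    assignments_table(res.assignments, res.genes).to_csv(
        out / "assignments.tsv", sep="\t", index=False)
    clusters_table(res.clusters).to_csv(out / "clusters.tsv", sep="\t",
                                        index=False)
    with open(out / "clusters.bed", "w") as fh:
        for c in res.clusters:
            lo, hi = c.span
            fh.write(f"{c.contig_id}\t{lo}\t{hi}\t{c.name}\n")
    events_table(res.events).to_csv(out / "duplications.tsv", sep="\t",
                                    index=False)
    res.stats["per_chromosome"].to_csv(out / "per_chromosome.tsv", sep="\t",
                                       index=False)
    write_report(res, out / "run_report.json", out / "run_report.tsv")
    return res


def _flatten(d: dict, prefix: str = "") -> dict:
    flat = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, key + "."))
        elif isinstance(v, (int, float, str, bool)):
            flat[key] = v
    return flat


def write_report(res: AnalysisResult, json_path: Path,
                 tsv_path: Path) -> None:
    report = {
        "funnel": res.funnel,
        "overall": res.stats["overall"],
        "mapped_genes": res.stats["mapped_genes"],
        "unplaced_genes": res.stats["unplaced_genes"],
        "n_clusters": res.stats["n_clusters"],
        "composition": res.stats.get("composition", {}),
        "duplication": {k: v for k, v in res.stats["duplication"].items()
                        if not isinstance(v, dict)},
        "duplication_by_kind": res.stats["duplication"]["by_kind"],
        "motif_profiles": {
            "n": res.stats["motif_profiles"]["n"],
            "all_three": res.stats["motif_profiles"]["all_three"],
            "pct_all_three": res.stats["motif_profiles"].get(
                "pct_all_three", 0.0),
        },
    }
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    flat = _flatten(report)
    with open(tsv_path, "w") as fh:
        fh.write("key\tvalue\n")
        for k in sorted(flat):
            fh.write(f"{k}\t{flat[k]}\n")
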