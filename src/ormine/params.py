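"""Pipeline-wide parameter set.

All thresholds that drive OR gene discovery and downstream repertoire
analysis live in one frozen dataclass so that a run is fully described by
(inputs, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class PipelineParams:
    """Tunable constants of the OR-mining pipeline.

    motif_max_diff
        Maximum tolerated mismatch fraction when matching a conserved motif
        (strict ``<``): 0.5 means a 10-mer motif may carry up to 4 mismatches.
    min_motifs_per_region
        Distinct TM motifs (TM3/TM6/TM7; the short GN motif never counts)
        required inside one window before it becomes a candidate region.
    flank_bp / region_len_bp
        Flank taken on each side of a motif-hit span midpoint, and the
        resulting nominal candidate-region length (2 * flank_bp).
    min_functional_aa
        Minimum reconstructed protein model length for a locus to be a
        full-length OR (functional or pseudogene); shorter models are partial.
    min_ref_identity
        Floor (percent) on best reference identity below which ORF
        reconstruction is not attempted for a region.
    non_or_floor
        Percent identity to the best OR reference below which a reconstructed
        model is discarded as non-OR.
    family_threshold / subfamily_threshold
        Percent amino-acid identity cut-offs separating OR families (40) and
        subfamilies (60).
    cluster_gap_bp
        Maximum gap between consecutive coding sequences within one genomic
        OR cluster (1 Mb; strictly larger gaps split clusters).
    crossref_threshold
        Percent identity for cross-species clustering and odorant-specificity
        transfer (60).
    start_search_codons
        How far (codons, in-frame, either direction) to search for an ATG
        around the reference-projected N terminus.
    """

    motif_max_diff: float = 0.5
    min_motifs_per_region: int = 2
    flank_bp: int = 1_000
    region_len_bp: int = 2_000
    min_functional_aa: int = 300
    min_ref_identity: float = 30.0
    non_or_floor: float = 40.0
    family_threshold: float = 40.0
    subfamily_threshold: float = 60.0
    cluster_gap_bp: int = 1_000_000
    crossref_threshold: float = 60.0
    start_search_codons: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.motif_max_diff <= 1.0):
            raise ValueError("motif_max_diff must be in (0, 1]")
        for name in ("family_threshold", "subfamily_threshold",
                     "crossref_threshold", "non_or_floor", "min_ref_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ValueError(f"{name} must be in (0, 100]")
        if self.family_threshold >= self.subfamily_threshold:
            raise ValueError("family_threshold must be < subfamily_threshold")
        for name in ("flank_bp", "region_len_bp", "cluster_gap_bp",
                     "min_functional_aa", "min_motifs_per_region"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_overrides(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)

    @classmethod
    def from_config(cls, path: str | Path, **overrides) -> "PipelineParams":
        """Read ``key = value`` lines; '#' starts a comment; overrides win."""
        values: dict = {}
        ftypes = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in ftypes:
                raise ValueError(f"unknown parameter: {key}")
            values[key] = casts[ftypes[key]](val)
        values.update(overrides)
        return cls(**values)
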