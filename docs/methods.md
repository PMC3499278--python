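# Methods

## Scope and model

`ormine` mines olfactory-receptor (OR) genes from a genome assembly under
the standard assumptions of OR subgenome studies: OR genes are intronless
single-exon loci of roughly 310 codons; intact OR proteins carry four short
conserved peptides — GN near residue 60, `MAYDRYVAIC` (TM3) near 121,
`KAFSTCASH` (TM6) near 239 and `PMLNPFIY` (TM7) near 284; degenerate copies
of these motifs survive in pseudogenes. Every stage is deterministic given
its inputs and the pipeline seed.

Internal coordinates are 0-based, half-open, forward-strand throughout;
conversion to 1-based inclusive happens only at the GFF3 writer. This keeps
a single convention across the scanner, the ORF model and the genomic
clustering, and confines off-by-one conversions to one function that is
tested against its BED counterpart.

## Motif scanning

Each contig is translated in all six frames (standard genetic code; codons
containing N render `X`; stops render `*`). Every window of each motif's
length is scored by Hamming mismatch fraction, with `X` and `*` counting as
mismatches, and reported when the fraction is strictly below
`motif_max_diff` (default 0.5, i.e. up to 4 mismatches in the 10-mer TM3).
"Sequence difference" is read as substitution-only distance: the motifs are
too short for internal indels to be identifiable, and a Hamming scan is
exhaustive and exactly reproducible, which a heuristic local aligner is not.
N-runs and assembly gaps translate to `X` and therefore can never match.

A candidate region needs at least two *distinct* motifs among TM3/TM6/TM7
within one ~2-kb window on one strand, in the canonical TM3 < TM6 < TM7
order along the direction of translation. The order constraint suppresses
chimeric windows; hits from different frames of the same strand may
co-qualify so that frameshifted pseudogenes are still found. GN is recorded
for reporting but never counts: two residues carry almost no specificity.
The region spans `flank_bp` (1 kb) each side of the qualifying hit-span
midpoint, clipped at contig edges; overlapping same-strand windows merge
with the union of their hits.

## Reference selection and ORF reconstruction

Protein comparisons use Biopython's `PairwiseAligner` with BLOSUM62 and
affine gaps (open −10, extend −0.5), global mode with end gaps charged.
Percent identity is identical columns over aligned columns, excluding
terminal-gap columns (internal gap columns count in the denominator). End
gaps must be charged: with free end gaps on both sequences, the optimal
"global" alignment of two unrelated ORs collapses onto their shared
conserved motifs and reports spuriously perfect identity over that stretch.

Each region's three reading frames (on its strand) are aligned to every
reference; the reference with the highest identity wins, ties broken by
longer alignment, then lexicographic id. Reconstruction then aligns that
reference protein directly against the region DNA with a frameshift-aware
local dynamic program (numba-compiled): a reference residue normally
consumes a 3-bp codon scored by BLOSUM62, or 2/4 bp at a frameshift penalty
(−12); unmatched residues/codons cost −11 (linear gaps — affine gain is
negligible at these divergences and the traceback stays simple). The coding
path gives:

* **start** — the in-frame ATG nearest the reference-projected N terminus,
  searched outward up to 30 codons, upstream preferred on ties; if none is
  found the model anchors at the alignment start and is flagged `no_start`
  (upstream-only search: a downstream ATG would require trimming the
  aligned path and never occurs in practice when the reference set is
  adequate);
* **end** — the first in-frame stop at/after the aligned C terminus; absence
  flags `no_stop`;
* **disruptions** — every 2/4-bp step is a frameshift, every `*` in the
  model a premature stop, each with its CDS offset.

The model length used for classification is the reference-spanned length
(chosen start through the last reference-aligned codon). Measuring
pseudogenes on this "repaired" model is deliberate: a premature stop would
otherwise shrink every pseudogene below the 300-aa floor and the
length-plus-disruption definition would be vacuous.

The best-reference identity stored on a gene is the maximum of the
frame-translation identity and the identity of the stitched model protein —
the latter is the fair measure for frameshifted loci, whose single-frame
translations are garbled downstream of the lesion.

## Classification and filtering

* functional: model ≥ `min_functional_aa` (300, inclusive — the boundary is
  tested explicitly) and an intact ORF (no disruptions, ATG start, terminal
  stop);
* pseudogene: model ≥ 300 but disrupted (premature stop, frameshift, or an
  unrecoverable start/stop);
* partial: model < 300. Partial loci are reported but excluded from
  repertoire statistics, clustering, naming and duplication analysis.

Models whose best reference identity falls below `non_or_floor` (40%) are
discarded as non-OR GPCR look-alikes — an identity floor against the OR
reference set stands in for a negative GPCR database, and each removal is
logged. Overlapping same-strand models collapse to the highest-identity one.

## Taxonomy and nomenclature

A gene inherits family and class (I/II) from its best labelled reference at
≥ `family_threshold` (40%) identity. Genes matching no reference group among
themselves by single linkage at 40% into novel families numbered after the
largest reference family (novel numbering appends rather than re-using any
external numbering). Within each family, single linkage at
`subfamily_threshold` (60%) defines subfamilies; letters go by decreasing
subfamily size, ties by the genome position of the first member, and extend
bijectively beyond Z (AA, AB, …). Single linkage is the graph-connected-
components reading of "everything above the cutoff clusters together", and
it is what the cross-species clustering uses too, so one engine serves both.
An unrooted neighbour-joining tree (newick, distances 100 − identity) can be
exported for inspection; it never drives assignment — threshold grouping is
deterministic and testable, a bootstrapped tree is neither.

Names are `<prefix>OR<family><subfamily letters><member>`: member indices
run in genome order (natural contig sort, then start); pseudogenes take a
terminal `P`; members of an exact-duplicate group share one index and take
suffixes `A`, `B`, `C`, … in genome order (extended alphabetically and
logged if a group ever exceeds three copies).

## Clusters, duplications, cross-species comparison, patterns

Positional clusters follow the 1-Mb rule: a new cluster starts when the gap
from the previous CDS end to the next CDS start strictly exceeds
`cluster_gap_bp`; a gap of exactly 1 Mb stays together. The gap is measured
between CDS extents, not midpoints. Clusters are named
`<chromosome>-<Mb floor of the cluster start>`; name collisions take `.2`,
`.3` suffixes. Unplaced contigs (anything not matching a chromosome-like
name) pool under "U" in per-chromosome tables. Percentages round half away
from zero, matching the conventional table style.

A duplication event is one group of ≥2 genes with byte-identical coding
sequences on the coding strand (orientation-normalised, so opposite-strand
copies match). One group = one event; a triplet is a single event of copy
count 3. Events are intra-chromosomal (one contig), inter-chromosomal (all
distinct) or mixed. The duplicated-segment span for each member pair extends
outward base-by-base from the CDS while the flanks agree, stopping at N or
a contig edge — a greedy exact measure of the identical segment.

Cross-species clusters are connected components of the ≥
`crossref_threshold` (60%) identity graph over all proteins regardless of
species; sharing tables count each species' genes per species-combination,
single-species clusters give species-specific counts. Markov clustering
would add an inflation parameter and stochastic convergence for no benefit
at this cutoff-driven contract; components are the deterministic reading.
Specificity transfer reports, for every receptor with annotated
odorant/percept, the best-identity query gene, flagging matches at/above
the same 60% threshold; sub-threshold best hits stay listed unflagged.

Position profiles report per-column residue frequencies (no pseudocounts)
and information content: log2(20) minus the Shannon entropy of the non-gap
residues, scaled by the non-gap fraction. Pattern induction is per-column
and deterministic: one residue at ≥ `conservation_min` (0.9) frequency →
fixed element; 2–3 residues jointly ≥ the threshold → bracketed set
(alphabetical); otherwise wildcard; runs of ≥2 wildcard columns with
variable gap content collapse to `x(m,n)` with m/n the min/max ungapped run
lengths. `X` in published patterns is parsed as a wildcard, per PROSITE
convention. Matching compiles the pattern to a regex inside a lookahead so
overlapping occurrences are all reported. This is not a branch-and-bound
pattern search; it induces the consensus pattern of an alignment region,
which is what validating published-style patterns requires.

## Synthetic benchmark

The generator plants reverse-translated OR templates (uniform synonymous
codon choice — codon bias is irrelevant to the nucleotide-level logic being
tested) in uniform-random intergenic DNA over several contigs and both
strands. Defaults are the benchmark conditions used throughout the tests:
100 genes, 15% pseudogenes (1–3 premature stops or ±1-bp frameshifts each,
placed ≥30 codons from either end), 10% partials (truncated to 250–299
codons, long enough to keep two motifs so the fragments remain findable),
2% amino-acid mutation rate (the initial methionine is kept — start-codon
conservation), five duplicate pairs plus one triplet inside identical
segments of 3–6 kb with divergence forced at the segment boundaries (so
measured spans equal the planted segment exactly), intergenic gaps of
2–8 kb, 4 contigs, 5 template families (each family is one template, so
subfamily structure is simple by construction). Mutation counts per status
are exact (`round(frac·n)`), not binomial, so planted compositions are
reproducible statements, and everything derives from one seeded generator.

What the generator does *not* emulate: repeats, GC heterogeneity, assembly
gaps, non-OR GPCR decoys, codon bias, or realistic intergenic composition.
Passing the benchmark therefore demonstrates the correctness of the
scanning/reconstruction/classification logic under the stated mutation
model, not performance on a real assembly; on real data the binding
constraints are reference-set coverage and the non-OR identity floor.

Recovery scoring matches predictions to planted genes by reciprocal ≥50%
interval overlap on the same contig and strand (any fixed convention works;
this one is symmetric and strict enough that a match implies the same
locus), then scores per-status precision/recall, a confusion table and
exact-status recall. Residual benchmark misclassifications are boundary
partials (249–299 codons planted; local-alignment end wobble of a few
codons can push a 298-codon fragment over the 300 floor when random
downstream DNA happens to extend the alignment).

## Numerical and degenerate-input choices

* Thresholds on identity and mismatch fractions are compared with ≥ (and
  the motif scan with strict <, as the 50%-difference rule states).
* Tie-breaks are total and documented: reference selection (identity, then
  aligned length, then id), subfamily letters (size, then genome order),
  cluster and event numbering (genome order) — two runs on the same input
  are byte-identical.
* Contigs shorter than 3 bp translate to empty frames; empty gene sets
  produce headers-only outputs and all-zero statistics; an empty reference
  set or an empty alignment is a hard error.
* Genome sizes in tests and the acceptance benchmark (~0.7 Mb, 107 loci)
  were chosen so the whole suite exercises every stage end-to-end in well
  under a minute per run on one CPU.

## Known limitations

* Splice variants and multi-exon edge cases are out of scope: the model is
  single-exon by construction.
* The non-OR filter is an identity floor, not a negative database; highly
  diverged true ORs below 40% to the supplied references are dropped.
* Start-codon choice ("nearest the projected N terminus") is a heuristic;
  ±1-codon start differences against an external annotation are possible.
* The duplicated-segment span is a lower-bound exact measure; it does not
  model near-identical segmental duplications (<100% CDS identity), which
  are outside the exact-duplication definition used here.
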