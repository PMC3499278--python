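"""ORF reconstruction and status classification."""

import numpy as np
import pytest

from ormine.genome_io import GenomeSequence, revcomp, six_frame_translate
from ormine.motif_scan import build_candidate_regions, scan_frames
from ormine.orf_model import (ORGene, ReferenceProtein, classify_gene,
                              dedupe_candidates, motif_presence,
                              motif_profile_summary, select_reference,
                              reconstruct_orf)
from ormine.params import PipelineParams
from ormine.synthetic import make_or_template, reverse_translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def template():
    return make_or_template("II", np.random.default_rng(5), length=310)


def region_for(cds, rng, strand="+", flank=600):
    """Wrap a CDS in random flanks and run the scanning front end."""
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
    block = cds if strand == "+" else revcomp(cds)
    g = GenomeSequence("c1", left + block + right)
    hits = scan_frames(six_frame_translate(g))
    regions = [r for r in build_candidate_regions(hits, [g])
               if r.strand == strand]
    assert len(regions) == 1
    return regions[0], g


class TestSelectReference:
    def test_exact_copy_scores_100(self, template, rng):
        cds = reverse_translate(template, rng) + "TAA"
        region, _ = region_for(cds, rng)
        refs = [ReferenceProtein("R1", template),
                ReferenceProtein("R2", make_or_template(
                    "I", np.random.default_rng(99)))]
        best, pid = select_reference(region, refs)
        assert best.id == "R1"
        assert pid == pytest.approx(100.0, abs=0.5)

    def test_tie_breaks_toward_longer_alignment_then_id(self, template, rng):
        cds = reverse_translate(template, rng) + "TAA"
        region, _ = region_for(cds, rng)
        # a truncated copy aligns shorter at the same identity
        refs = [ReferenceProtein("Rshort", template[:200]),
                ReferenceProtein("Rfull", template)]
        best, _ = select_reference(region, refs)
        assert best.id == "Rfull"
        # exact duplicates of one reference: lexicographic id wins
        refs = [ReferenceProtein("Rb", template),
                ReferenceProtein("Ra", template)]
        best, _ = select_reference(region, refs)
        assert best.id == "Ra"

    def test_decoy_region_scores_low(self, template, rng):
        decoy_protein = "".join(AA20[i] for i in rng.integers(0, 20, size=310))
        cds = reverse_translate(decoy_protein, rng) + "TAA"
        left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        g = GenomeSequence("c1", left + cds + left)
        from ormine.motif_scan import CandidateRegion
        region = CandidateRegion("c1", 0, g.length, "+", [], g.seq)
        _, pid = select_reference(region, [ReferenceProtein("R1", template)])
        assert pid < 40.0

    def test_empty_reference_set_rejected(self, template, rng):
        cds = reverse_translate(template, rng) + "TAA"
        region, _ = region_for(cds, rng)
        with pytest.raises(ValueError):
            select_reference(region, [])


class TestReconstructOrf:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_intact_gene(self, template, rng, strand):
        cds = reverse_translate(template, rng) + "TAA"
        region, g = region_for(cds, rng, strand=strand)
        ref = ReferenceProtein("R1", template)
        gene = reconstruct_orf(region, ref, 100.0)
        classify_gene(gene)
        assert gene.status == "functional"
        assert gene.disruptions == []
        assert gene.model_length == 310
        assert gene.cds == cds
        assert gene.genomic_end - gene.genomic_start == len(cds)
        assert gene.protein == template

    def test_single_deletion_is_a_frameshift_near_the_lesion(self, template,
                                                             rng):
        cds = reverse_translate(template, rng) + "TAA"
        damaged = cds[:450] + cds[451:]  # delete one base at codon 150
        region, _ = region_for(damaged, rng)
        gene = reconstruct_orf(region, ReferenceProtein("R1", template), 95.0)
        classify_gene(gene)
        fs = [d for d in gene.disruptions if d.kind == "frameshift"]
        assert len(fs) == 1
        assert abs(fs[0].cds_offset - 450) <= 9
        assert gene.status == "pseudogene"
        assert gene.model_length >= 300

    def test_premature_stop_at_planted_codon(self, template, rng):
        cds = reverse_translate(template, rng) + "TAA"
        damaged = cds[:297] + "TGA" + cds[300:]  # codon 100 -> stop
        region, _ = region_for(damaged, rng)
        gene = reconstruct_orf(region, ReferenceProtein("R1", template), 95.0)
        classify_gene(gene)
        stops = [d for d in gene.disruptions if d.kind == "premature_stop"]
        assert len(stops) == 1
        assert 297 <= stops[0].cds_offset <= 299
        assert gene.status == "pseudogene"


class TestClassifyBoundary:
    """The 300-aa boundary and the disruption rules, exhaustively around
    the threshold."""

    @pytest.mark.parametrize("model_len", [298, 299, 300, 301, 302])
    @pytest.mark.parametrize("n_disruptions", [0, 1])
    def test_trichotomy(self, model_len, n_disruptions):
        from ormine.orf_model import Disruption
        g = ORGene("g", "c", 0, 3 * model_len, "+", "", "A" * model_len,
                   model_len,
                   [Disruption("premature_stop", 30)] * n_disruptions,
                   [], "r", 95.0)
        status = classify_gene(g)
        if model_len < 300:
            assert status == "partial"
        elif n_disruptions:
            assert status == "pseudogene"
        else:
            assert status == "functional"

    @pytest.mark.parametrize("kind", ["premature_stop", "frameshift"])
    def test_any_disruption_kind_pseudogenizes(self, kind):
        from ormine.orf_model import Disruption
        g = ORGene("g", "c", 0, 900, "+", "", "A" * 305, 305,
                   [Disruption(kind, 150)], [], "r", 95.0)
        assert classify_gene(g) == "pseudogene"

    def test_missing_start_blocks_functional(self):
        g = ORGene("g", "c", 0, 900, "+", "", "A" * 305, 305, [],
                   ["no_start"], "r", 95.0)
        assert classify_gene(g) == "pseudogene"

    def test_statuses_are_exclusive_and_exhaustive(self, bench):
        syn, res = bench
        for g in res.genes + res.partials:
            assert g.status in ("functional", "pseudogene", "partial")
            assert (g.status == "partial") == (g.model_length < 300)
            if g.status == "functional":
                assert not g.disruptions
                assert "*" not in g.protein

    def test_functional_cds_is_a_clean_orf(self, bench):
        from ormine.genome_io import STOP_CODONS, translate_dna
        syn, res = bench
        for g in res.genes:
            if g.status != "functional":
                continue
            assert g.cds.startswith("ATG")
            assert g.cds[-3:] in STOP_CODONS
            assert len(g.cds) % 3 == 0
            assert "*" not in translate_dna(g.cds[:-3])


class TestMotifPresence:
    def _gene(self, protein):
        return ORGene("g", "c", 0, 3 * len(protein), "+", "", protein,
                      len(protein), [], [], "r", 95.0, "functional")

    def test_intact_template_has_all_motifs(self, template):
        prof = motif_presence(self._gene(template))
        assert all(prof[m] for m in ("GN", "TM3", "TM6", "TM7"))

    def test_scrambled_tm6_is_reported_missing(self, template, rng):
        scrambled = (template[:238]
                     + "".join(AA20[i] for i in rng.integers(0, 20, size=9))
                     + template[247:])
        prof = motif_presence(self._gene(scrambled))
        assert prof["TM3"] and prof["TM7"]
        # the random 9-mer may still weakly match; require what was planted
        assert not prof["TM6"] or scrambled[238:247] != template[238:247]

    def test_summary_counts(self, template):
        genes = [self._gene(template), self._gene(template)]
        s = motif_profile_summary(genes)
        assert s["n"] == 2 and s["all_three"] == 2
        assert s["pct_all_three"] == 100.0
        assert motif_profile_summary([]) == {
            "n": 0, "all_three": 0,
            "missing": {"TM3": 0, "TM6": 0, "TM7": 0}, "other": 0}


class TestDedupe:
    def _gene(self, gid, start, end, strand="+", pid=90.0):
        return ORGene(gid, "c", start, end, strand, "ATG", "M", 310, [],
                      [], "r", pid, "functional")

    def test_overlapping_models_collapse_to_best(self):
        kept, removed = dedupe_candidates(
            [self._gene("a", 0, 900, pid=80), self._gene("b", 100, 950,
                                                         pid=95)])
        assert [g.gene_id for g in kept] == ["b"]
        assert [(g.gene_id, r) for g, r in removed] == \
            [("a", "overlap_lower_identity")]

    def test_low_identity_dropped_as_non_or(self):
        kept, removed = dedupe_candidates([self._gene("a", 0, 900, pid=25)])
        assert kept == []
        assert removed[0][1] == "non_or_identity_floor"

    def test_disjoint_and_opposite_strand_models_kept(self):
        genes = [self._gene("a", 0, 900), self._gene("b", 2000, 2900),
                 self._gene("c", 100, 950, strand="-")]
        kept, removed = dedupe_candidates(genes)
        assert {g.gene_id for g in kept} == {"a", "b", "c"}
        assert removed == []
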