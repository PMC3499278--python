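"""Family/subfamily assignment, identity computations and nomenclature."""

import itertools

import numpy as np
import pytest

from ormine.classify import (Assignment, assign_names, assign_taxonomy,
                             assignments_table, export_nj_tree,
                             identity_matrix, pairwise_identity,
                             subfamily_letters)
from ormine.orf_model import ORGene, ReferenceProtein
from ormine.params import PipelineParams

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n=200):
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def mutate(seq, frac, rng):
    """Substitute ``frac`` of the residues (never to the same letter)."""
    aas = list(seq)
    idx = rng.choice(len(aas), size=int(round(frac * len(aas))),
                     replace=False)
    for i in idx:
        aas[i] = AA20[(AA20.index(aas[i]) + 1 + int(rng.integers(19))) % 20]
    return "".join(aas)


class TestPairwiseIdentity:
    def test_self_identity(self):
        assert pairwise_identity("S", "S") == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AAA")

    def test_symmetry(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(50, 150)))
            b = mutate(a, float(rng.uniform(0, 0.8)), rng)
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_identity_tracks_planted_divergence(self, rng):
        a = random_protein(rng, 300)
        for frac in (0.1, 0.3, 0.5):
            pid = pairwise_identity(a, mutate(a, frac, rng))
            assert pid == pytest.approx(100 * (1 - frac), abs=4)

    def test_identity_matrix_is_symmetric_with_unit_diagonal(self, rng):
        seqs = {f"g{i}": random_protein(rng, 80) for i in range(4)}
        m = identity_matrix(seqs)
        assert (m.values == m.values.T).all()
        assert (np.diag(m.values) == 100.0).all()


def _gene(gid, protein, contig="chr1", start=0, status="functional"):
    return ORGene(gid, contig, start, start + 3 * len(protein), "+", "",
                  protein, len(protein), [], [], "r", 95.0, status)


class TestAssignTaxonomy:
    def test_family_and_class_inherited_from_best_reference(self, rng):
        base = random_protein(rng, 250)
        refs = [ReferenceProtein("r52", base, family=52, class_label="I"),
                ReferenceProtein("rX", random_protein(rng, 250), family=3,
                                 class_label="II")]
        gene = _gene("g1", mutate(base, 0.15, rng))  # ~85% identity
        a = assign_taxonomy([gene], refs)["g1"]
        assert a.family == 52
        assert a.class_label == "I"

    def test_novel_family_groups_by_single_linkage(self, rng):
        ref = ReferenceProtein("r1", random_protein(rng, 250), family=9,
                               class_label="II")
        base = random_protein(rng, 250)
        genes = [_gene(f"g{i}", mutate(base, 0.17, rng), start=1000 * i)
                 for i in range(3)]  # pairwise ~ 66-70%
        out = assign_taxonomy(genes, [ref])
        families = {a.family for a in out.values()}
        assert families == {10}  # appended after the largest reference family
        assert {a.subfamily for a in out.values()} == {"A"}

    def test_same_family_different_subfamilies(self, rng):
        ref = ReferenceProtein("r1", random_protein(rng, 250), family=1,
                               class_label="II")
        base = random_protein(rng, 250)
        # ~45% mutual identity: same family (>=40), separate subfamilies (<60)
        g1 = _gene("g1", base)
        g2 = _gene("g2", mutate(base, 0.55, rng), start=5000)
        out = assign_taxonomy([g1, g2], [ref])
        assert out["g1"].family == out["g2"].family == 2
        assert out["g1"].subfamily != out["g2"].subfamily

    def test_partition_property(self, bench):
        syn, res = bench
        assert set(res.assignments) == {g.gene_id for g in res.genes}
        for g in res.genes:
            a = res.assignments[g.gene_id]
            assert a.family >= 1
            assert a.subfamily

    def test_single_linkage_matches_transitive_closure(self, rng):
        """Threshold grouping equals exhaustive connected components."""
        from ormine.classify import _single_linkage
        for _ in range(20):
            n = int(rng.integers(3, 21))
            ids = [f"s{i}" for i in range(n)]
            pid = {}
            for a, b in itertools.combinations(ids, 2):
                pid[frozenset((a, b))] = float(rng.uniform(0, 100))

            comps = _single_linkage(
                ids, lambda a, b: pid[frozenset((a, b))], 60.0)

            # oracle: repeated merging until fixpoint
            groups = [{i} for i in ids]
            changed = True
            while changed:
                changed = False
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        if any(pid[frozenset((a, b))] >= 60.0
                               for a in groups[i] for b in groups[j]
                               if a != b):
                            groups[i] |= groups[j]
                            del groups[j]
                            changed = True
                            break
                    if changed:
                        break
            assert sorted(map(sorted, comps)) == sorted(map(sorted, groups))

    def test_subfamily_count_monotone_in_threshold(self, rng):
        base = random_protein(rng, 150)
        genes = [_gene(f"g{i}", mutate(base, float(rng.uniform(0, 0.5)), rng),
                       start=1000 * i) for i in range(8)]
        ref = ReferenceProtein("r1", base, family=1, class_label="II")
        counts = []
        for thr in (50.0, 60.0, 70.0):
            params = PipelineParams(subfamily_threshold=thr)
            out = assign_taxonomy(genes, [ref], params)
            counts.append(len({a.subfamily for a in out.values()}))
        assert counts == sorted(counts)


class TestSubfamilyLetters:
    @pytest.mark.parametrize("i,expected", [
        (0, "A"), (25, "Z"), (26, "AA"), (27, "AB"), (45, "AT"), (51, "AZ"),
        (52, "BA"),
    ])
    def test_lettering(self, i, expected):
        assert subfamily_letters(i) == expected


class TestAssignNames:
    def _named(self, specs, dup_groups=None):
        """specs: (gene_id, family, subfamily, start, status)."""
        genes, assignments = [], {}
        for gid, fam, sub, start, status in specs:
            genes.append(_gene(gid, "M" * 310, start=start, status=status))
            assignments[gid] = Assignment(gid, "II", fam, sub)
        assign_names(assignments, genes, "s", dup_groups)
        return {gid: a.name for gid, a in assignments.items()}

    def test_first_member_of_family_one(self):
        names = self._named([("g1", 1, "A", 0, "functional")])
        assert names["g1"] == "sOR1A1"

    def test_twelfth_member_pseudogene(self):
        specs = [(f"g{i}", 7, "E", 1000 * i, "functional")
                 for i in range(1, 12)]
        specs.append(("gP", 7, "E", 20_000, "pseudogene"))
        names = self._named(specs)
        assert names["gP"] == "sOR7E12P"

    def test_exact_duplicates_share_index_with_suffixes(self):
        specs = [("g1", 51, "N", 0, "functional"),
                 ("g2", 51, "N", 1000, "functional"),
                 ("g3", 51, "N", 2000, "functional"),
                 ("g4", 51, "N", 3000, "functional")]
        names = self._named(specs, dup_groups=[["g3", "g4"]])
        assert names["g1"] == "sOR51N1"
        assert names["g2"] == "sOR51N2"
        assert names["g3"] == "sOR51N3A"
        assert names["g4"] == "sOR51N3B"

    def test_triplet_gets_abc(self):
        specs = [(f"g{i}", 7, "A", 1000 * i, "functional") for i in range(3)]
        names = self._named(specs, dup_groups=[["g0", "g1", "g2"]])
        assert [names[f"g{i}"] for i in range(3)] == \
            ["sOR7A1A", "sOR7A1B", "sOR7A1C"]

    def test_member_index_follows_genome_order_across_contigs(self):
        specs = [("a", 1, "A", 500, "functional")]
        genes = [_gene("a", "M" * 310, contig="chr2", start=500),
                 _gene("b", "M" * 310, contig="chr10", start=0)]
        assignments = {"a": Assignment("a", "II", 1, "A"),
                       "b": Assignment("b", "II", 1, "A")}
        assign_names(assignments, genes, "s")
        # natural contig order: chr2 before chr10
        assert assignments["a"].name == "sOR1A1"
        assert assignments["b"].name == "sOR1A2"

    def test_naming_is_deterministic(self, bench):
        syn, res = bench
        from ormine.classify import assign_taxonomy as at
        from ormine.duplication import find_identical_cds
        subset = res.genes[:25]
        groups = [[g.gene_id for g in e.members]
                  for e in find_identical_cds(subset)]
        tables = []
        for _ in range(2):
            a = at(subset, syn.references)
            assign_names(a, subset, "s", groups)
            tables.append(assignments_table(a, subset).to_csv())
        assert tables[0] == tables[1]


def test_nj_tree_export_contains_all_leaves(rng):
    seqs = {f"g{i}": random_protein(rng, 60) for i in range(4)}
    nwk = export_nj_tree(seqs)
    assert nwk.endswith(";")
    for gid in seqs:
        assert gid in nwk
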