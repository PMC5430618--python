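"""Core quantification: best-hit selection, exact mapper vs exhaustive
oracle, weight splitting, abundance arithmetic and rollups."""

import math

import numpy as np
import pytest

from conftest import make_read, oracle_best_placement, random_dna
from viroquant.quantify import (
    AlignmentHit,
    abundance_table,
    assign_read,
    best_hits,
    candidate_union,
    kmer_map,
    map_reads,
    map_sequence,
    rollup,
)
from viroquant.records import Lineage, LineageTable, SequenceRecord, revcomp


def hit(subject, score, evalue=1e-20, query="q"):
    return AlignmentHit(
        query_id=query, subject=subject, identity=100.0, aligned_length=50,
        score=score, evalue=evalue, q_start=1, q_end=50, s_start=1, s_end=50,
        strand="+",
    )


class TestBestHits:
    def test_single_passing_hit(self):
        assert best_hits([hit("A", 95.0)], evalue_cutoff=1e-5) == {"A"}

    def test_exact_tie_returns_both(self):
        assert best_hits([hit("A", 95.0), hit("B", 95.0)]) == {"A", "B"}

    def test_evalue_cutoff_filters(self):
        assert best_hits([hit("A", 95.0, evalue=1e-2)], evalue_cutoff=1e-5) == set()

    def test_tie_tolerance_widens(self):
        hits = [hit("A", 95.0), hit("B", 94.5)]
        assert best_hits(hits, tie_tolerance=0.0) == {"A"}
        assert best_hits(hits, tie_tolerance=1.0) == {"A", "B"}

    def test_empty_in_empty_out(self):
        assert best_hits([]) == set()


class TestAssignRead:
    @pytest.mark.parametrize("m", [1, 2, 4])
    def test_weights_are_one_over_m(self, m):
        hits = [hit(f"R{i}", 95.0) for i in range(m)]
        a = assign_read(hits)
        assert len(a.weights) == m
        assert all(w == pytest.approx(1.0 / m) for _, w in a.weights)
        assert sum(w for _, w in a.weights) == pytest.approx(1.0, abs=1e-12)

    def test_unassigned_when_nothing_passes(self):
        a = assign_read([hit("A", 95.0, evalue=1.0)], evalue_cutoff=1e-5)
        assert not a.assigned and a.weights == []


class TestCandidateUnion:
    def test_union_is_sorted_set_union(self):
        per_sample = {"S1": {"a", "b"}, "S2": {"b", "c"}}
        assert candidate_union(per_sample) == ["a", "b", "c"]

    def test_single_sample(self):
        assert candidate_union({"S1": {"z", "a"}}) == ["a", "z"]

    def test_all_empty(self):
        assert candidate_union({"S1": set(), "S2": set()}) == []

    def test_order_invariant(self):
        a = candidate_union({"S1": {"a"}, "S2": {"b"}})
        b = candidate_union({"S2": {"b"}, "S1": {"a"}})
        assert a == b

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            candidate_union({})


class TestKmerMap:
    def test_exact_substring_single_hit(self, rng):
        ref = SequenceRecord("R", "", random_dna(rng, 300))
        read = make_read("q", ref.residues[100:150])
        decoy = SequenceRecord("D", "", random_dna(rng, 300))
        hits = kmer_map(read, [ref, decoy], min_score=45)
        assert [h.subject for h in hits] == ["R"]
        assert hits[0].score == 50 == hits[0].aligned_length
        assert hits[0].strand == "+"
        assert hits[0].s_start == 101 and hits[0].s_end == 150

    def test_reverse_complement_minus_strand(self, rng):
        ref = SequenceRecord("R", "", random_dna(rng, 300))
        read = make_read("q", revcomp(ref.residues[100:150]))
        (h,) = kmer_map(read, [ref], min_score=45)
        assert h.strand == "-"
        assert h.score == 50
        assert h.s_start == 150 and h.s_end == 101  # 1-based, reversed

    def test_one_mismatch_scores_l_minus_1(self, rng):
        genome = random_dna(rng, 200)
        refA = SequenceRecord("A", "", genome)
        mutated = list(genome)
        mutated[120] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[120]]
        refB = SequenceRecord("B", "", "".join(mutated))
        read = make_read("q", genome[100:150])  # covers the divergent base
        by_subject = {h.subject: h.score for h in kmer_map(read, [refA, refB], 10)}
        assert by_subject == {"A": 50, "B": 49}

    def test_n_bases_never_match(self):
        ref = SequenceRecord("R", "", "ACGTACGTACGT")
        read = make_read("q", "ACGTNCGT")
        (h,) = kmer_map(read, [ref], min_score=1)
        assert h.score == 7  # N contributes nothing

    def test_matches_exhaustive_oracle(self, rng):
        """Hit sets and scores equal the all-placements, both-strands scan
        on references up to 500 bp."""
        refs = [
            SequenceRecord(f"R{i}", "", random_dna(rng, int(length)))
            for i, length in enumerate(rng.integers(60, 500, size=4))
        ]
        reads = []
        for i in range(12):
            src = refs[int(rng.integers(len(refs)))]
            start = int(rng.integers(0, len(src) - 40 + 1))
            bases = src.residues[start : start + 40]
            if i % 3 == 0:
                bases = revcomp(bases)
            if i % 4 == 0:
                pos = int(rng.integers(40))
                b = list(bases)
                b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
                bases = "".join(b)
            reads.append(make_read(f"q{i}", bases))
        reads.append(make_read("rand", random_dna(rng, 40)))
        min_score = 25
        got = map_reads(reads, refs, min_score=min_score)
        for read, hits in zip(reads, got):
            by_subject = {h.subject: h for h in hits}
            for ref in refs:
                score, offset, strand = oracle_best_placement(
                    read.bases, ref.residues
                )
                if score >= min_score:
                    h = by_subject.pop(ref.accession)
                    assert h.score == score
                    if score >= 39:  # planted read: unique best placement
                        assert h.strand == strand
                        lo = min(h.s_start, h.s_end)
                        assert lo == offset + 1
            assert by_subject == {}  # no hits the oracle does not sanction


class TestMapSequence:
    def test_query_longer_than_reference(self, rng):
        ref = SequenceRecord("R", "", random_dna(rng, 100))
        contig = random_dna(rng, 50) + ref.residues + random_dna(rng, 50)
        hits = map_sequence("c1", contig, [ref], min_score=90)
        assert [h.subject for h in hits] == ["R"]
        assert hits[0].score == 100


class TestAbundanceTable:
    def test_forced_arithmetic(self):
        assignments = {
            "S1": [
                assign_read([hit("a", 90.0)]),
                assign_read([hit("a", 90.0), hit("b", 90.0)]),
                assign_read([hit("b", 90.0)]),
            ]
        }
        table = abundance_table(assignments)
        col = table.values["S1"]
        assert col["a"] == pytest.approx(1.5, abs=1e-12)
        assert col["b"] == pytest.approx(1.5, abs=1e-12)
        assert col.sum() == pytest.approx(3.0, abs=1e-12)

    def test_empty_sample_all_zero_column(self):
        assignments = {
            "S1": [assign_read([hit("a", 90.0)])],
            "S2": [],
        }
        table = abundance_table(assignments)
        assert table.values["S2"].sum() == 0.0
        assert set(table.values.index) == {"a"}

    def test_union_references_keep_zero_rows(self):
        assignments = {"S1": [assign_read([hit("a", 90.0)])]}
        table = abundance_table(assignments, references=["a", "b"])
        assert list(table.values.index) == ["a", "b"]
        assert table.values.loc["b", "S1"] == 0.0

    def test_column_sum_equals_assigned_count_with_odd_splits(self):
        # 1/3 weights are not dyadic; exact accumulation keeps conservation
        hits3 = [hit(x, 80.0) for x in "abc"]
        assignments = {"S1": [assign_read(hits3) for _ in range(9)]}
        table = abundance_table(assignments)
        assert math.fsum(table.values["S1"]) == pytest.approx(9.0, abs=1e-12)


class TestRollup:
    @pytest.fixture()
    def lineage(self):
        table = LineageTable()
        table.add("a1", Lineage("dsDNA", "F1", "G1", "Sp1"))
        table.add("a2", Lineage("dsDNA", "F1", "G1", "Sp1"))
        table.add("b1", Lineage("dsDNA", "F1", "G2", "Sp2"))
        table.add("c1", Lineage("ssRNA", "F2", "G3", "Sp3"))
        return table

    def make_table(self, lineage):
        assignments = {
            "S1": [assign_read([hit(acc, 90.0)]) for acc in
                   ["a1", "a1", "a2", "b1", "c1"]],
            "S2": [assign_read([hit(acc, 90.0)]) for acc in ["c1", "c1"]],
        }
        return abundance_table(assignments, lineage=lineage)

    def test_same_species_rows_merge(self, lineage):
        rolled = rollup(self.make_table(lineage), "species")
        assert rolled.values.loc["Sp1", "S1"] == 3.0

    def test_totals_conserved_at_every_rank(self, lineage):
        table = self.make_table(lineage)
        for rank in ("group", "family", "genus", "species"):
            rolled = rollup(table, rank)
            for sample in table.samples:
                assert rolled.values[sample].sum() == pytest.approx(
                    table.values[sample].sum(), abs=1e-12
                )

    def test_genus_totals_are_species_sums(self, lineage):
        table = self.make_table(lineage)
        by_genus = rollup(table, "genus").values
        by_species = rollup(table, "species").values
        # G1 = Sp1, G2 = Sp2, G3 = Sp3 under this lineage
        assert by_genus.loc["G1", "S1"] == by_species.loc["Sp1", "S1"]

    def test_missing_lineage_lands_in_unknown(self):
        table = abundance_table({"S1": [assign_read([hit("zz", 1.0)])]},
                                lineage=LineageTable())
        rolled = rollup(table, "species")
        assert list(rolled.values.index) == ["unknown"]
        assert rolled.values.loc["unknown", "S1"] == 1.0

    def test_bad_rank_rejected(self, lineage):
        with pytest.raises(ValueError, match="rank"):
            rollup(self.make_table(lineage), "kingdom")


class TestAmbiguitySplitting:
    def test_shared_region_splits_half_half(self, rng):
        """Reads from a region two references share verbatim give each
        reference exactly half a read."""
        shared = random_dna(rng, 120)
        refA = SequenceRecord("A", "", shared + random_dna(rng, 100))
        refB = SequenceRecord("B", "", random_dna(rng, 80) + shared)
        reads = [make_read(f"q{i}", shared[i * 10 : i * 10 + 60]) for i in range(6)]
        assignments = [
            assign_read(h) for h in map_reads(reads, [refA, refB], min_score=55)
        ]
        for a in assignments:
            assert sorted(acc for acc, _ in a.weights) == ["A", "B"]
            assert all(w == 0.5 for _, w in a.weights)
        table = abundance_table({"S": assignments})
        assert table.values.loc["A", "S"] == table.values.loc["B", "S"] == 3.0
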