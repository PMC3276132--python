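from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import translink as tl
from translink.records import SequenceRecord
from translink.unigene import clean_sequences, sequences_overlap

from conftest import mutate_seq, random_seq
from dp_oracle import best_local_both_strands

CFG = tl.CleaningConfig()


class TestTrimPolyTails:
    def test_terminal_polya_removed(self):
        rec = SequenceRecord("s", "ACGTACGTACGT" + "A" * 15)
        assert tl.trim_poly_tails(rec, CFG).residues == "ACGTACGTACGT"

    def test_short_run_untouched(self):
        rec = SequenceRecord("s", "ACGTACGTACGT")
        assert tl.trim_poly_tails(rec, CFG).residues == "ACGTACGTACGT"

    def test_five_prime_polyt_removed(self):
        rec = SequenceRecord("s", "T" * 20 + "GGGCCCGGGCCC")
        assert tl.trim_poly_tails(rec, CFG).residues == "GGGCCCGGGCCC"

    def test_interior_run_untouched(self):
        body = "GCGC" + "A" * 20 + "GCGC"
        assert tl.trim_poly_tails(SequenceRecord("s", body),
                                  CFG).residues == body

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=60, deadline=None)
    def test_idempotent(self, body, t5, a3):
        rec = SequenceRecord("s", "T" * t5 + body + "A" * a3)
        once = tl.trim_poly_tails(rec, CFG)
        twice = tl.trim_poly_tails(once, CFG)
        assert once.residues == twice.residues


class TestMaskRepeats:
    def test_exact_repeat_copy_masked(self, rng):
        repeat = SequenceRecord("rep", random_seq(rng, 60))
        seq = SequenceRecord("s", random_seq(rng, 100) + repeat.residues
                             + random_seq(rng, 100))
        masked = tl.mask_repeats(seq, [repeat], CFG)
        assert masked.residues[100:160] == "N" * 60
        assert len(masked) == len(seq)
        assert (100, 160) in masked.masked_spans

    def test_empty_library_is_identity(self, rng):
        seq = SequenceRecord("s", random_seq(rng, 120))
        assert tl.mask_repeats(seq, [], CFG).residues == seq.residues

    def test_diverged_copy_masked_when_oracle_agrees(self, rng):
        """An 80%-identity repeat copy qualifies by the DP-oracle criteria."""
        repeat = SequenceRecord("rep", random_seq(rng, 60))
        copy = mutate_seq(rng, repeat.residues, n_subs=12)  # 80% identity
        oracle, _ = best_local_both_strands(copy, repeat.residues)
        assert oracle.identity_pct >= 80.0  # oracle confirms it qualifies
        seq = SequenceRecord("s", random_seq(rng, 80) + copy
                             + random_seq(rng, 80))
        masked = tl.mask_repeats(seq, [repeat], CFG)
        assert "N" * 40 in masked.residues

    def test_two_copies_both_masked(self, rng):
        repeat = SequenceRecord("rep", random_seq(rng, 50))
        seq = SequenceRecord("s", repeat.residues + random_seq(rng, 100)
                             + repeat.residues)
        masked = tl.mask_repeats(seq, [repeat], CFG)
        assert masked.residues.count("N") == 100


class TestScreenVector:
    VEC = SequenceRecord("vec", "GCTAGCCTGCAGGTCGACTCTAGAGGATCCCCGGGTACCG")

    def test_terminal_vector_trimmed(self, rng):
        insert = random_seq(rng, 300)
        seq = SequenceRecord("s", self.VEC.residues + insert)
        assert tl.screen_vector(seq, [self.VEC], CFG).residues == insert

    def test_no_vector_similarity_unchanged(self, rng):
        seq = SequenceRecord("s", random_seq(rng, 200))
        assert tl.screen_vector(seq, [self.VEC], CFG).residues == seq.residues

    def test_internal_vector_flagged_not_cut(self, rng, caplog):
        left, right = random_seq(rng, 150), random_seq(rng, 150)
        seq = SequenceRecord("s", left + self.VEC.residues + right)
        with caplog.at_level("WARNING"):
            out = tl.screen_vector(seq, [self.VEC], CFG)
        assert out.residues == seq.residues
        assert any("internal vector" in r.message for r in caplog.records)


class TestFilterLength:
    def test_boundary_inclusive(self):
        seqs = [SequenceRecord(f"s{n}", "A" * n) for n in (99, 100, 101)]
        kept = tl.filter_length(seqs, CFG)
        assert [len(s) for s in kept] == [100, 101]

    def test_empty_input(self):
        assert tl.filter_length([], CFG) == []

    def test_matches_brute_force_recount(self, rng):
        lengths = rng.integers(50, 151, size=1000)
        seqs = [SequenceRecord(f"s{i}", "A" * int(n))
                for i, n in enumerate(lengths)]
        kept = tl.filter_length(seqs, CFG)
        assert len(kept) == int((lengths >= 100).sum())
        assert [s.id for s in kept] == [s.id for s in seqs if len(s) >= 100]


class TestCleaningPipeline:
    def test_idempotent(self, rng):
        vec = TestScreenVector.VEC
        rep = SequenceRecord("rep", random_seq(rng, 60))
        seqs = [SequenceRecord(
            "s1", vec.residues + random_seq(rng, 150) + rep.residues
            + random_seq(rng, 60) + "A" * 20)]
        once, _ = clean_sequences(seqs, CFG, [rep], [vec])
        twice, _ = clean_sequences(once, CFG, [rep], [vec])
        assert [s.residues for s in once] == [s.residues for s in twice]


class TestClusterUnigenes:
    def test_identical_pair_forms_contig(self, rng):
        seq = random_seq(rng, 200)
        unigenes = tl.cluster_unigenes([SequenceRecord("a", seq),
                                        SequenceRecord("b", seq)])
        assert len(unigenes) == 1
        assert unigenes[0].depth == 2 and unigenes[0].is_contig

    def test_ninety_percent_pair_stays_apart_at_95(self, rng):
        seq = random_seq(rng, 200)
        diverged = mutate_seq(rng, seq, n_subs=20)
        unigenes = tl.cluster_unigenes([SequenceRecord("a", seq),
                                        SequenceRecord("b", diverged)])
        assert len(unigenes) == 2
        assert all(not u.is_contig for u in unigenes)

    def test_single_linkage_transitivity(self, rng):
        gene = random_seq(rng, 300)
        # A covers [0,140), B covers [60,240), C covers [160,300):
        # A-B and B-C overlap, A-C do not.
        a = SequenceRecord("A", gene[:140])
        b = SequenceRecord("B", gene[60:240])
        c = SequenceRecord("C", gene[160:])
        assert sequences_overlap(a, b, tl.ClusterConfig())
        assert not sequences_overlap(a, c, tl.ClusterConfig())
        unigenes = tl.cluster_unigenes([a, b, c])
        assert len(unigenes) == 1
        assert unigenes[0].members == ["A", "B", "C"]

    def test_representative_is_longest_then_lexicographic(self, rng):
        seq = random_seq(rng, 200)
        recs = [SequenceRecord("b", seq), SequenceRecord("a", seq),
                SequenceRecord("c", seq[:150])]
        unigenes = tl.cluster_unigenes(recs)
        assert len(unigenes) == 1
        assert unigenes[0].representative == seq  # longest; 'a' beats 'b'

    def test_partition_property(self, rng):
        gene_pool = [random_seq(rng, 250) for _ in range(5)]
        seqs = []
        for i in range(30):
            src = gene_pool[int(rng.integers(5))]
            start = int(rng.integers(0, 100))
            seqs.append(SequenceRecord(
                f"r{i:02d}", mutate_seq(rng, src[start:start + 150],
                                        n_subs=2)))
        unigenes = tl.cluster_unigenes(seqs)
        members = [m for u in unigenes for m in u.members]
        assert sorted(members) == sorted(s.id for s in seqs)
        assert sum(u.depth for u in unigenes) == len(seqs)

    def test_cluster_count_monotone_in_identity_threshold(self, rng):
        base = random_seq(rng, 200)
        seqs = [SequenceRecord(f"s{i}", mutate_seq(rng, base, n_subs=4 * i))
                for i in range(8)]
        counts = []
        for identity in (1.0, 0.97, 0.92, 0.85, 0.70):
            cfg = tl.ClusterConfig(min_overlap_identity=identity)
            counts.append(len(tl.cluster_unigenes(seqs, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_equivalence_with_brute_force_components(self, rng):
        """Clusters equal connected components of the all-pairs DP overlap
        graph."""
        gene_pool = [random_seq(rng, 200) for _ in range(4)]
        seqs = []
        for i in range(20):
            src = gene_pool[int(rng.integers(4))]
            start = int(rng.integers(0, 80))
            seqs.append(SequenceRecord(
                f"r{i:02d}", mutate_seq(rng, src[start:start + 120],
                                        n_subs=1)))
        ccfg = tl.ClusterConfig()
        # Oracle: all-pairs full DP, same acceptance rule, union-find.
        parent = {s.id: s.id for s in seqs}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                aln, _ = best_local_both_strands(seqs[i].residues,
                                                 seqs[j].residues)
                if (aln and aln.identity_pct / 100.0
                        >= ccfg.min_overlap_identity
                        and aln.q_end - aln.q_start >= ccfg.min_overlap_len):
                    ri, rj = find(seqs[i].id), find(seqs[j].id)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        oracle_groups = {}
        for s in seqs:
            oracle_groups.setdefault(find(s.id), set()).add(s.id)
        ours = {frozenset(u.members) for u in tl.cluster_unigenes(seqs, ccfg)}
        assert ours == {frozenset(g) for g in oracle_groups.values()}


class TestAnnotateUnigene:
    def _unigene(self, residues):
        return tl.Unigene(id="U1", members=["U1"], representative=residues)

    def _run(self, rng, n_subs, db_len=400):
        subject = random_seq(rng, db_len)
        query = mutate_seq(rng, subject, n_subs=n_subs)
        u = self._unigene(query)
        db = [("db1", [SequenceRecord("g1", subject)], "nucleotide")]
        return tl.annotate_unigene(u, db)

    def test_strong_hit_gets_highly_similar(self, rng):
        out = self._run(rng, n_subs=0)
        assert out.annotation is not None
        assert out.annotation[4] == "highly_similar"
        assert out.annotation[2] < 1e-50

    def test_low_identity_hit_rejected_and_next_db_used(self, rng):
        subject = random_seq(rng, 300)
        query = mutate_seq(rng, subject, n_subs=0)
        u = self._unigene(query)
        # First db: same sequence but we fake low identity via heavy
        # divergence; second db: exact.
        diverged = mutate_seq(rng, subject, n_subs=120)  # 60% identity
        dbs = [("weak", [SequenceRecord("w1", diverged)], "nucleotide"),
               ("exact", [SequenceRecord("g1", subject)], "nucleotide")]
        out = tl.annotate_unigene(u, dbs)
        assert out.annotation is not None
        assert out.annotation[0] == "exact"

    def test_no_database_leaves_unannotated(self, caplog):
        u = self._unigene("ACGT" * 50)
        with caplog.at_level("WARNING"):
            out = tl.annotate_unigene(u, [])
        assert out.annotation is None

    def test_tier_boundaries(self, monkeypatch, rng):
        """Tiers grade the E-value: similar in (1e-20, 1e-15], very_similar
        in (1e-50, 1e-20), highly_similar below 1e-50."""
        from translink import unigene as ug

        u = self._unigene("ACGT" * 50)
        db = [("d", [SequenceRecord("g", "ACGT" * 50)], "nucleotide")]

        def fake_hits(evalue_value):
            hit = tl.AlignmentHit(query_id="U1", subject_id="g", score=100,
                                  bitscore=100, evalue=evalue_value,
                                  identity_pct=85.0, q_start=0, q_end=10,
                                  s_start=0, s_end=10, strand="+")
            return lambda *a, **k: [hit]

        for ev, tier in ((1e-16, "similar"), (1e-30, "very_similar"),
                         (1e-55, "highly_similar")):
            monkeypatch.setattr(ug, "best_hits", fake_hits(ev))
            out = tl.annotate_unigene(u, db)
            assert out.annotation[4] == tier, ev

    def test_translated_search_finds_protein_homolog(self, rng):
        from translink.unigene import translated_best_hits

        # A coding query whose translation matches the protein subject.
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        codon = {"M": "ATG", "K": "AAA", "T": "ACC", "A": "GCT", "Y": "TAT",
                 "I": "ATT", "Q": "CAA", "R": "CGT", "S": "TCT", "F": "TTT",
                 "V": "GTT", "H": "CAT", "L": "CTG", "E": "GAA", "G": "GGT",
                 "P": "CCG", "D": "GAT", "N": "AAT"}
        cds = "".join(codon[a] for a in protein)
        query = SequenceRecord("q", cds)
        # Protein subjects are duck-typed records with amino-acid residues.
        subject = SimpleNamespace(id="prot1", residues=protein)
        hits = translated_best_hits(query, [subject], e_max=1e-5)
        assert hits and hits[0].subject_id == "prot1"
        assert hits[0].identity_pct == 100.0
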