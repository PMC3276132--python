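import numpy as np
import pytest

import translink as tl
from translink.align import AlignmentHit
from translink.records import SequenceRecord, reverse_complement
from translink.rbh import rbh_from_hits, round_half_up, summarize_counts

from conftest import mutate_seq, random_seq
from dp_oracle import best_local_both_strands


def _unigene(uid, residues):
    return tl.Unigene(id=uid, members=[uid], representative=residues)


class TestRbhSearch:
    def test_true_ortholog_is_reciprocal(self, rng):
        gene = random_seq(rng, 600)
        homolog = mutate_seq(rng, gene, n_subs=30)  # 95% identity
        target = tl.TargetGenome(
            predicted_genes=[SequenceRecord("g1", homolog),
                             SequenceRecord("g2", random_seq(rng, 600))],
            gene_positions={"g1": ("chr1", 1000, 1600, "+"),
                            "g2": ("chr1", 5000, 5600, "+")})
        u = _unigene("UG00001", gene)
        r = tl.rbh_search(u, target, [SequenceRecord(u.id, gene)])
        assert r.is_reciprocal
        assert r.category == "predicted_gene"
        assert r.subject_id == "g1"

    def test_paralog_capture_is_not_reciprocal(self, rng):
        """When the subject's best reverse hit is a different unigene, the
        pair is rejected even though the forward hit is strong."""
        gene = random_seq(rng, 600)
        # u_b is closer to g1 than u_a is.
        u_a = _unigene("UG_A", mutate_seq(rng, gene, n_subs=60))
        u_b = _unigene("UG_B", mutate_seq(rng, gene, n_subs=5))
        target = tl.TargetGenome(predicted_genes=[SequenceRecord("g1", gene)])
        db = [SequenceRecord(u.id, u.representative) for u in (u_a, u_b)]
        r = tl.rbh_search(u_a, target, db)
        assert r.category == "predicted_gene" and r.subject_id == "g1"
        assert not r.is_reciprocal
        assert r.reverse_hit.subject_id == "UG_B"

    def test_reverse_tie_rejected_as_ambiguous(self, rng):
        gene = random_seq(rng, 500)
        u_a = _unigene("UG_A", gene)
        u_b = _unigene("UG_B", gene)  # identical twin: exact reverse tie
        target = tl.TargetGenome(predicted_genes=[SequenceRecord("g1", gene)])
        db = [SequenceRecord(u.id, u.representative) for u in (u_a, u_b)]
        assert not tl.rbh_search(u_a, target, db).is_reciprocal

    def test_no_hit_gives_category_none(self, rng):
        u = _unigene("UG1", random_seq(rng, 300))
        target = tl.TargetGenome(
            predicted_genes=[SequenceRecord("g1", random_seq(rng, 300))])
        r = tl.rbh_search(u, target, [SequenceRecord("UG1",
                                                     u.representative)])
        assert r.category == "none" and not r.is_reciprocal

    def test_genomic_window_reverse_query_clamped(self, rng, monkeypatch):
        """A genomic hit near the sequence start uses a window clamped at 0
        rather than a negative slice."""
        from translink import rbh as rbh_mod

        gene = random_seq(rng, 500)
        chrom = gene + random_seq(rng, 4000)  # hit begins at position 0
        target = tl.TargetGenome(
            genomic_seqs=[SequenceRecord("chr1", chrom)],
            pseudochromosomes={"chr1"})
        u = _unigene("UG1", gene)

        captured = {}
        real_best_hits = rbh_mod.best_hits

        def spy(query, db, *a, **k):
            captured["query"] = query
            return real_best_hits(query, db, *a, **k)

        monkeypatch.setattr(rbh_mod, "best_hits", spy)
        r = tl.rbh_search(u, target, [SequenceRecord("UG1", gene)],
                          window_bp=2000)
        assert r.is_reciprocal and r.category == "genomic_window"
        assert captured["query"].id == "chr1:0-2500"
        assert len(captured["query"]) == 2500  # clamped left, +2000 right

    def test_genomic_hit_positions_at_window_midpoint(self, rng):
        gene = random_seq(rng, 400)
        chrom = random_seq(rng, 3000) + gene + random_seq(rng, 3000)
        target = tl.TargetGenome(
            genomic_seqs=[SequenceRecord("chr1", chrom)],
            pseudochromosomes={"chr1"})
        u = _unigene("UG1", gene)
        r = tl.rbh_search(u, target, [SequenceRecord("UG1", gene)])
        r = tl.resolve_position(r, target)
        assert r.position == ("chr1", 3200)
        assert r.position_method == "window"

    def test_predicted_gene_positions_at_annotated_midpoint(self, rng):
        gene = random_seq(rng, 400)
        target = tl.TargetGenome(
            predicted_genes=[SequenceRecord("g1", gene)],
            gene_positions={"g1": ("chr2", 10_000, 10_400, "-")})
        u = _unigene("UG1", gene)
        r = tl.rbh_search(u, target, [SequenceRecord("UG1", gene)])
        r = tl.resolve_position(r, target)
        assert r.position == ("chr2", 10_200)
        assert r.position_method == "direct"

    def test_tc_relay_positions_through_gene_homolog(self, rng):
        gene = random_seq(rng, 500)
        tc = mutate_seq(rng, gene, n_subs=10)
        u = _unigene("UG1", mutate_seq(rng, tc, n_subs=5))
        target = tl.TargetGenome(
            predicted_genes=[SequenceRecord("g1", gene)],
            transcript_contigs=[SequenceRecord("TC1", tc)],
            gene_positions={"g1": ("chr3", 100, 700, "+")})
        r = tl.RbhResult(unigene_id="UG1", category="transcript_contig",
                         subject_id="TC1", is_reciprocal=True)
        r = tl.resolve_position(r, target)
        assert r.position == ("chr3", 400)
        assert r.position_method == "tc_relay"

    def test_minus_strand_ortholog_recovered(self, rng):
        gene = random_seq(rng, 500)
        target = tl.TargetGenome(
            predicted_genes=[SequenceRecord(
                "g1", reverse_complement(mutate_seq(rng, gene, n_subs=20)))])
        u = _unigene("UG1", gene)
        r = tl.rbh_search(u, target, [SequenceRecord("UG1", gene)])
        assert r.is_reciprocal
        assert r.forward_hit.strand == "-"


class TestAllPairsOracleEquivalence:
    def test_ten_by_ten_matches_dp_oracle_decisions(self):
        """RBH decisions from the package aligner equal those recomputed
        with the independent quadratic-DP oracle on a 10x10 instance."""
        rng = np.random.default_rng(11)
        genes = [random_seq(rng, 400) for _ in range(10)]
        unigenes = [_unigene(f"UG{i}", mutate_seq(rng, g, n_subs=20))
                    for i, g in enumerate(genes)]
        target = tl.TargetGenome(
            predicted_genes=[SequenceRecord(f"g{i}", g)
                             for i, g in enumerate(genes)])
        db = [SequenceRecord(u.id, u.representative) for u in unigenes]
        ours = {u.id: tl.rbh_search(u, target, db) for u in unigenes}

        scoring = tl.AlignmentScoring()
        n_union = sum(len(g) for g in genes)
        n_udb = sum(len(u.representative) for u in unigenes)

        def oracle_best(query, subjects, n_total):
            best = None
            for sid, s in subjects:
                aln, _ = best_local_both_strands(query, s)
                if aln is None:
                    continue
                e = tl.evalue(aln.score, scoring, m=len(query), n=n_total)
                if e <= 1e-20 and (best is None or (e, sid) < best[:2]):
                    best = (e, sid, aln.score)
            return best

        for u in unigenes:
            fwd = oracle_best(u.representative,
                              [(f"g{i}", g) for i, g in enumerate(genes)],
                              n_union)
            r = ours[u.id]
            if fwd is None:
                assert r.category == "none"
                continue
            assert r.subject_id == fwd[1]
            subject = genes[int(fwd[1][1:])]
            rev = oracle_best(subject,
                              [(v.id, v.representative) for v in unigenes],
                              n_udb)
            assert r.is_reciprocal == (rev is not None and rev[1] == u.id)


class TestRbhFromHits:
    def _hit(self, q, s, evalue, bitscore=200.0):
        return AlignmentHit(query_id=q, subject_id=s, score=100,
                            bitscore=bitscore, evalue=evalue,
                            identity_pct=95.0, q_start=0, q_end=100,
                            s_start=0, s_end=100, strand="+")

    def _target(self):
        return tl.TargetGenome(
            predicted_genes=[SequenceRecord("g1", "ACGT" * 100),
                             SequenceRecord("g2", "ACGT" * 100)],
            transcript_contigs=[SequenceRecord("TC1", "ACGT" * 100)],
            gene_positions={"g1": ("chr1", 0, 400, "+"),
                            "g2": ("chr1", 1000, 1400, "+")})

    def test_reciprocal_pair_from_table(self):
        hits = [self._hit("UG1", "g1", 1e-80),
                self._hit("g1", "UG1", 1e-80)]
        (r,) = rbh_from_hits(hits, ["UG1"], self._target())
        assert r.is_reciprocal and r.position == ("chr1", 200)

    def test_non_reciprocal_when_reverse_prefers_other(self):
        hits = [self._hit("UG1", "g1", 1e-80),
                self._hit("g1", "UG2", 1e-90, bitscore=300),
                self._hit("g1", "UG1", 1e-80)]
        r, _ = rbh_from_hits(hits, ["UG1", "UG2"], self._target())
        assert not r.is_reciprocal

    def test_weak_hits_filtered_by_e_max(self):
        hits = [self._hit("UG1", "g1", 1e-10)]
        (r,) = rbh_from_hits(hits, ["UG1"], self._target())
        assert r.category == "none"

    def test_tc_relay_through_table(self):
        hits = [self._hit("UG1", "TC1", 1e-90),
                self._hit("TC1", "UG1", 1e-90),
                self._hit("TC1", "g2", 1e-70)]
        (r,) = rbh_from_hits(hits, ["UG1"], self._target())
        assert r.is_reciprocal and r.category == "transcript_contig"
        assert r.position == ("chr1", 1200)
        assert r.position_method == "tc_relay"


class TestSummaries:
    def test_round_half_up(self):
        assert round_half_up(42.5) == 43
        assert round_half_up(42.49) == 42
        assert round_half_up(0.5) == 1

    def test_counts_5888_of_13747_at_60pct_coverage(self):
        assert summarize_counts(5888, 13747, 0.60) == (43, 71)

    def test_counts_6626_of_13747_at_98pct_coverage(self):
        assert summarize_counts(6626, 13747, 0.98) == (48, 49)

    def test_estimate_divides_unrounded_ratio(self):
        # 5433/13747 = 39.52% rounds to 40, but the estimate divides the
        # unrounded ratio: 39.52/0.67 = 58.99 -> 59, not 40/0.67 -> 60.
        assert summarize_counts(5433, 13747, 0.67) == (40, 59)

    def test_zero_reciprocal(self):
        assert summarize_counts(0, 100, 0.5) == (0, 0)

    def test_summarize_rbh_aggregates_categories(self):
        results = [
            tl.RbhResult("U1", category="predicted_gene", subject_id="g1",
                         is_reciprocal=True),
            tl.RbhResult("U2", category="predicted_gene", subject_id="g2",
                         is_reciprocal=False),
            tl.RbhResult("U3", category="transcript_contig",
                         subject_id="TC1", is_reciprocal=True),
            tl.RbhResult("U4"),
        ]
        s = tl.summarize_rbh(results, total_unigenes=4,
                             coverage_fraction=0.5)
        assert s.unidirectional == 3 and s.reciprocal == 2
        assert s.per_category_reciprocal["predicted_gene"] == 1
        assert s.hit_rate_pct == 50 and s.estimated_hit_rate_pct == 100

    def test_summarize_rejects_empty_total(self):
        with pytest.raises(ValueError):
            tl.summarize_rbh([], total_unigenes=0)
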