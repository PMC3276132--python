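"""Best reciprocal homolog (RBH) search against an annotated target genome.

A Unigene is searched against the union of three target databases —
predicted genes, transcript contigs (TCs) and genomic sequences
(pseudo-chromosomes / BAC-scale fragments).  The winning forward hit
determines the reverse query: the full predicted-gene or TC sequence,
or, for a genomic hit, the matched genomic segment padded by a fixed
window (default 2 kb) on each side.  The pair is a best reciprocal
homolog when the strict best reverse hit (E <= 1e-20) is the original
Unigene.

Reciprocal pairs are then positioned on the target pseudo-chromosomes:
directly for predicted genes, through the best predicted-gene homolog
for TCs (the "relay" rule), or at the matched interval's midpoint for
genomic hits.  Summary statistics mirror the customary comparative-map
reporting: unidirectional and reciprocal counts per database, the hit
rate as a percent of all Unigenes, and the hit rate extrapolated to a
fully sequenced genome via the genome-coverage fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .align import AlignmentHit, AlignmentScoring, local_align, \
    min_score_for_evalue, best_hits
from .records import SequenceRecord
from .unigene import Unigene

logger = logging.getLogger(__name__)

CATEGORIES = ("predicted_gene", "transcript_contig", "genomic_window", "none")
_CATEGORY_PRIORITY = {"predicted_gene": 0, "transcript_contig": 1,
                      "genomic_window": 2}

GenePosition = Tuple[str, int, int, str]  # chromosome, start, end, strand


@dataclass
class TargetGenome:
    """The three searchable databases of a target genome plus positions.

    ``gene_positions`` maps predicted-gene ids to 0-based half-open
    genomic intervals.  ``pseudochromosomes`` names the genomic entries
    that carry meaningful chromosome coordinates; by default these are
    the chromosomes referenced by the position table.
    ``coverage_fraction`` is the fraction of the genome represented by
    the sequence databases, used for the estimated hit rate.
    """

    predicted_genes: List[SequenceRecord] = field(default_factory=list)
    transcript_contigs: List[SequenceRecord] = field(default_factory=list)
    genomic_seqs: List[SequenceRecord] = field(default_factory=list)
    gene_positions: Dict[str, GenePosition] = field(default_factory=dict)
    coverage_fraction: float = 1.0
    pseudochromosomes: Optional[set] = None

    def __post_init__(self) -> None:
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        known = {g.id for g in self.predicted_genes}
        missing = set(self.gene_positions) - known
        if missing:
            raise ValueError(
                f"positioned gene ids absent from predicted_genes: "
                f"{sorted(missing)[:5]}")
        if self.pseudochromosomes is None:
            self.pseudochromosomes = {
                chrom for chrom, _, _, _ in self.gene_positions.values()}

    def db(self, category: str) -> List[SequenceRecord]:
        return {"predicted_gene": self.predicted_genes,
                "transcript_contig": self.transcript_contigs,
                "genomic_window": self.genomic_seqs}[category]


@dataclass
class RbhResult:
    """Outcome of one Unigene's reciprocal search."""

    unigene_id: str
    category: str = "none"
    subject_id: Optional[str] = None
    forward_hit: Optional[AlignmentHit] = None
    reverse_hit: Optional[AlignmentHit] = None
    is_reciprocal: bool = False
    position: Optional[Tuple[str, int]] = None  # chromosome, bp midpoint
    position_method: str = "unplaced"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.position is not None and self.category == "none":
            raise ValueError("cannot position a Unigene without a hit")


@dataclass
class RbhSummary:
    """Counts and rates for a batch of RBH searches."""

    total_unigenes: int
    unidirectional: int
    reciprocal: int
    per_category_unidirectional: Dict[str, int]
    per_category_reciprocal: Dict[str, int]
    hit_rate_pct: int
    estimated_hit_rate_pct: int
    coverage_fraction: float


def round_half_up(x: float) -> int:
    """Round to nearest integer, half away from zero (for percentages)."""
    return int(math.floor(x + 0.5))


def _union_search(query: SequenceRecord, target: TargetGenome,
                  scoring: AlignmentScoring, e_max: float
                  ) -> List[Tuple[AlignmentHit, str]]:
    """Forward hits over the union of the three databases.

    E-values use the union database length so hits are comparable
    across databases; ranking is (E, -bitscore, category priority,
    subject id).
    """
    n_union = sum(len(s) for cat in _CATEGORY_PRIORITY
                  for s in target.db(cat))
    if n_union == 0:
        return []
    m = len(query)
    scoring_db = replace(scoring, search_space_m=m, search_space_n=n_union)
    min_score = min_score_for_evalue(e_max, scoring_db, m, n_union)
    tagged = []
    for category in _CATEGORY_PRIORITY:
        for subject in target.db(category):
            hits = local_align(query, subject, scoring_db,
                               min_score=min_score)
            if hits and hits[0].evalue <= e_max:
                tagged.append((hits[0], category))
    tagged.sort(key=lambda hc: (hc[0].evalue, -hc[0].bitscore,
                                _CATEGORY_PRIORITY[hc[1]], hc[0].subject_id))
    return tagged


def rbh_search(u: Unigene, target: TargetGenome,
               unigene_db: Sequence[SequenceRecord],
               scoring: AlignmentScoring = AlignmentScoring(),
               e_max: float = 1e-20,
               window_bp: int = 2000) -> RbhResult:
    """Forward search, reverse check, reciprocity decision for one Unigene.

    The reverse query is the full subject for predicted genes and TCs;
    for genomic hits it is the matched subject interval extended by
    ``window_bp`` on each side (clamped to the sequence).  Reciprocity
    requires the unique strict-best reverse hit at ``E <= e_max`` to be
    the original Unigene — a tie with another Unigene rejects the pair
    as ambiguous.
    """
    query = SequenceRecord(u.id, u.representative)
    forward = _union_search(query, target, scoring, e_max)
    if not forward:
        return RbhResult(unigene_id=u.id)
    best, category = forward[0]
    subject = next(s for s in target.db(category)
                   if s.id == best.subject_id)
    if category == "genomic_window":
        lo = max(0, best.s_start - window_bp)
        hi = min(len(subject), best.s_end + window_bp)
        reverse_query = SequenceRecord(
            f"{subject.id}:{lo}-{hi}", subject.residues[lo:hi])
    else:
        reverse_query = subject
    reverse = best_hits(reverse_query, list(unigene_db), scoring,
                        e_max=e_max, k=2)
    reciprocal = False
    reverse_hit = reverse[0] if reverse else None
    if reverse_hit and reverse_hit.subject_id == u.id:
        if len(reverse) > 1 and reverse[1].score == reverse_hit.score:
            logger.info("ambiguous reverse best for %s (tie with %s)",
                        u.id, reverse[1].subject_id)
        else:
            reciprocal = True
    return RbhResult(unigene_id=u.id, category=category,
                     subject_id=best.subject_id, forward_hit=best,
                     reverse_hit=reverse_hit, is_reciprocal=reciprocal)


def resolve_position(r: RbhResult, target: TargetGenome,
                     scoring: AlignmentScoring = AlignmentScoring(),
                     e_max: float = 1e-20) -> RbhResult:
    """Attach a pseudo-chromosome position to a reciprocal result.

    predicted gene -> midpoint of its annotated interval (``direct``);
    genomic hit -> midpoint of the matched interval when the subject is
    a pseudo-chromosome (``window``); TC -> position of its best
    predicted-gene homolog at ``E <= e_max`` (``tc_relay``).
    """
    if not r.is_reciprocal:
        return r
    if r.category == "predicted_gene":
        pos = target.gene_positions.get(r.subject_id)
        if pos is None:
            logger.warning("gene %s missing from the position table",
                           r.subject_id)
            return r
        chrom, start, end, _ = pos
        r.position = (chrom, (start + end) // 2)
        r.position_method = "direct"
    elif r.category == "genomic_window":
        if r.subject_id in (target.pseudochromosomes or ()):
            r.position = (r.subject_id,
                          (r.forward_hit.s_start + r.forward_hit.s_end) // 2)
            r.position_method = "window"
    elif r.category == "transcript_contig":
        tc = next(s for s in target.transcript_contigs
                  if s.id == r.subject_id)
        hits = best_hits(tc, target.predicted_genes, scoring,
                         e_max=e_max, k=1)
        if hits:
            pos = target.gene_positions.get(hits[0].subject_id)
            if pos is not None:
                chrom, start, end, _ = pos
                r.position = (chrom, (start + end) // 2)
                r.position_method = "tc_relay"
    return r


def rbh_pipeline(unigenes: Sequence[Unigene], target: TargetGenome,
                 scoring: AlignmentScoring = AlignmentScoring(),
                 e_max: float = 1e-20,
                 window_bp: int = 2000) -> List[RbhResult]:
    """Run the reciprocal search + positioning for a batch of Unigenes."""
    unigene_db = [SequenceRecord(u.id, u.representative) for u in unigenes]
    results = []
    for u in unigenes:
        r = rbh_search(u, target, unigene_db, scoring,
                       e_max=e_max, window_bp=window_bp)
        results.append(resolve_position(r, target, scoring, e_max=e_max))
    return results


def rbh_from_hits(hits: Sequence[AlignmentHit], unigene_ids: Sequence[str],
                  target: TargetGenome,
                  e_max: float = 1e-20) -> List[RbhResult]:
    """Reciprocal-best search over a precomputed tabular hit set.

    For large external runs the alignment stage can be replaced by a
    blast-style hit table holding both search directions (unigene ->
    target and target/TC -> unigene).  Predicted-gene and TC subjects
    are supported; genomic-window reverse queries need the built-in
    aligner because their reverse query is a sequence slice, not a
    database entry.
    """
    unigene_set = set(unigene_ids)
    gene_ids = {g.id for g in target.predicted_genes}
    tc_ids = {t.id for t in target.transcript_contigs}
    ranked: Dict[str, List[AlignmentHit]] = {}
    for h in hits:
        if h.evalue <= e_max:
            ranked.setdefault(h.query_id, []).append(h)
    for query_hits in ranked.values():
        query_hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    results = []
    for uid in unigene_ids:
        forward = [h for h in ranked.get(uid, ())
                   if h.subject_id in gene_ids or h.subject_id in tc_ids]
        if not forward:
            results.append(RbhResult(unigene_id=uid))
            continue
        best = forward[0]
        category = ("predicted_gene" if best.subject_id in gene_ids
                    else "transcript_contig")
        reverse = [h for h in ranked.get(best.subject_id, ())
                   if h.subject_id in unigene_set]
        reciprocal = False
        reverse_hit = reverse[0] if reverse else None
        if reverse_hit and reverse_hit.subject_id == uid:
            tie = (len(reverse) > 1
                   and reverse[1].bitscore == reverse_hit.bitscore)
            reciprocal = not tie
        r = RbhResult(unigene_id=uid, category=category,
                      subject_id=best.subject_id, forward_hit=best,
                      reverse_hit=reverse_hit, is_reciprocal=reciprocal)
        if reciprocal:
            if category == "predicted_gene":
                pos = target.gene_positions.get(best.subject_id)
                if pos is not None:
                    chrom, start, end, _ = pos
                    r.position = (chrom, (start + end) // 2)
                    r.position_method = "direct"
            else:  # TC relay through its best predicted-gene hit
                relay = [h for h in ranked.get(best.subject_id, ())
                         if h.subject_id in gene_ids]
                if relay:
                    pos = target.gene_positions.get(relay[0].subject_id)
                    if pos is not None:
                        chrom, start, end, _ = pos
                        r.position = (chrom, (start + end) // 2)
                        r.position_method = "tc_relay"
        results.append(r)
    return results


def summarize_counts(reciprocal: int, total_unigenes: int,
                     coverage_fraction: float = 1.0) -> Tuple[int, int]:
    """(hit rate %, estimated hit rate %) under half-up integer rounding.

    The estimated rate divides the *unrounded* hit-rate ratio by the
    genome-coverage fraction before rounding.
    """
    ratio = 100.0 * reciprocal / total_unigenes
    return (round_half_up(ratio),
            round_half_up(ratio / coverage_fraction))


def summarize_rbh(results: Sequence[RbhResult], total_unigenes: int,
                  coverage_fraction: float = 1.0) -> RbhSummary:
    """Aggregate a batch of results into the summary-table statistics."""
    if total_unigenes < 1:
        raise ValueError("total_unigenes must be >= 1")
    uni = {c: 0 for c in _CATEGORY_PRIORITY}
    rec = {c: 0 for c in _CATEGORY_PRIORITY}
    for r in results:
        if r.category != "none":
            uni[r.category] += 1
            if r.is_reciprocal:
                rec[r.category] += 1
    unidirectional = sum(uni.values())
    reciprocal = sum(rec.values())
    hit_rate, est_rate = summarize_counts(reciprocal, total_unigenes,
                                          coverage_fraction)
    return RbhSummary(total_unigenes=total_unigenes,
                      unidirectional=unidirectional,
                      reciprocal=reciprocal,
                      per_category_unidirectional=uni,
                      per_category_reciprocal=rec,
                      hit_rate_pct=hit_rate,
                      estimated_hit_rate_pct=est_rate,
                      coverage_fraction=coverage_fraction)
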