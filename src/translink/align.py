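"""Local nucleotide alignment with Karlin–Altschul E-values.

The homology searches in this toolkit all reduce to scored local
alignments of a query against a database of subjects.  Alignments are
computed with an affine-gap Smith–Waterman (``Bio.Align.PairwiseAligner``
in local mode); for large query x subject products an exact k-mer
seeding step restricts the dynamic programme to candidate windows, so
unrelated pairs are rejected at dictionary-lookup cost.  The backend is
deterministic: for fixed inputs and scoring the same hits come back in
the same order.

E-values use the ungapped Karlin–Altschul form ``E = K * m * n *
exp(-lambda * S)`` so that the familiar thresholds (1e-20 for homolog
search, 1e-15 for annotation, 1e-50 for the top annotation tier) have an
operational meaning for the built-in aligner.  The constants are
configurable through :class:`AlignmentScoring`.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from .records import SequenceRecord, reverse_complement

# Direct dynamic programming below this many cells; seed-and-extend above.
_DP_DIRECT_CELLS = 50_000
_SEED_K = 11
_SEED_BAND = 48
_MAX_REGIONS = 8
# A region needs this many seeds before the DP runs; any alignment strong
# enough for the usual E-value thresholds carries far more exact k-mers.
_MIN_REGION_SEEDS = 2


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme and statistical constants for local alignment.

    ``match``/``mismatch`` are per-column scores; ``gap_open`` and
    ``gap_extend`` are positive penalties (a gap of length L costs
    ``gap_open + L * gap_extend``).  ``lam`` and ``k_const`` are the
    Karlin–Altschul lambda and K; ``search_space_m``/``search_space_n``
    are the effective query and database lengths used for E-values when
    set (otherwise the actual sequence lengths are used).
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 1.28
    k_const: float = 0.46
    search_space_m: Optional[int] = None
    search_space_n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k_const <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@dataclass
class AlignmentHit:
    """One local alignment.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; ``strand`` is the subject strand ('+' or '-').  Identity
    is computed over aligned columns with gap columns counted as
    mismatches.
    """

    query_id: str
    subject_id: str
    score: float
    bitscore: float
    evalue: float
    identity_pct: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("alignment intervals must be non-empty")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


def evalue(score: float, scoring: AlignmentScoring,
           m: Optional[int] = None, n: Optional[int] = None) -> float:
    """Karlin–Altschul expectation ``K * m * n * exp(-lambda * S)``.

    ``m``/``n`` default to the scoring object's search-space sizes.
    Strictly decreasing in the score and linear in each space size.
    """
    m = m if m is not None else scoring.search_space_m
    n = n if n is not None else scoring.search_space_n
    if m is None or n is None:
        raise ValueError("search space sizes m and n must be provided")
    return scoring.k_const * m * n * math.exp(-scoring.lam * score)


def bitscore(score: float, scoring: AlignmentScoring) -> float:
    return (scoring.lam * score - math.log(scoring.k_const)) / math.log(2.0)


def min_score_for_evalue(e_max: float, scoring: AlignmentScoring,
                         m: int, n: int) -> float:
    """Smallest raw score whose E-value is <= ``e_max``."""
    return (math.log(scoring.k_const * m * n) - math.log(e_max)) / scoring.lam


@lru_cache(maxsize=8)
def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int):
    from Bio import Align
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                matrix[a, b] = float(match)
            else:
                matrix[a, b] = float(mismatch)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _get_aligner(scoring: AlignmentScoring):
    return _aligner(scoring.match, scoring.mismatch,
                    scoring.gap_open, scoring.gap_extend)


@lru_cache(maxsize=512)
def _kmer_index(subject: str, k: int) -> Dict[str, Tuple[int, ...]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for pos in range(len(subject) - k + 1):
        kmer = subject[pos:pos + k]
        if "N" not in kmer:
            index[kmer].append(pos)
    return {kmer: tuple(v) for kmer, v in index.items()}


def _seed_regions(query: str, subject: str) -> List[Tuple[int, int, int]]:
    """Candidate subject windows from exact k-mer seeds.

    Returns ``(n_seeds, s_lo, s_hi)`` tuples, best-seeded first, after
    merging neighbouring diagonal bands.
    """
    index = _kmer_index(subject, _SEED_K)
    bands: Dict[int, List[int]] = defaultdict(list)
    for q_pos in range(len(query) - _SEED_K + 1):
        kmer = query[q_pos:q_pos + _SEED_K]
        if "N" in kmer:
            continue
        for s_pos in index.get(kmer, ()):
            bands[(s_pos - q_pos) // _SEED_BAND].append(s_pos)
    if not bands:
        return []
    regions: List[Tuple[int, List[int]]] = []
    for band in sorted(bands):
        if regions and band - regions[-1][0] <= 1:
            regions[-1] = (band, regions[-1][1] + bands[band])
        else:
            regions.append((band, list(bands[band])))
    out = []
    for _, positions in regions:
        if len(positions) < _MIN_REGION_SEEDS:
            continue
        s_lo = max(0, min(positions) - len(query))
        s_hi = min(len(subject), max(positions) + _SEED_K + len(query))
        out.append((len(positions), s_lo, s_hi))
    out.sort(key=lambda r: (-r[0], r[1]))
    return out[:_MAX_REGIONS]


def _alignment_stats(aln) -> Tuple[int, int, int, int, float]:
    """(q_start, q_end, s_start, s_end, identity_pct) from an alignment."""
    blocks_q, blocks_s = aln.aligned
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return q_start, q_end, s_start, s_end, identity


def _align_forward(query: str, subject: str, scoring: AlignmentScoring,
                   min_score: float) -> List[Tuple[float, int, int, int, int, float]]:
    """Best local alignments of forward ``query`` vs forward ``subject``.

    Returns ``(score, q_start, q_end, s_start, s_end, identity_pct)``
    tuples, best first.  Subjects larger than the direct-DP budget are
    screened by exact k-mer seeding first.
    """
    aligner = _get_aligner(scoring)
    threshold = max(min_score, 1e-9)

    def _solve(window: str, offset: int):
        score = aligner.score(query, window)
        if score < threshold:
            return None
        aln = aligner.align(query, window)[0]
        q0, q1, s0, s1, ident = _alignment_stats(aln)
        return (float(score), q0, q1, s0 + offset, s1 + offset, ident)

    if len(query) * len(subject) <= _DP_DIRECT_CELLS:
        hit = _solve(subject, 0)
        return [hit] if hit else []

    results = []
    for _, s_lo, s_hi in _seed_regions(query, subject):
        hit = _solve(subject[s_lo:s_hi], s_lo)
        if hit:
            results.append(hit)
    # Deduplicate overlapping subject windows, keeping the best score.
    results.sort(key=lambda h: (-h[0], h[3]))
    kept: List[Tuple[float, int, int, int, int, float]] = []
    for hit in results:
        if all(hit[4] <= k[3] or hit[3] >= k[4] for k in kept):
            kept.append(hit)
    return kept


def local_align(query: SequenceRecord, subject: SequenceRecord,
                scoring: AlignmentScoring = AlignmentScoring(),
                min_score: float = 1.0) -> List[AlignmentHit]:
    """Local alignments of ``query`` vs ``subject`` on both strands.

    Hits are returned best-first by score (ties: '+' before '-', then
    subject start).  Coordinates always refer to the forward strands;
    ``strand`` records which subject strand matched.  A query or
    subject consisting only of ``N`` yields no hits.
    """
    if not query.residues or not subject.residues:
        raise ValueError("sequences must be non-empty")
    m = scoring.search_space_m or len(query)
    n = scoring.search_space_n or len(subject)
    hits: List[AlignmentHit] = []
    qlen = len(query)
    for strand, qseq in (("+", query.residues),
                         ("-", reverse_complement(query.residues))):
        for score, q0, q1, s0, s1, ident in _align_forward(
                qseq, subject.residues, scoring, min_score):
            if strand == "-":
                q0, q1 = qlen - q1, qlen - q0
            hits.append(AlignmentHit(
                query_id=query.id, subject_id=subject.id,
                score=score, bitscore=bitscore(score, scoring),
                evalue=evalue(score, scoring, m=m, n=n),
                identity_pct=ident,
                q_start=q0, q_end=q1, s_start=s0, s_end=s1,
                strand=strand))
    hits.sort(key=lambda h: (-h.score, h.strand, h.s_start))
    return hits


def best_hits(query: SequenceRecord, db: Sequence[SequenceRecord],
              scoring: AlignmentScoring = AlignmentScoring(),
              e_max: float = 1e-20,
              k: Optional[int] = None) -> List[AlignmentHit]:
    """Ranked database hits for one query.

    One hit per subject (its best local alignment), filtered at
    ``E <= e_max`` over the whole-database search space and ranked by
    (E ascending, bitscore descending, subject id ascending).  At most
    ``k`` hits are returned when ``k`` is given.
    """
    if not db:
        return []
    m = len(query)
    n = sum(len(s) for s in db)
    scoring_db = replace(scoring, search_space_m=m, search_space_n=n)
    min_score = min_score_for_evalue(e_max, scoring_db, m, n)
    hits = []
    for subject in db:
        sub_hits = local_align(query, subject, scoring_db,
                               min_score=min_score)
        if sub_hits:
            hits.append(sub_hits[0])
    hits = [h for h in hits if h.evalue <= e_max]
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return hits[:k] if k is not None else hits
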