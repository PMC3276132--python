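"""Transcript cleaning and Unigene clustering.

Raw transcript evidence (ESTs, CDSs) is cleaned — vector screening,
poly-A/T tail trimming, repeat masking against a user-supplied library,
and a minimum-length filter — and then clustered into a non-redundant
Unigene set by single-linkage over the pairwise overlap graph: two
sequences are joined when they share a local alignment at or above a
minimum identity (default 95%, the classic EST-assembly overlap
stringency) and a minimum aligned length (default 40 bp).  Each
connected component becomes one Unigene whose representative is its
longest member.

Functional annotation walks an ordered list of reference databases and
keeps the first hit passing E <= 1e-15 and >= 70% identity, graded into
three similarity tiers by E-value (< 1e-20 "very similar",
< 1e-50 "highly similar").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import AlignmentScoring, best_hits, local_align
from .records import SequenceRecord, normalize_spans

logger = logging.getLogger(__name__)

TIERS = ("similar", "very_similar", "highly_similar")


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for the sequence-cleaning operators.

    ``min_length`` (bp) drops short sequences after cleaning;
    ``polyA_min_run`` is the minimum terminal homopolymer run trimmed;
    ``entropy_window``/``entropy_threshold`` (bits) flag low-complexity
    windows in the cleaning report; the remaining fields control
    alignment-based repeat masking and vector trimming.
    """

    min_length: int = 100
    polyA_min_run: int = 12
    entropy_window: int = 20
    entropy_threshold: float = 1.0
    repeat_mask_min_identity: float = 0.8
    repeat_mask_min_len: int = 40
    vector_trim_min_identity: float = 0.9
    vector_min_len: int = 20
    vector_terminal_margin: int = 50

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for name in ("repeat_mask_min_identity", "vector_trim_min_identity"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ClusterConfig:
    """Overlap criteria for Unigene clustering."""

    min_overlap_identity: float = 0.95
    min_overlap_len: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("min_overlap_identity must be in (0, 1]")
        if self.min_overlap_len < 1:
            raise ValueError("min_overlap_len must be >= 1")


@dataclass
class Unigene:
    """A cluster of cleaned sequences: a contig (depth >= 2) or singleton."""

    id: str
    members: List[str]
    representative: str
    annotation: Optional[Tuple[str, str, float, float, str]] = None

    @property
    def depth(self) -> int:
        return len(self.members)

    @property
    def is_contig(self) -> bool:
        return self.depth >= 2

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a Unigene needs at least one member")
        if self.annotation is not None and self.annotation[4] not in TIERS:
            raise ValueError(f"unknown annotation tier {self.annotation[4]!r}")


def _shift_spans(spans, offset, new_len):
    shifted = [(s - offset, e - offset) for s, e in spans]
    clipped = [(max(s, 0), min(e, new_len)) for s, e in shifted]
    return normalize_spans([(s, e) for s, e in clipped if s < e], new_len)


def trim_poly_tails(seq: SequenceRecord, cfg: CleaningConfig) -> SequenceRecord:
    """Trim a 5' poly-T and/or 3' poly-A homopolymer run.

    Only strict terminal runs of length >= ``polyA_min_run`` are
    removed; interior runs are untouched.  Idempotent by maximality of
    the trimmed runs.
    """
    residues = seq.residues
    start = 0
    run = 0
    while run < len(residues) and residues[run] == "T":
        run += 1
    if run >= cfg.polyA_min_run:
        start = run
    end = len(residues)
    run = 0
    while run < end - start and residues[end - 1 - run] == "A":
        run += 1
    if run >= cfg.polyA_min_run:
        end -= run
    if start == 0 and end == len(residues):
        return seq
    trimmed = residues[start:end]
    return SequenceRecord(seq.id, trimmed, seq.source_tag,
                          _shift_spans(seq.masked_spans, start, len(trimmed)))


def mask_repeats(seq: SequenceRecord, repeat_lib: Sequence[SequenceRecord],
                 cfg: CleaningConfig,
                 scoring: AlignmentScoring = AlignmentScoring()) -> SequenceRecord:
    """Replace repeat-library matches by ``N``.

    Every local alignment against a library entry with identity >=
    ``repeat_mask_min_identity`` and query span >= ``repeat_mask_min_len``
    is hard-masked (length preserved) and recorded in ``masked_spans``.
    Iterates until no further qualifying match is found, so multiple
    copies of a repeat are all masked.
    """
    if not repeat_lib or not seq.residues:
        return seq
    residues = list(seq.residues)
    new_spans = list(seq.masked_spans)
    min_score = _qualifying_min_score(cfg.repeat_mask_min_identity,
                                      cfg.repeat_mask_min_len, scoring)
    for _ in range(64):  # safety bound; each pass masks >= 1 new span
        current = SequenceRecord(seq.id, "".join(residues))
        found = False
        for repeat in repeat_lib:
            for hit in local_align(current, repeat, scoring,
                                   min_score=min_score):
                if (hit.identity_pct / 100.0 >= cfg.repeat_mask_min_identity
                        and hit.q_end - hit.q_start >= cfg.repeat_mask_min_len):
                    for i in range(hit.q_start, hit.q_end):
                        residues[i] = "N"
                    new_spans.append((hit.q_start, hit.q_end))
                    found = True
                    break
        if not found:
            break
    return SequenceRecord(seq.id, "".join(residues), seq.source_tag, new_spans)


def screen_vector(seq: SequenceRecord, vector_lib: Sequence[SequenceRecord],
                  cfg: CleaningConfig,
                  scoring: AlignmentScoring = AlignmentScoring()) -> SequenceRecord:
    """Trim vector contamination from the sequence ends.

    Vector matches (identity >= ``vector_trim_min_identity``, length >=
    ``vector_min_len``) whose query span starts/ends within
    ``vector_terminal_margin`` of a sequence end are cut off together
    with everything outward of them.  Internal vector hits are only
    logged, mirroring the usual screening practice of flagging putative
    chimeras instead of splitting them.
    """
    if not vector_lib or not seq.residues:
        return seq
    min_score = _qualifying_min_score(cfg.vector_trim_min_identity,
                                      cfg.vector_min_len, scoring)
    start, end = 0, len(seq.residues)
    for vector in vector_lib:
        for hit in local_align(seq, vector, scoring, min_score=min_score):
            if (hit.identity_pct / 100.0 < cfg.vector_trim_min_identity
                    or hit.q_end - hit.q_start < cfg.vector_min_len):
                continue
            if hit.q_start <= cfg.vector_terminal_margin:
                start = max(start, hit.q_end)
            elif len(seq.residues) - hit.q_end <= cfg.vector_terminal_margin:
                end = min(end, hit.q_start)
            else:
                logger.warning(
                    "internal vector match in %s at %d-%d (left in place)",
                    seq.id, hit.q_start, hit.q_end)
    if start == 0 and end == len(seq.residues):
        return seq
    if start >= end:
        return SequenceRecord(seq.id, "", seq.source_tag)
    trimmed = seq.residues[start:end]
    return SequenceRecord(seq.id, trimmed, seq.source_tag,
                          _shift_spans(seq.masked_spans, start, len(trimmed)))


def _qualifying_min_score(min_identity: float, min_len: int,
                          scoring: AlignmentScoring) -> float:
    """Lower bound on the score of any qualifying alignment (halved for slack)."""
    per_col = min_identity * scoring.match + (1 - min_identity) * scoring.mismatch
    return max(1.0, 0.5 * min_len * per_col)


def filter_length(seqs: Iterable[SequenceRecord],
                  cfg: CleaningConfig) -> List[SequenceRecord]:
    """Keep sequences of length >= ``min_length``, preserving order."""
    return [s for s in seqs if len(s) >= cfg.min_length]


def shannon_entropy(window: str) -> float:
    """Per-symbol Shannon entropy (bits) of a nucleotide window."""
    if not window:
        return 0.0
    total = len(window)
    h = 0.0
    for base in set(window):
        p = window.count(base) / total
        h -= p * math.log2(p)
    return h


def low_entropy_spans(seq: SequenceRecord,
                      cfg: CleaningConfig) -> List[Tuple[int, int]]:
    """Windows whose entropy falls below the configured threshold.

    Reported (for the cleaning report) but never trimmed automatically.
    """
    w = cfg.entropy_window
    spans = []
    for start in range(0, max(len(seq) - w + 1, 0)):
        if shannon_entropy(seq.residues[start:start + w]) < cfg.entropy_threshold:
            spans.append((start, start + w))
    return normalize_spans(spans, len(seq))


def clean_sequences(seqs: Sequence[SequenceRecord], cfg: CleaningConfig,
                    repeat_lib: Sequence[SequenceRecord] = (),
                    vector_lib: Sequence[SequenceRecord] = (),
                    scoring: AlignmentScoring = AlignmentScoring()
                    ) -> Tuple[List[SequenceRecord], List[dict]]:
    """Full cleaning pipeline: vector -> poly tails -> repeats -> length.

    Returns the surviving records plus a report (one dict per action)
    suitable for TSV export.  The pipeline is idempotent.
    """
    report: List[dict] = []
    cleaned: List[SequenceRecord] = []
    for seq in seqs:
        step = screen_vector(seq, vector_lib, cfg, scoring)
        if len(step) != len(seq):
            report.append(_action(seq.id, "vector_trim", 0, len(seq) - len(step),
                                  "terminal vector match"))
        before = len(step)
        step = trim_poly_tails(step, cfg)
        if len(step) != before:
            report.append(_action(seq.id, "poly_tail_trim", 0, before - len(step),
                                  "terminal homopolymer run"))
        step = mask_repeats(step, repeat_lib, cfg, scoring)
        for span in step.masked_spans:
            report.append(_action(seq.id, "repeat_mask", span[0], span[1],
                                  "repeat library match"))
        for span in low_entropy_spans(step, cfg):
            report.append(_action(seq.id, "low_complexity_flag",
                                  span[0], span[1], "low entropy window"))
        if len(step) >= cfg.min_length:
            cleaned.append(step)
        else:
            report.append(_action(seq.id, "length_filter", 0, len(step),
                                  f"shorter than {cfg.min_length} bp"))
    return cleaned, report


def _action(seq_id, action, start, end, reason):
    return {"seq_id": seq_id, "action": action,
            "span_start": start, "span_end": end, "reason": reason}


class _DisjointSet:
    def __init__(self, items):
        self.parent = {item: item for item in items}

    def find(self, item):
        root = item
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[item] != root:
            self.parent[item], item = root, self.parent[item]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def sequences_overlap(a: SequenceRecord, b: SequenceRecord,
                      ccfg: ClusterConfig,
                      scoring: AlignmentScoring = AlignmentScoring()) -> bool:
    """True when the best local alignment satisfies the overlap criteria.

    The criterion is evaluated on the optimal-score alignment: identity
    over aligned columns (gaps as mismatches) >= ``min_overlap_identity``
    and aligned query span >= ``min_overlap_len``.
    """
    min_score = _qualifying_min_score(ccfg.min_overlap_identity,
                                      ccfg.min_overlap_len, scoring)
    for hit in local_align(a, b, scoring, min_score=min_score):
        if (hit.identity_pct / 100.0 >= ccfg.min_overlap_identity
                and hit.q_end - hit.q_start >= ccfg.min_overlap_len):
            return True
    return False


def _candidate_pairs(seqs: Sequence[SequenceRecord], k: int = 11):
    """Pairs sharing at least one exact k-mer (either strand)."""
    from .records import reverse_complement

    owners: Dict[str, set] = {}
    for idx, seq in enumerate(seqs):
        kmers = set()
        for strand_seq in (seq.residues, reverse_complement(seq.residues)):
            for pos in range(len(strand_seq) - k + 1):
                kmer = strand_seq[pos:pos + k]
                if "N" not in kmer:
                    kmers.add(kmer)
        for kmer in kmers:
            owners.setdefault(kmer, set()).add(idx)
    pairs = set()
    for members in owners.values():
        if len(members) > 1:
            ordered = sorted(members)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1:]:
                    pairs.add((a, b))
    return sorted(pairs)


def cluster_unigenes(seqs: Sequence[SequenceRecord],
                     ccfg: ClusterConfig = ClusterConfig(),
                     scoring: AlignmentScoring = AlignmentScoring()
                     ) -> List[Unigene]:
    """Single-linkage clustering over the pairwise overlap graph.

    Every input sequence ends up in exactly one Unigene; the
    representative is the longest member (ties broken by smallest id).
    Candidate pairs are pre-screened by shared exact k-mers, which
    cannot miss any pair passing the overlap criteria as long as
    ``min_overlap_len`` exceeds the seed size.
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in clustering input")
    dsu = _DisjointSet(range(len(seqs)))
    for i, j in _candidate_pairs(list(seqs)):
        if dsu.find(i) != dsu.find(j) and sequences_overlap(
                seqs[i], seqs[j], ccfg, scoring):
            dsu.union(i, j)
    components: Dict[int, List[int]] = {}
    for idx in range(len(seqs)):
        components.setdefault(dsu.find(idx), []).append(idx)
    # Deterministic unigene numbering: by smallest member id.
    ordered = sorted(components.values(),
                     key=lambda idxs: min(seqs[i].id for i in idxs))
    unigenes = []
    for number, idxs in enumerate(ordered, start=1):
        members = sorted(seqs[i].id for i in idxs)
        best = sorted((seqs[i] for i in idxs),
                      key=lambda s: (-len(s), s.id))[0]
        unigenes.append(Unigene(id=f"UG{number:05d}", members=members,
                                representative=best.residues))
    return unigenes


def annotate_unigene(u: Unigene,
                     dbs: Sequence[Tuple[str, Sequence[SequenceRecord], str]],
                     e_max: float = 1e-15,
                     min_identity_pct: float = 70.0,
                     tier_very: float = 1e-20,
                     tier_high: float = 1e-50,
                     scoring: AlignmentScoring = AlignmentScoring()) -> Unigene:
    """Annotate against an ordered database list.

    The first database (in priority order) producing a hit with
    ``E <= e_max`` and identity >= ``min_identity_pct`` supplies the
    annotation; the tier grades the E-value.  ``search_mode`` per
    database is ``"nucleotide"`` or ``"translated"`` (protein database
    searched with the translated query).
    """
    if not dbs:
        logger.warning("no annotation databases supplied for %s", u.id)
        return u
    query = SequenceRecord(u.id, u.representative)
    for name, db, mode in dbs:
        if mode == "nucleotide":
            hits = best_hits(query, db, scoring, e_max=e_max, k=5)
        elif mode == "translated":
            hits = translated_best_hits(query, db, e_max=e_max, k=5)
        else:
            raise ValueError(f"unknown search_mode {mode!r}")
        for hit in hits:
            if hit.identity_pct >= min_identity_pct:
                if hit.evalue < tier_high:
                    tier = "highly_similar"
                elif hit.evalue < tier_very:
                    tier = "very_similar"
                else:
                    tier = "similar"
                annotated = replace_annotation(u, (name, hit.subject_id,
                                                   hit.evalue,
                                                   hit.identity_pct, tier))
                return annotated
    return u


def replace_annotation(u: Unigene, annotation) -> Unigene:
    return Unigene(id=u.id, members=list(u.members),
                   representative=u.representative, annotation=annotation)


# Protein scoring for translated searches: BLOSUM62 with the customary
# gapped Karlin-Altschul constants.
_PROTEIN_LAMBDA = 0.267
_PROTEIN_K = 0.041


@lru_cache(maxsize=1)
def _protein_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def _six_frame_translations(residues: str) -> List[str]:
    from Bio.Seq import Seq

    frames = []
    for strand_seq in (residues, str(Seq(residues).reverse_complement())):
        for offset in range(3):
            frame = strand_seq[offset:]
            frame = frame[:len(frame) - len(frame) % 3]
            if frame:
                frames.append(str(Seq(frame).translate()).replace("*", "X"))
    return frames


def translated_best_hits(query: SequenceRecord,
                         db: Sequence[SequenceRecord],
                         e_max: float = 1e-15,
                         k: Optional[int] = None) -> List["AlignmentHit"]:
    """Six-frame translated search against a protein database.

    The protein subjects are stored in :class:`SequenceRecord`-like
    objects whose ``residues`` hold amino acids (validation is relaxed
    for them upstream).  Scores use BLOSUM62 with gapped-statistics
    lambda/K; identity is amino-acid identity over aligned columns.
    """
    from .align import AlignmentHit

    aligner = _protein_aligner()
    frames = _six_frame_translations(query.residues)
    if not frames or not db:
        return []
    m = max(len(f) for f in frames)
    n = sum(len(s.residues) for s in db)
    hits = []
    for subject in db:
        best = None
        for frame in frames:
            if not frame:
                continue
            score = aligner.score(frame, subject.residues)
            if score <= 0 or (best and score <= best[0]):
                continue
            aln = aligner.align(frame, subject.residues)[0]
            q0, q1, s0, s1, ident = _alignment_stats_protein(aln)
            best = (score, q0, q1, s0, s1, ident)
        if best is None:
            continue
        score, q0, q1, s0, s1, ident = best
        e = _PROTEIN_K * m * n * math.exp(-_PROTEIN_LAMBDA * score)
        if e > e_max:
            continue
        hits.append(AlignmentHit(
            query_id=query.id, subject_id=subject.id, score=float(score),
            bitscore=(_PROTEIN_LAMBDA * score - math.log(_PROTEIN_K))
            / math.log(2.0),
            evalue=e, identity_pct=ident,
            q_start=q0, q_end=q1, s_start=s0, s_end=s1, strand="+"))
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return hits[:k] if k is not None else hits


def _alignment_stats_protein(aln):
    blocks_q, blocks_s = aln.aligned
    q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s0, s1 = int(blocks_s[0][0]), int(blocks_s[-1][1])
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    ident = 100.0 * counts.identities / columns if columns else 0.0
    return q0, q1, s0, s1, ident
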