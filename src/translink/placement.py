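"""Genetic-map placement by interpolation between syntenic anchors.

Anchor markers carry both a genetic position (linkage group, cM) and a
physical position on a target pseudo-chromosome (bp), linking the two
coordinate systems.  A sequence whose reciprocal homolog falls at some
bp on a chromosome is assigned a cM position by piecewise-linear
interpolation between the nearest flanking anchors of the same linkage
group; outside the anchored span the nearest interval's local cM/bp
rate is continued and clamped to the linkage-group bounds.  When the
immediate flanking anchors disagree on the linkage group (chromosomes
syntenic to two groups) only the chromosome assignment is reported.

The module also answers the two toolkit queries: sequence -> putative
map position (top five database hits with their placements) and
locus -> candidate genes (placements within a cM window or between two
markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .align import AlignmentScoring, best_hits
from .records import SequenceRecord
from .rbh import RbhResult

logger = logging.getLogger(__name__)

STATUSES = ("interpolated", "extrapolated", "chromosome_only", "unplaced")


@dataclass
class MapLocus:
    marker_id: str
    linkage_group: str
    cm: float

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise ValueError("cM positions must be non-negative")


@dataclass
class GeneticMap:
    """A consensus genetic map: markers with (LG, cM) positions."""

    loci: List[MapLocus]
    lg_lengths: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [l.marker_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in genetic map")
        for locus in self.loci:
            self.lg_lengths.setdefault(locus.linkage_group, 0.0)
            self.lg_lengths[locus.linkage_group] = max(
                self.lg_lengths[locus.linkage_group], locus.cm)
        self._by_id = {l.marker_id: l for l in self.loci}

    def locus(self, marker_id: str) -> Optional[MapLocus]:
        return self._by_id.get(marker_id)

    @property
    def total_length_cm(self) -> float:
        return sum(self.lg_lengths.values())


@dataclass
class Anchor:
    """A marker placed on both the genetic map and a pseudo-chromosome."""

    marker_id: str
    linkage_group: str
    cm: float
    chromosome: str
    bp: int

    def __post_init__(self) -> None:
        if self.bp < 0:
            raise ValueError("bp must be non-negative")


@dataclass
class MapPlacement:
    """An inferred genetic-map position for one sequence."""

    unigene_id: str
    linkage_group: Optional[str] = None
    cm: Optional[float] = None
    status: str = "unplaced"
    flanking_anchor_ids: Tuple[Optional[str], Optional[str]] = (None, None)
    nearest_anchor_distance_bp: Optional[int] = None
    chromosome: Optional[str] = None
    bp: Optional[int] = None
    candidate_lgs: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        has_cm = self.cm is not None
        if has_cm != (self.status in ("interpolated", "extrapolated")):
            raise ValueError("cm present iff interpolated/extrapolated")


def build_anchor_table(gmap: GeneticMap,
                       marker_rbh: Sequence[RbhResult]) -> List[Anchor]:
    """Anchors from positioned reciprocal marker results, sorted by
    (chromosome, bp, marker_id)."""
    anchors = []
    for r in marker_rbh:
        locus = gmap.locus(r.unigene_id)
        if locus is None:
            logger.warning("marker %s absent from the genetic map; skipped",
                           r.unigene_id)
            continue
        if not r.is_reciprocal or r.position is None:
            logger.warning("marker %s has no genome position; skipped",
                           r.unigene_id)
            continue
        chrom, bp = r.position
        anchors.append(Anchor(marker_id=r.unigene_id,
                              linkage_group=locus.linkage_group,
                              cm=locus.cm, chromosome=chrom, bp=bp))
    anchors.sort(key=lambda a: (a.chromosome, a.bp, a.marker_id))
    return anchors


def _block_restricted(anchors: List[Anchor], chromosome: str, bp: int,
                      blocks) -> List[Anchor]:
    """Anchors of the synteny block containing ``bp``, else all on the
    chromosome."""
    if blocks:
        containing = [b for b in blocks
                      if b.chromosome == chromosome
                      and b.bp_span[0] <= bp <= b.bp_span[1]]
        if containing:
            block = min(containing,
                        key=lambda b: abs((b.bp_span[0] + b.bp_span[1]) // 2
                                          - bp))
            member_ids = {p.id for p in block.points}
            restricted = [a for a in anchors if a.marker_id in member_ids]
            if restricted:
                return restricted
    return anchors


def infer_map_position(pos: Tuple[str, int], anchors: Sequence[Anchor],
                       blocks=None,
                       lg_lengths: Optional[Dict[str, float]] = None,
                       unigene_id: str = "") -> MapPlacement:
    """Infer (LG, cM) for a physical position via flanking anchors.

    Piecewise-linear interpolation between the immediate flanking
    anchors when they share a linkage group; rate-continued,
    bounds-clamped extrapolation outside the anchored span; chromosome
    assignment only when the flanks disagree on the linkage group or a
    single anchor is available.
    """
    chromosome, bp = pos
    chrom_anchors = sorted((a for a in anchors if a.chromosome == chromosome),
                           key=lambda a: (a.bp, a.marker_id))
    if not chrom_anchors:
        return MapPlacement(unigene_id=unigene_id, chromosome=chromosome,
                            bp=bp, status="unplaced")
    chrom_anchors = _block_restricted(chrom_anchors, chromosome, bp, blocks)
    nearest = min(chrom_anchors, key=lambda a: abs(a.bp - bp))
    nearest_d = abs(nearest.bp - bp)
    if len(chrom_anchors) == 1:
        a = chrom_anchors[0]
        return MapPlacement(unigene_id=unigene_id,
                            linkage_group=None, status="chromosome_only",
                            flanking_anchor_ids=(a.marker_id, a.marker_id),
                            nearest_anchor_distance_bp=nearest_d,
                            chromosome=chromosome, bp=bp,
                            candidate_lgs=(a.linkage_group,))
    left = [a for a in chrom_anchors if a.bp <= bp]
    right = [a for a in chrom_anchors if a.bp >= bp]
    if left and right:
        a_l, a_r = left[-1], right[0]
        if a_l.linkage_group != a_r.linkage_group:
            return MapPlacement(
                unigene_id=unigene_id, status="chromosome_only",
                flanking_anchor_ids=(a_l.marker_id, a_r.marker_id),
                nearest_anchor_distance_bp=nearest_d,
                chromosome=chromosome, bp=bp,
                candidate_lgs=tuple(dict.fromkeys(
                    (a_l.linkage_group, a_r.linkage_group))))
        if a_l.bp == a_r.bp:
            cm = (a_l.cm + a_r.cm) / 2.0
        else:
            cm = a_l.cm + (a_r.cm - a_l.cm) * (bp - a_l.bp) / (a_r.bp - a_l.bp)
        return MapPlacement(unigene_id=unigene_id,
                            linkage_group=a_l.linkage_group, cm=cm,
                            status="interpolated",
                            flanking_anchor_ids=(a_l.marker_id, a_r.marker_id),
                            nearest_anchor_distance_bp=nearest_d,
                            chromosome=chromosome, bp=bp)
    # Outside the anchored span: continue the nearest interval's rate.
    edge_side = left if left else right
    edge = edge_side[-1] if left else edge_side[0]
    same_lg = [a for a in chrom_anchors if a.linkage_group == edge.linkage_group]
    if len(same_lg) < 2:
        return MapPlacement(unigene_id=unigene_id, status="chromosome_only",
                            flanking_anchor_ids=(edge.marker_id, edge.marker_id),
                            nearest_anchor_distance_bp=nearest_d,
                            chromosome=chromosome, bp=bp,
                            candidate_lgs=(edge.linkage_group,))
    if left:
        a1, a2 = same_lg[-2], same_lg[-1]
    else:
        a1, a2 = same_lg[0], same_lg[1]
    rate = 0.0 if a2.bp == a1.bp else (a2.cm - a1.cm) / (a2.bp - a1.bp)
    cm = edge.cm + rate * (bp - edge.bp)
    lg_max = (lg_lengths or {}).get(edge.linkage_group)
    if lg_max is None:
        lg_max = max(a.cm for a in same_lg)
    cm = min(max(cm, 0.0), lg_max)
    return MapPlacement(unigene_id=unigene_id,
                        linkage_group=edge.linkage_group, cm=cm,
                        status="extrapolated",
                        flanking_anchor_ids=(a1.marker_id, a2.marker_id),
                        nearest_anchor_distance_bp=nearest_d,
                        chromosome=chromosome, bp=bp)


def place_all(unigene_rbh: Sequence[RbhResult], anchors: Sequence[Anchor],
              blocks=None,
              lg_lengths: Optional[Dict[str, float]] = None
              ) -> List[MapPlacement]:
    """One placement per result, deterministically ordered.

    Positioned reciprocal results are interpolated/extrapolated; the
    rest are carried through with status ``unplaced``.  Order: placed
    results by (LG, cM, id), then chromosome-only, then unplaced.
    """
    placements = []
    for r in unigene_rbh:
        if r.is_reciprocal and r.position is not None:
            placements.append(infer_map_position(
                r.position, anchors, blocks=blocks, lg_lengths=lg_lengths,
                unigene_id=r.unigene_id))
        else:
            placements.append(MapPlacement(unigene_id=r.unigene_id,
                                           status="unplaced"))

    def sort_key(p: MapPlacement):
        if p.cm is not None:
            return (0, p.linkage_group, p.cm, p.unigene_id)
        if p.status == "chromosome_only":
            return (1, p.chromosome or "", 0.0, p.unigene_id)
        return (2, "", 0.0, p.unigene_id)

    placements.sort(key=sort_key)
    return placements


def query_position_for_sequence(seq: Union[str, SequenceRecord],
                                unigene_db: Sequence[SequenceRecord],
                                placements: Sequence[MapPlacement],
                                scoring: AlignmentScoring = AlignmentScoring(),
                                e_max: float = 1e-20,
                                k: int = 5
                                ) -> List[Tuple[str, MapPlacement]]:
    """Forward query: where does this sequence fall on the map?

    The sequence is searched against the Unigene database; the top ``k``
    hits at ``E <= e_max`` are returned with their placements (an
    ``unplaced`` placeholder when a hit has none).
    """
    if isinstance(seq, str):
        seq = SequenceRecord("query", seq)
    by_id = {p.unigene_id: p for p in placements}
    hits = best_hits(seq, list(unigene_db), scoring, e_max=e_max, k=k)
    out = []
    for hit in hits:
        placement = by_id.get(hit.subject_id,
                              MapPlacement(unigene_id=hit.subject_id,
                                           status="unplaced"))
        out.append((hit.subject_id, placement))
    return out


def query_candidates_near(placements: Sequence[MapPlacement],
                          gmap: GeneticMap,
                          marker: Optional[str] = None,
                          marker2: Optional[str] = None,
                          lg: Optional[str] = None,
                          cm: Optional[float] = None,
                          window_cm: float = 5.0
                          ) -> List[Tuple[str, str, float]]:
    """Reverse query: candidate genes near a genetic locus.

    One marker or an (LG, cM) point selects placements within
    ``+/- window_cm``; two markers (same LG) select the closed cM
    interval between them.  Returns (unigene_id, LG, cM) sorted by cM
    then id.
    """
    if marker is not None:
        locus = gmap.locus(marker)
        if locus is None:
            raise ValueError(f"marker {marker!r} not in the genetic map")
        if marker2 is not None:
            locus2 = gmap.locus(marker2)
            if locus2 is None:
                raise ValueError(f"marker {marker2!r} not in the genetic map")
            if locus.linkage_group != locus2.linkage_group:
                raise ValueError("markers not on the same linkage group")
            lg = locus.linkage_group
            lo, hi = sorted((locus.cm, locus2.cm))
        else:
            lg = locus.linkage_group
            lo, hi = locus.cm - window_cm, locus.cm + window_cm
    elif lg is not None and cm is not None:
        lo, hi = cm - window_cm, cm + window_cm
    else:
        raise ValueError("provide a marker, two markers, or (lg, cm)")
    out = [(p.unigene_id, p.linkage_group, p.cm)
           for p in placements
           if p.cm is not None and p.linkage_group == lg
           and lo <= p.cm <= hi]
    out.sort(key=lambda t: (t[2], t[0]))
    return out
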