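"""Dot-plot tables and synteny-block detection.

Homolog pairs that are positioned on both coordinate systems — a
linkage group (cM) and a pseudo-chromosome (bp) — form the points of a
comparative dot-plot.  Blocks of conserved synteny are called per
chromosome and per linkage group by chaining consecutive same-LG points
along the chromosome, tolerating a bounded number of interleaved points
from other linkage groups ("intruders", e.g. isolated translocated
genes).  A chain qualifies as a block when it contains at least
``min_pairs`` homolog pairs (default three, the usual dot-plot
colouring rule).  Block orientation records whether genetic position
increases (+) or decreases (-) along the chromosome; ties in cM
(co-segregating markers) do not break an otherwise monotone trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd


@dataclass
class HomologPoint:
    """One homolog pair with positions in both coordinate systems."""

    id: str
    linkage_group: str
    cm: float
    chromosome: str
    bp: int

    def __post_init__(self) -> None:
        if self.cm < 0 or self.bp < 0:
            raise ValueError("cM and bp must be non-negative")


@dataclass
class SyntenyBlock:
    """A run of same-LG homolog points along one chromosome."""

    block_id: str
    linkage_group: str
    chromosome: str
    points: List[HomologPoint]
    orientation: str  # plus | minus | mixed

    def __post_init__(self) -> None:
        if self.orientation not in ("plus", "minus", "mixed"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        lgs = {p.linkage_group for p in self.points}
        chroms = {p.chromosome for p in self.points}
        if lgs != {self.linkage_group} or chroms != {self.chromosome}:
            raise ValueError("block points must share (LG, chromosome)")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def cm_span(self) -> Tuple[float, float]:
        cms = [p.cm for p in self.points]
        return (min(cms), max(cms))

    @property
    def bp_span(self) -> Tuple[int, int]:
        return (self.points[0].bp, self.points[-1].bp)


@dataclass(frozen=True)
class BlockConfig:
    """Chaining parameters for block detection."""

    min_pairs: int = 3
    max_intruders: int = 2
    max_gap_bp: Optional[int] = None
    max_gap_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")
        if self.max_intruders < 0:
            raise ValueError("max_intruders must be >= 0")


def make_dotplot_table(anchors=None, placements=None,
                       pairs: Optional[Sequence[HomologPoint]] = None
                       ) -> List[HomologPoint]:
    """Assemble dot-plot points from anchors, placements and/or raw pairs.

    Entries lacking either coordinate are excluded.  Deterministic sort
    by (chromosome, bp, id).
    """
    import logging
    logger = logging.getLogger(__name__)
    points: List[HomologPoint] = []
    for a in anchors or ():
        points.append(HomologPoint(id=a.marker_id,
                                   linkage_group=a.linkage_group, cm=a.cm,
                                   chromosome=a.chromosome, bp=a.bp))
    for p in placements or ():
        if p.cm is None or p.chromosome is None or p.bp is None:
            logger.warning("placement %s lacks coordinates; excluded from "
                           "dot-plot", p.unigene_id)
            continue
        points.append(HomologPoint(id=p.unigene_id,
                                   linkage_group=p.linkage_group, cm=p.cm,
                                   chromosome=p.chromosome, bp=p.bp))
    points.extend(pairs or ())
    points.sort(key=lambda pt: (pt.chromosome, pt.bp, pt.id))
    return points


def _orientation(cms: Sequence[float]) -> str:
    diffs = [b - a for a, b in zip(cms, cms[1:])]
    if any(d > 0 for d in diffs) and all(d >= 0 for d in diffs):
        return "plus"
    if any(d < 0 for d in diffs) and all(d <= 0 for d in diffs):
        return "minus"
    return "mixed"


def detect_blocks(points: Sequence[HomologPoint],
                  cfg: BlockConfig = BlockConfig()) -> List[SyntenyBlock]:
    """Chain same-LG points along each chromosome into blocks.

    For each (chromosome, LG): the LG's points, taken in bp order, are
    chained while at most ``max_intruders`` consecutive points of other
    linkage groups (and, optionally, bounded bp/cM gaps) separate
    neighbours.  Intruders are not members, so a point can only ever
    belong to its own LG's block and blocks partition their members.
    Chains shorter than ``min_pairs`` are discarded.
    """
    by_chrom: Dict[str, List[HomologPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chromosome, []).append(p)
    blocks: List[SyntenyBlock] = []
    for chrom in sorted(by_chrom):
        chrom_points = sorted(by_chrom[chrom], key=lambda p: (p.bp, p.id))
        ranks = {id(p): i for i, p in enumerate(chrom_points)}
        for lg in sorted({p.linkage_group for p in chrom_points}):
            own = [p for p in chrom_points if p.linkage_group == lg]
            chains: List[List[HomologPoint]] = [[own[0]]]
            for prev, cur in zip(own, own[1:]):
                intruders = ranks[id(cur)] - ranks[id(prev)] - 1
                gap_bp = cur.bp - prev.bp
                gap_cm = abs(cur.cm - prev.cm)
                breaks = (intruders > cfg.max_intruders
                          or (cfg.max_gap_bp is not None
                              and gap_bp > cfg.max_gap_bp)
                          or (cfg.max_gap_cm is not None
                              and gap_cm > cfg.max_gap_cm))
                if breaks:
                    chains.append([cur])
                else:
                    chains[-1].append(cur)
            for chain in chains:
                if len(chain) >= cfg.min_pairs:
                    blocks.append(SyntenyBlock(
                        block_id="", linkage_group=lg, chromosome=chrom,
                        points=chain,
                        orientation=_orientation([p.cm for p in chain])))
    blocks.sort(key=lambda b: (b.chromosome, b.bp_span[0], b.linkage_group))
    for i, b in enumerate(blocks, start=1):
        b.block_id = f"B{i:03d}"
    return blocks


def block_summary(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Per-(LG, chromosome) block counts, sizes, spans and orientations."""
    rows = []
    for b in blocks:
        cm_lo, cm_hi = b.cm_span
        bp_lo, bp_hi = b.bp_span
        rows.append({"linkage_group": b.linkage_group,
                     "chromosome": b.chromosome, "block_id": b.block_id,
                     "n_points": b.n_points,
                     "cm_start": cm_lo, "cm_end": cm_hi,
                     "bp_start": bp_lo, "bp_end": bp_hi,
                     "orientation": b.orientation})
    df = pd.DataFrame(rows, columns=["linkage_group", "chromosome",
                                     "block_id", "n_points", "cm_start",
                                     "cm_end", "bp_start", "bp_end",
                                     "orientation"])
    return df.sort_values(["linkage_group", "chromosome", "bp_start"],
                          kind="stable").reset_index(drop=True)


def dotplot_frame(points: Sequence[HomologPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": p.id, "linkage_group": p.linkage_group, "cm": p.cm,
          "chromosome": p.chromosome, "bp": p.bp} for p in points],
        columns=["id", "linkage_group", "cm", "chromosome", "bp"])


def export_views(points: Sequence[HomologPoint],
                 blocks: Sequence[SyntenyBlock], outdir,
                 plot: bool = False) -> Dict[str, str]:
    """Write the dot-plot TSV, block TSV and LG<->chromosome pairing table.

    Outputs are byte-stable across runs for identical inputs.  With
    ``plot=True`` a dot-plot PNG is also written (requires matplotlib).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    dot = dotplot_frame(points)
    dot_path = outdir / "dotplot.tsv"
    dot.to_csv(dot_path, sep="\t", index=False, float_format="%.4f")
    written["dotplot"] = str(dot_path)

    blk = block_summary(blocks)
    blk_path = outdir / "blocks.tsv"
    blk.to_csv(blk_path, sep="\t", index=False, float_format="%.4f")
    written["blocks"] = str(blk_path)

    pairing = blk[["linkage_group", "cm_start", "cm_end", "chromosome",
                   "bp_start", "bp_end", "orientation"]]
    pair_path = outdir / "pairing.tsv"
    pairing.to_csv(pair_path, sep="\t", index=False, float_format="%.4f")
    written["pairing"] = str(pair_path)

    if plot:
        written["plot"] = _plot_dotplot(points, outdir / "dotplot.png")
    return written


def _plot_dotplot(points: Sequence[HomologPoint], path) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({p.chromosome for p in points})
    fig, axes = plt.subplots(1, max(len(chroms), 1),
                             figsize=(4 * max(len(chroms), 1), 4),
                             squeeze=False)
    lgs = sorted({p.linkage_group for p in points})
    colors = {lg: f"C{i % 10}" for i, lg in enumerate(lgs)}
    for ax, chrom in zip(axes[0], chroms):
        for lg in lgs:
            xs = [p.bp / 1e6 for p in points
                  if p.chromosome == chrom and p.linkage_group == lg]
            ys = [p.cm for p in points
                  if p.chromosome == chrom and p.linkage_group == lg]
            if xs:
                ax.scatter(xs, ys, s=12, c=colors[lg], label=lg)
        ax.set_xlabel(f"{chrom} (Mb)")
        ax.set_ylabel("genetic position (cM)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
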