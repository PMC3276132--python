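"""Format readers and writers shared by all stages.

Conventions: internal coordinates are 0-based half-open everywhere;
GFF3 (1-based inclusive) and BED (0-based half-open) are converted at
the boundary.  FASTA reading is gzip-transparent and validates the
nucleotide alphabet; FASTA writing wraps at 60 columns.  All tabular
outputs are TSV with headers.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .align import AlignmentHit
from .placement import GeneticMap, MapLocus, MapPlacement
from .records import SequenceRecord

GenePosition = Tuple[str, int, int, str]


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, source_tag: str = "") -> List[SequenceRecord]:
    """Read a (possibly gzipped, multi-line) FASTA into validated records.

    Duplicate ids and characters outside {A,C,G,T,N} raise ``ValueError``
    naming the offending record.
    """
    records: List[SequenceRecord] = []
    seen = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper(),
                                          source_tag=source_tag))
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> str:
    path = Path(path)
    bio = [BioSeqRecord(Seq(r.residues), id=r.id, description="")
           for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio)
    return str(path)


def read_positions(path, dialect: Optional[str] = None
                   ) -> Dict[str, GenePosition]:
    """Gene positions from GFF3 or BED, normalised to 0-based half-open.

    ``dialect`` is ``"gff3"`` or ``"bed"``; inferred from the file
    extension when omitted.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        if suffix in ("gff", "gff3"):
            dialect = "gff3"
        elif suffix == "bed":
            dialect = "bed"
        else:
            raise ValueError(f"cannot infer dialect from {path.name!r}; "
                             "pass dialect='gff3' or 'bed'")
    table: Dict[str, GenePosition] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 "
                                     "columns")
                chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
                start_i, end_i = int(start) - 1, int(end)
                gene_id = None
                for item in attrs.split(";"):
                    if item.startswith("ID="):
                        gene_id = item[3:]
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: missing ID attribute")
            else:
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected >= 4 BED "
                                     "columns")
                chrom, start, end, gene_id = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "+"
                start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: end <= start")
            table[gene_id] = (chrom, start_i, end_i,
                              strand if strand in "+-" else "+")
    return table


def write_gff3(positions: Dict[str, GenePosition], path) -> str:
    path = Path(path)
    rows = sorted(positions.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene_id, (chrom, start, end, strand) in rows:
            handle.write(f"{chrom}\ttranslink\tgene\t{start + 1}\t{end}\t.\t"
                         f"{strand}\t.\tID={gene_id}\n")
    return str(path)


def write_bed(positions: Dict[str, GenePosition], path) -> str:
    path = Path(path)
    rows = sorted(positions.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    with open(path, "w") as handle:
        for gene_id, (chrom, start, end, strand) in rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{gene_id}\t0\t{strand}\n")
    return str(path)


def read_genetic_map(path) -> GeneticMap:
    """Genetic map TSV with required header
    ``marker_id  linkage_group  position_cM``."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "linkage_group", "position_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: genetic map needs columns {sorted(required)}")
    loci = [MapLocus(marker_id=str(r.marker_id),
                     linkage_group=str(r.linkage_group),
                     cm=float(r.position_cM))
            for r in df.itertuples()]
    return GeneticMap(loci=loci)


def write_genetic_map(gmap: GeneticMap, path) -> str:
    df = pd.DataFrame(
        [{"marker_id": l.marker_id, "linkage_group": l.linkage_group,
          "position_cM": l.cm} for l in gmap.loci],
        columns=["marker_id", "linkage_group", "position_cM"])
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return str(path)


# 12-column blast-style tabular hits (1-based inclusive coordinates,
# subject start > end on the minus strand).
_HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                "bitscore"]


def read_hits_tsv(path) -> List[AlignmentHit]:
    df = pd.read_csv(path, sep="\t", names=_HIT_COLUMNS, comment="#")
    hits = []
    for r in df.itertuples():
        s_start, s_end, strand = ((int(r.sstart) - 1, int(r.send), "+")
                                  if r.sstart <= r.send
                                  else (int(r.send) - 1, int(r.sstart), "-"))
        hits.append(AlignmentHit(
            query_id=str(r.qseqid), subject_id=str(r.sseqid),
            score=float(r.bitscore), bitscore=float(r.bitscore),
            evalue=float(r.evalue), identity_pct=float(r.pident),
            q_start=int(r.qstart) - 1, q_end=int(r.qend),
            s_start=s_start, s_end=s_end, strand=strand))
    return hits


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> str:
    rows = []
    for h in hits:
        if h.strand == "+":
            sstart, send = h.s_start + 1, h.s_end
        else:
            sstart, send = h.s_end, h.s_start + 1
        rows.append([h.query_id, h.subject_id, f"{h.identity_pct:.2f}",
                     h.q_end - h.q_start, "", "", h.q_start + 1, h.q_end,
                     sstart, send, f"{h.evalue:.3g}", f"{h.bitscore:.1f}"])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
    return str(path)


def write_cleaning_report(report: Sequence[dict], path) -> str:
    df = pd.DataFrame(list(report), columns=["seq_id", "action",
                                             "span_start", "span_end",
                                             "reason"])
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def write_membership(unigenes, path) -> str:
    rows = []
    for u in unigenes:
        for member in u.members:
            rows.append({"unigene_id": u.id, "member_id": member,
                         "depth": u.depth,
                         "is_contig": "Y" if u.is_contig else "N"})
    pd.DataFrame(rows, columns=["unigene_id", "member_id", "depth",
                                "is_contig"]).to_csv(path, sep="\t",
                                                     index=False)
    return str(path)


def write_rbh_table(results, path) -> str:
    rows = []
    for r in results:
        fwd = r.forward_hit
        rows.append({
            "unigene_id": r.unigene_id, "category": r.category,
            "subject_id": r.subject_id or "",
            "evalue": f"{fwd.evalue:.3g}" if fwd else "",
            "bitscore": f"{fwd.bitscore:.1f}" if fwd else "",
            "identity_pct": f"{fwd.identity_pct:.1f}" if fwd else "",
            "reciprocal": "Y" if r.is_reciprocal else "N",
            "chromosome": r.position[0] if r.position else "",
            "position_bp": r.position[1] if r.position else "",
            "position_method": r.position_method})
    pd.DataFrame(rows, columns=["unigene_id", "category", "subject_id",
                                "evalue", "bitscore", "identity_pct",
                                "reciprocal", "chromosome", "position_bp",
                                "position_method"]).to_csv(path, sep="\t",
                                                           index=False)
    return str(path)


def write_placements(placements: Sequence[MapPlacement], path) -> str:
    rows = []
    for p in placements:
        rows.append({
            "unigene_id": p.unigene_id,
            "linkage_group": p.linkage_group or "",
            "cM": f"{p.cm:.4f}" if p.cm is not None else "",
            "status": p.status,
            "left_anchor": p.flanking_anchor_ids[0] or "",
            "right_anchor": p.flanking_anchor_ids[1] or "",
            "chromosome": p.chromosome or "",
            "bp": p.bp if p.bp is not None else ""})
    pd.DataFrame(rows, columns=["unigene_id", "linkage_group", "cM",
                                "status", "left_anchor", "right_anchor",
                                "chromosome", "bp"]).to_csv(path, sep="\t",
                                                            index=False)
    return str(path)


def write_summary(summary, path) -> str:
    """Summary TSV mirroring the comparative-map report tables."""
    uni, rec = summary.per_category_unidirectional, \
        summary.per_category_reciprocal
    total = summary.total_unigenes
    from .rbh import round_half_up

    def pct(x):
        return round_half_up(100.0 * x / total)

    rows = [
        {"statistic": "total_unigenes", "value": total},
        {"statistic": "unidirectional_total", "value": summary.unidirectional},
        {"statistic": "unidirectional_pct", "value": pct(summary.unidirectional)},
        {"statistic": "reciprocal_total", "value": summary.reciprocal},
        {"statistic": "reciprocal_pct", "value": pct(summary.reciprocal)},
        {"statistic": "hit_rate_pct", "value": summary.hit_rate_pct},
        {"statistic": "estimated_hit_rate_pct",
         "value": summary.estimated_hit_rate_pct},
        {"statistic": "coverage_fraction", "value": summary.coverage_fraction},
    ]
    for cat in sorted(uni):
        rows.append({"statistic": f"unidirectional_{cat}", "value": uni[cat]})
        rows.append({"statistic": f"unidirectional_{cat}_pct",
                     "value": pct(uni[cat])})
    for cat in sorted(rec):
        rows.append({"statistic": f"reciprocal_{cat}", "value": rec[cat]})
        rows.append({"statistic": f"reciprocal_{cat}_pct",
                     "value": pct(rec[cat])})
    for row in rows:  # integers stay integers in the TSV
        if isinstance(row["value"], float) and row["value"].is_integer():
            row["value"] = int(row["value"])
    pd.DataFrame(rows, columns=["statistic", "value"]).astype(
        {"value": str}).to_csv(path, sep="\t", index=False)
    return str(path)
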