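"""Synthetic genome pairs with known ground truth.

Emulates the inputs the toolkit consumes: a query species with a
genetic map and transcript evidence (ESTs), and a diverged target
species with pseudo-chromosomes, predicted genes and a gene-position
table.  An ancestral genome is simulated as alternating intergenic and
gene segments; each lineage then accumulates substitutions (and small
indels inside segments) independently at half the configured pairwise
divergence, and the target lineage optionally undergoes inversions,
translocations, gene losses and tandem duplications.  Because
chromosomes are rebuilt from their segments, gene coordinates stay
exact under every edit, and a :class:`TruthTable` records orthology,
physical positions, true genetic positions and the rearrangement log.

Genetic positions are the integral of a (possibly piecewise-constant)
local recombination rate in cM/Mb along the query chromosome, which
reproduces the realistic situation where a physically long chromosome
corresponds to a genetically short linkage group.  All draws come from
one seeded NumPy generator, so a fixed seed reproduces every output
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .placement import GeneticMap, MapLocus
from .rbh import TargetGenome
from .records import SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Synthetic 40-mer standing in for a cloning-vector fragment.
VECTOR_40MER = "GCTAGCCTGCAGGTCGACTCTAGAGGATCCCCGGGTACCG"

RateSpec = Union[float, Dict[str, List[Tuple[int, float]]]]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated genome pair.

    Defaults describe a desk-scale comparative-mapping scenario: two
    chromosomes of fifty ~1 kb genes, 10% pairwise sequence divergence
    between the species, markers on 20% of query genes, a constant
    3 cM/Mb recombination rate (the order observed for compact legume
    pseudo-chromosomes), and two to four sequencing reads per gene with
    1% read error plus occasional poly-A tails and vector fragments.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    gene_length_bp: Tuple[int, int] = (900, 1100)
    intergenic_bp: Tuple[int, int] = (300, 1500)
    divergence: float = 0.10
    indel_rate: float = 0.002
    n_inversions: int = 0
    n_translocations: int = 0
    inversion_span_genes: Tuple[int, int] = (5, 10)
    # Explicit inversions as (chromosome, first_gene, last_gene) inclusive
    # gene-rank spans; when set, n_inversions and the random span draw are
    # ignored, giving full control over the rearrangement ground truth.
    inversion_spans: Optional[Tuple[Tuple[str, int, int], ...]] = None
    translocation_span_genes: Tuple[int, int] = (3, 6)
    gene_loss_rate: float = 0.0
    tandem_dup_rate: float = 0.0
    marker_fraction: float = 0.2
    cm_per_mb: RateSpec = 3.0
    est_per_gene: Tuple[int, int] = (2, 4)
    est_length_bp: Tuple[int, int] = (250, 600)
    est_error_rate: float = 0.01
    polyA_prob: float = 0.3
    polyA_len: Tuple[int, int] = (14, 30)
    vector_prob: float = 0.1
    tc_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("divergence", "indel_rate", "gene_loss_rate",
                     "tandem_dup_rate", "marker_fraction", "est_error_rate",
                     "polyA_prob", "vector_prob", "tc_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


Segment = Tuple[str, Optional[str], str, str]
# (kind 'ig'|'gene', gene_id or None, residues, strand '+'|'-')


@dataclass
class Genome:
    """Chromosomes as ordered segment lists; coordinates derived on demand."""

    chromosomes: Dict[str, List[Segment]]

    def sequences(self) -> List[SequenceRecord]:
        return [SequenceRecord(name, "".join(seg[2] for seg in segs))
                for name, segs in self.chromosomes.items()]

    def gene_positions(self) -> Dict[str, Tuple[str, int, int, str]]:
        table = {}
        for name, segs in self.chromosomes.items():
            offset = 0
            for kind, gene_id, residues, strand in segs:
                if kind == "gene":
                    table[gene_id] = (name, offset, offset + len(residues),
                                      strand)
                offset += len(residues)
        return table

    def gene_records(self) -> List[SequenceRecord]:
        records = []
        for name in self.chromosomes:
            for kind, gene_id, residues, strand in self.chromosomes[name]:
                if kind == "gene":
                    seq = residues if strand == "+" \
                        else reverse_complement(residues)
                    records.append(SequenceRecord(gene_id, seq,
                                                  source_tag="gene"))
        return records


@dataclass
class TruthTable:
    """Ground truth for scoring every downstream module."""

    orthologs: pd.DataFrame       # query_gene, target_gene
    query_positions: pd.DataFrame  # gene_id, chromosome, start, end, strand
    target_positions: pd.DataFrame
    map_truth: pd.DataFrame       # gene_id, linkage_group, cm
    rearrangements: pd.DataFrame  # type, chromosome, detail
    est_truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["read_id", "gene_id"]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_ancestor(cfg: SimConfig,
                      rng: Optional[np.random.Generator] = None) -> Genome:
    """Ancestral genome of non-overlapping genes with intergenic spacers."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    chromosomes: Dict[str, List[Segment]] = {}
    gene_counter = 0
    for c in range(1, cfg.n_chromosomes + 1):
        name = f"chr{c}"
        segs: List[Segment] = []
        for _ in range(cfg.genes_per_chromosome):
            ig_len = int(rng.integers(cfg.intergenic_bp[0],
                                      cfg.intergenic_bp[1] + 1))
            segs.append(("ig", None, _random_seq(rng, ig_len), "+"))
            gene_counter += 1
            g_len = int(rng.integers(cfg.gene_length_bp[0],
                                     cfg.gene_length_bp[1] + 1))
            segs.append(("gene", f"G{gene_counter:04d}",
                         _random_seq(rng, g_len), "+"))
        segs.append(("ig", None,
                     _random_seq(rng, int(rng.integers(
                         cfg.intergenic_bp[0], cfg.intergenic_bp[1] + 1))),
                     "+"))
        chromosomes[name] = segs
    return Genome(chromosomes=chromosomes)


def _mutate(residues: str, sub_rate: float, indel_rate: float,
            rng: np.random.Generator) -> str:
    """Substitutions plus short (1-3 bp) indels at the given per-site rates."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    if n == 0:
        return residues
    if sub_rate > 0:
        hits = np.nonzero(rng.random(n) < sub_rate)[0]
        if hits.size:
            # Substitute with a uniformly random *different* base.
            shifts = rng.integers(1, 4, size=hits.size)
            lut = np.zeros(256, dtype=np.int64)
            for i, b in enumerate(_BASES.tolist()):
                lut[b] = i
            arr[hits] = _BASES[(lut[arr[hits]] + shifts) % 4]
    if indel_rate > 0:
        out = []
        pos = 0
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        for site in events:
            if site < pos:  # swallowed by a previous deletion
                continue
            out.append(arr[pos:site].tobytes())
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pos = min(site + size, n)
            else:  # insertion
                out.append(arr[site:site + 1].tobytes())
                out.append(rng.choice(_BASES, size=size).tobytes())
                pos = site + 1
        out.append(arr[pos:].tobytes())
        return b"".join(out).decode("ascii")
    return arr.tobytes().decode("ascii")


def _mutate_genome(genome: Genome, sub_rate: float, indel_rate: float,
                   rng: np.random.Generator) -> Genome:
    mutated = {}
    for name, segs in genome.chromosomes.items():
        mutated[name] = [(kind, gid, _mutate(res, sub_rate, indel_rate, rng),
                          strand) for kind, gid, res, strand in segs]
    return Genome(chromosomes=mutated)


def _gene_indices(segs: List[Segment]) -> List[int]:
    return [i for i, s in enumerate(segs) if s[0] == "gene"]


def _apply_inversion(segs: List[Segment], gi_lo: int, gi_hi: int
                     ) -> List[Segment]:
    """Reverse-complement the segment span covering genes gi_lo..gi_hi."""
    gene_idx = _gene_indices(segs)
    lo, hi = gene_idx[gi_lo], gene_idx[gi_hi]
    span = segs[lo:hi + 1]
    flipped = [(kind, gid, reverse_complement(res),
                ("-" if strand == "+" else "+") if kind == "gene" else "+")
               for kind, gid, res, strand in reversed(span)]
    return segs[:lo] + flipped + segs[hi + 1:]


def evolve_genomes(ancestor: Genome, cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[Genome, Genome, TruthTable]:
    """Derive the query and target genomes and record the ground truth.

    Each lineage mutates independently at ``divergence / 2`` (and
    ``indel_rate / 2``); rearrangements, losses and duplications apply
    to the target lineage only.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    half_sub = cfg.divergence / 2.0
    half_indel = cfg.indel_rate / 2.0
    query = _mutate_genome(ancestor, half_sub, half_indel, rng)
    target = _mutate_genome(ancestor, half_sub, half_indel, rng)

    log_rows = []
    chrom_names = sorted(target.chromosomes)

    # Inversions: non-overlapping gene spans, one chromosome at a time.
    used_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    if cfg.inversion_spans is not None:
        for chrom, start, stop in cfg.inversion_spans:
            n_genes = len(_gene_indices(target.chromosomes[chrom]))
            if not 0 <= start <= stop < n_genes:
                raise ValueError(
                    f"inversion span {start}-{stop} outside chromosome "
                    f"{chrom} ({n_genes} genes)")
            if any(not (stop < lo or start > hi)
                   for lo, hi in used_spans[chrom]):
                raise ValueError("explicit inversion spans overlap")
            target.chromosomes[chrom] = _apply_inversion(
                target.chromosomes[chrom], start, stop)
            used_spans[chrom].append((start, stop))
            log_rows.append({"type": "inversion", "chromosome": chrom,
                             "detail": f"genes {start}-{stop}"})
    for _ in range(cfg.n_inversions if cfg.inversion_spans is None else 0):
        for _attempt in range(100):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            n_genes = len(_gene_indices(target.chromosomes[chrom]))
            span = int(rng.integers(cfg.inversion_span_genes[0],
                                    cfg.inversion_span_genes[1] + 1))
            if span >= n_genes:
                continue
            start = int(rng.integers(0, n_genes - span))
            if any(not (start + span - 1 < lo or start > hi)
                   for lo, hi in used_spans[chrom]):
                continue
            target.chromosomes[chrom] = _apply_inversion(
                target.chromosomes[chrom], start, start + span - 1)
            used_spans[chrom].append((start, start + span - 1))
            log_rows.append({"type": "inversion", "chromosome": chrom,
                             "detail": f"genes {start}-{start + span - 1}"})
            break

    # Translocations: move a gene span to the end of another chromosome.
    for _ in range(cfg.n_translocations):
        if len(chrom_names) < 2:
            break
        for _attempt in range(100):
            src, dst = rng.choice(len(chrom_names), size=2, replace=False)
            src_name, dst_name = chrom_names[int(src)], chrom_names[int(dst)]
            segs = target.chromosomes[src_name]
            gene_idx = _gene_indices(segs)
            span = int(rng.integers(cfg.translocation_span_genes[0],
                                    cfg.translocation_span_genes[1] + 1))
            if span >= len(gene_idx):
                continue
            start = int(rng.integers(0, len(gene_idx) - span))
            lo, hi = gene_idx[start], gene_idx[start + span - 1]
            moved = segs[lo:hi + 1]
            target.chromosomes[src_name] = segs[:lo] + segs[hi + 1:]
            target.chromosomes[dst_name] = \
                target.chromosomes[dst_name] + moved
            log_rows.append({"type": "translocation",
                             "chromosome": f"{src_name}->{dst_name}",
                             "detail": f"genes {start}-{start + span - 1}"})
            break

    # Gene loss and tandem duplication.
    lost: List[str] = []
    duplicated: List[Tuple[str, str]] = []
    for chrom in chrom_names:
        new_segs: List[Segment] = []
        for seg in target.chromosomes[chrom]:
            if seg[0] == "gene" and rng.random() < cfg.gene_loss_rate:
                lost.append(seg[1])
                log_rows.append({"type": "loss", "chromosome": chrom,
                                 "detail": seg[1]})
                continue
            new_segs.append(seg)
            if seg[0] == "gene" and rng.random() < cfg.tandem_dup_rate:
                dup_id = seg[1] + "_d"
                new_segs.append(("gene", dup_id, seg[2], seg[3]))
                duplicated.append((seg[1], dup_id))
                log_rows.append({"type": "duplication", "chromosome": chrom,
                                 "detail": f"{seg[1]}->{dup_id}"})
        target.chromosomes[chrom] = new_segs

    query_positions = _positions_frame(query)
    target_positions = _positions_frame(target)
    ortho_rows = [{"query_gene": gid, "target_gene": gid}
                  for gid in query_positions["gene_id"]
                  if gid not in lost]
    truth = TruthTable(
        orthologs=pd.DataFrame(ortho_rows,
                               columns=["query_gene", "target_gene"]),
        query_positions=query_positions,
        target_positions=target_positions,
        map_truth=pd.DataFrame(columns=["gene_id", "linkage_group", "cm"]),
        rearrangements=pd.DataFrame(
            log_rows, columns=["type", "chromosome", "detail"]))
    return query, target, truth


def _positions_frame(genome: Genome) -> pd.DataFrame:
    rows = [{"gene_id": gid, "chromosome": chrom, "start": start,
             "end": end, "strand": strand}
            for gid, (chrom, start, end, strand)
            in genome.gene_positions().items()]
    rows.sort(key=lambda r: (r["chromosome"], r["start"]))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start",
                                       "end", "strand"])


def _rate_segments(cfg: SimConfig, chromosome: str
                   ) -> List[Tuple[int, float]]:
    if isinstance(cfg.cm_per_mb, dict):
        return sorted(cfg.cm_per_mb[chromosome])
    return [(0, float(cfg.cm_per_mb))]


def cm_at(cfg: SimConfig, chromosome: str, bp: int) -> float:
    """Genetic position: integral of the local cM/Mb rate from 0 to bp."""
    total = 0.0
    segments = _rate_segments(cfg, chromosome)
    for i, (start, rate) in enumerate(segments):
        end = segments[i + 1][0] if i + 1 < len(segments) else None
        hi = bp if end is None else min(bp, end)
        if hi > start:
            total += rate * (hi - start) / 1e6
        if end is not None and bp <= end:
            break
    return total


def simulate_genetic_map(query: Genome, cfg: SimConfig,
                         rng: Optional[np.random.Generator] = None,
                         truth: Optional[TruthTable] = None
                         ) -> Tuple[GeneticMap, List[SequenceRecord]]:
    """Promote a random fraction of query genes to mapped markers.

    True cM for *every* query gene is recorded in the truth table; the
    returned map lists only the marker subset.  Linkage-group names
    mirror the query chromosomes (chr1 -> LG1).  LG lengths are the cM
    at each chromosome end, so extrapolation bounds are well defined.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    positions = query.gene_positions()
    gene_seqs = {g.id: g for g in query.gene_records()}
    map_rows = []
    loci = []
    marker_records = []
    for gid in sorted(positions):
        chrom, start, end, _ = positions[gid]
        lg = "LG" + chrom.removeprefix("chr")
        cm = cm_at(cfg, chrom, (start + end) // 2)
        map_rows.append({"gene_id": gid, "linkage_group": lg, "cm": cm})
        if rng.random() < cfg.marker_fraction:
            loci.append(MapLocus(marker_id=gid, linkage_group=lg, cm=cm))
            marker_records.append(gene_seqs[gid])
    lg_lengths = {}
    for name, segs in query.chromosomes.items():
        length = sum(len(s[2]) for s in segs)
        lg_lengths["LG" + name.removeprefix("chr")] = cm_at(cfg, name, length)
    gmap = GeneticMap(loci=loci, lg_lengths=lg_lengths)
    if truth is not None:
        truth.map_truth = pd.DataFrame(
            map_rows, columns=["gene_id", "linkage_group", "cm"])
    return gmap, marker_records


def simulate_ests(query: Genome, cfg: SimConfig,
                  rng: Optional[np.random.Generator] = None,
                  truth: Optional[TruthTable] = None
                  ) -> List[SequenceRecord]:
    """Sequencing reads from random gene subintervals.

    Per-base errors at ``est_error_rate``; a poly-A tail is appended
    with ``polyA_prob`` and a vector 40-mer prepended with
    ``vector_prob``, exercising the cleaning operators.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    reads = []
    truth_rows = []
    counter = 0
    for gene in query.gene_records():
        n_reads = int(rng.integers(cfg.est_per_gene[0],
                                   cfg.est_per_gene[1] + 1))
        for _ in range(n_reads):
            length = min(len(gene),
                         int(rng.integers(cfg.est_length_bp[0],
                                          cfg.est_length_bp[1] + 1)))
            start = int(rng.integers(0, len(gene) - length + 1))
            residues = _mutate(gene.residues[start:start + length],
                               cfg.est_error_rate, 0.0, rng)
            if rng.random() < cfg.polyA_prob:
                residues += "A" * int(rng.integers(cfg.polyA_len[0],
                                                   cfg.polyA_len[1] + 1))
            if rng.random() < cfg.vector_prob:
                residues = VECTOR_40MER + residues
            counter += 1
            read_id = f"EST{counter:05d}"
            reads.append(SequenceRecord(read_id, residues, source_tag="EST"))
            truth_rows.append({"read_id": read_id, "gene_id": gene.id})
    if truth is not None:
        truth.est_truth = pd.DataFrame(truth_rows,
                                       columns=["read_id", "gene_id"])
    return reads


@dataclass
class SimBundle:
    """Everything one simulation run produces."""

    cfg: SimConfig
    query: Genome
    target_genome: Genome
    target: TargetGenome
    gmap: GeneticMap
    markers: List[SequenceRecord]
    ests: List[SequenceRecord]
    truth: TruthTable


def simulate_bundle(cfg: SimConfig) -> SimBundle:
    """Run the whole generator: ancestor -> lineages -> map -> reads.

    A single generator seeded from ``cfg.seed`` drives every stage, so
    two calls with the same config are identical.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = simulate_ancestor(cfg, rng)
    query, target_genome, truth = evolve_genomes(ancestor, cfg, rng)
    gmap, markers = simulate_genetic_map(query, cfg, rng, truth)
    ests = simulate_ests(query, cfg, rng, truth)

    gene_records = target_genome.gene_records()
    tcs = []
    if cfg.tc_fraction > 0:
        take = rng.random(len(gene_records)) < cfg.tc_fraction
        tcs = [SequenceRecord("TC_" + g.id, g.residues, source_tag="TC")
               for g, t in zip(gene_records, take) if t]
    target = TargetGenome(
        predicted_genes=gene_records,
        transcript_contigs=tcs,
        genomic_seqs=target_genome.sequences(),
        gene_positions=target_genome.gene_positions(),
        coverage_fraction=1.0)
    return SimBundle(cfg=cfg, query=query, target_genome=target_genome,
                     target=target, gmap=gmap, markers=markers, ests=ests,
                     truth=truth)


def write_bundle(bundle: SimBundle, outdir) -> Dict[str, str]:
    """Write the complete input bundle plus truth tables to ``outdir``."""
    from pathlib import Path

    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["ests"] = tio.write_fasta(bundle.ests, outdir / "ests.fasta")
    paths["markers"] = tio.write_fasta(bundle.markers,
                                       outdir / "markers.fasta")
    paths["predicted_genes"] = tio.write_fasta(
        bundle.target.predicted_genes, outdir / "target_genes.fasta")
    paths["transcript_contigs"] = tio.write_fasta(
        bundle.target.transcript_contigs, outdir / "target_tcs.fasta")
    paths["genomic"] = tio.write_fasta(bundle.target.genomic_seqs,
                                       outdir / "target_genomic.fasta")
    paths["positions"] = tio.write_gff3(bundle.target.gene_positions,
                                        outdir / "target_genes.gff3")
    paths["map"] = tio.write_genetic_map(bundle.gmap, outdir / "map.tsv")
    assoc = pd.DataFrame(
        [{"marker_id": m.id, "sequence_id": m.id} for m in bundle.markers],
        columns=["marker_id", "sequence_id"])
    assoc_path = outdir / "marker_assoc.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False)
    paths["marker_assoc"] = str(assoc_path)
    for name in ("orthologs", "query_positions", "target_positions",
                 "map_truth", "rearrangements", "est_truth"):
        path = outdir / f"truth_{name}.tsv"
        getattr(bundle.truth, name).to_csv(path, sep="\t", index=False)
        paths[f"truth_{name}"] = str(path)
    return paths
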