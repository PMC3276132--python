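"""End-to-end orchestration: clean -> cluster -> annotate -> reciprocal
search -> map placement -> synteny -> summary.

Given the input bundle (transcript FASTA, target-genome FASTAs and gene
positions, genetic map, marker sequences) the pipeline writes every
stage's table plus a machine-readable manifest (package version, config
digest, input paths, stages run).  Reruns on identical inputs and
configuration reproduce identical bytes, which the manifest makes easy
to audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__, io as tio
from .align import AlignmentScoring
from .config import ToolkitConfig
from .placement import build_anchor_table, place_all
from .rbh import TargetGenome, rbh_from_hits, rbh_pipeline, summarize_rbh
from .records import SequenceRecord
from .synteny import BlockConfig, detect_blocks, export_views, \
    make_dotplot_table
from .unigene import CleaningConfig, ClusterConfig, Unigene, \
    annotate_unigene, clean_sequences, cluster_unigenes

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """Paths to the input bundle (all plain-text; FASTA may be gzipped)."""

    transcripts: str
    target_genes: str
    target_genomic: str
    positions: str
    genetic_map: str
    marker_seqs: str
    target_tcs: Optional[str] = None
    marker_assoc: Optional[str] = None
    repeat_lib: Optional[str] = None
    vector_lib: Optional[str] = None
    hits_in: Optional[str] = None
    coverage_fraction: float = 1.0

    def required_paths(self) -> List[str]:
        return [self.transcripts, self.target_genes, self.target_genomic,
                self.positions, self.genetic_map, self.marker_seqs]


def load_target(inputs: PipelineInputs) -> TargetGenome:
    return TargetGenome(
        predicted_genes=tio.read_fasta(inputs.target_genes, "gene"),
        transcript_contigs=(tio.read_fasta(inputs.target_tcs, "TC")
                            if inputs.target_tcs else []),
        genomic_seqs=tio.read_fasta(inputs.target_genomic, "genomic"),
        gene_positions=tio.read_positions(inputs.positions),
        coverage_fraction=inputs.coverage_fraction)


def run_pipeline(config: ToolkitConfig, inputs: PipelineInputs,
                 outdir=None) -> Dict[str, str]:
    """Execute every stage and write the output bundle.

    Validates all required inputs up front so a missing file fails
    before any stage runs.  Returns the paths written, keyed by stage.
    """
    missing = [p for p in inputs.required_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            "missing input file(s): " + ", ".join(sorted(missing)))
    for optional in (inputs.target_tcs, inputs.marker_assoc,
                     inputs.repeat_lib, inputs.vector_lib, inputs.hits_in):
        if optional and not Path(optional).exists():
            raise FileNotFoundError(f"missing input file: {optional}")

    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scoring = AlignmentScoring()
    written: Dict[str, str] = {}

    # --- clean ---------------------------------------------------------
    raw = tio.read_fasta(inputs.transcripts, "EST")
    repeat_lib = tio.read_fasta(inputs.repeat_lib) if inputs.repeat_lib else []
    vector_lib = tio.read_fasta(inputs.vector_lib) if inputs.vector_lib else []
    ccfg = CleaningConfig(min_length=config.min_length,
                          polyA_min_run=config.polyA_min_run)
    cleaned, report = clean_sequences(raw, ccfg, repeat_lib, vector_lib,
                                      scoring)
    written["cleaning_report"] = tio.write_cleaning_report(
        report, outdir / "cleaning_report.tsv")
    written["cleaned"] = tio.write_fasta(cleaned, outdir / "cleaned.fasta")

    # --- cluster -------------------------------------------------------
    cluster_cfg = ClusterConfig(min_overlap_identity=config.cluster_identity,
                                min_overlap_len=config.min_overlap_len)
    unigenes = cluster_unigenes(cleaned, cluster_cfg, scoring)
    written["membership"] = tio.write_membership(
        unigenes, outdir / "unigene_membership.tsv")
    written["unigenes"] = tio.write_fasta(
        [SequenceRecord(u.id, u.representative) for u in unigenes],
        outdir / "unigenes.fasta")

    # --- annotate (against the target predicted genes) -----------------
    target = load_target(inputs)
    dbs = [("target_genes", target.predicted_genes, "nucleotide")]
    unigenes = [annotate_unigene(u, dbs, e_max=config.annot_e,
                                 min_identity_pct=config.min_identity_pct,
                                 tier_very=config.tier_very_e,
                                 tier_high=config.tier_high_e,
                                 scoring=scoring) for u in unigenes]
    written["annotation"] = _write_annotation(
        unigenes, outdir / "annotation.tsv")

    # --- reciprocal homolog search -------------------------------------
    hits_precomputed = inputs.hits_in is not None
    if hits_precomputed:
        hits = tio.read_hits_tsv(inputs.hits_in)
        results = rbh_from_hits(hits, [u.id for u in unigenes], target,
                                e_max=config.e_max)
    else:
        results = rbh_pipeline(unigenes, target, scoring,
                               e_max=config.e_max,
                               window_bp=config.window_bp)
    written["rbh"] = tio.write_rbh_table(results, outdir / "rbh.tsv")

    # --- anchors from marker sequences ---------------------------------
    gmap = tio.read_genetic_map(inputs.genetic_map)
    markers = tio.read_fasta(inputs.marker_seqs, "marker")
    assoc = _read_assoc(inputs.marker_assoc)
    marker_unigenes = [Unigene(id=assoc.get(m.id, m.id), members=[m.id],
                               representative=m.residues) for m in markers]
    marker_db = [SequenceRecord(mu.id, mu.representative)
                 for mu in marker_unigenes]
    from .rbh import rbh_search, resolve_position
    marker_results = []
    for mu in marker_unigenes:
        r = rbh_search(mu, target, marker_db, scoring,
                       e_max=config.e_max, window_bp=config.window_bp)
        marker_results.append(resolve_position(r, target, scoring,
                                               e_max=config.e_max))
    anchors = build_anchor_table(gmap, marker_results)

    # --- placement -----------------------------------------------------
    placements = place_all(results, anchors, lg_lengths=gmap.lg_lengths)
    written["placements"] = tio.write_placements(
        placements, outdir / "placements.tsv")

    # --- synteny -------------------------------------------------------
    points = make_dotplot_table(anchors=anchors, placements=placements)
    blocks = detect_blocks(points, BlockConfig(
        min_pairs=config.min_pairs, max_intruders=config.max_intruders))
    written.update(export_views(points, blocks, outdir))

    # --- summary -------------------------------------------------------
    summary = summarize_rbh(results, total_unigenes=len(unigenes),
                            coverage_fraction=inputs.coverage_fraction)
    written["summary"] = tio.write_summary(summary, outdir / "summary.tsv")

    manifest = {
        "package": "translink",
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "inputs": {k: v for k, v in vars(inputs).items()},
        "alignment_stage": ("precomputed_hits" if hits_precomputed
                            else "builtin_aligner"),
        "stages": ["clean", "cluster", "annotate", "rbh", "place",
                   "synteny", "summarize"],
        "outputs": {k: str(Path(v).name) for k, v in sorted(written.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    written["manifest"] = str(manifest_path)
    return written


def _write_annotation(unigenes, path) -> str:
    import pandas as pd

    rows = []
    for u in unigenes:
        if u.annotation:
            db, subject, ev, ident, tier = u.annotation
            rows.append({"unigene_id": u.id, "db": db, "subject_id": subject,
                         "evalue": f"{ev:.3g}", "identity_pct": f"{ident:.1f}",
                         "tier": tier})
        else:
            rows.append({"unigene_id": u.id, "db": "", "subject_id": "",
                         "evalue": "", "identity_pct": "", "tier": ""})
    pd.DataFrame(rows, columns=["unigene_id", "db", "subject_id", "evalue",
                                "identity_pct", "tier"]).to_csv(
        path, sep="\t", index=False)
    return str(path)


def _read_assoc(path) -> Dict[str, str]:
    if not path:
        return {}
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {str(r.sequence_id): str(r.marker_id) for r in df.itertuples()}
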