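# translink

A translational-genomics toolkit for transferring positional information
from a sequenced model genome to a related, less-characterized species.
Given a set of transcript reads from the query species, an annotated
target genome (predicted genes, transcript contigs, pseudo-chromosomes)
and a genetic map with marker sequences, `translink`:

1. **cleans and clusters** the reads into a non-redundant Unigene set
   (vector screening, poly-A/T trimming, repeat masking, length filter,
   single-linkage clustering at 95% identity over ≥ 40 bp overlaps);
2. **annotates** each Unigene against reference databases with tiered
   similarity labels (`similar` / `very_similar` / `highly_similar`);
3. finds **best reciprocal homologs (RBH)** against the union of the
   target's predicted genes, transcript contigs and genomic sequence —
   for genomic hits the reverse query is the matched segment ± 2 kb —
   and positions each reciprocal pair on the target pseudo-chromosomes;
4. builds **anchor markers** (map loci whose homologs have physical
   positions) and **places** every positioned Unigene on the genetic
   map by piecewise-linear cM interpolation between flanking anchors;
5. detects **synteny blocks** (runs of ≥ 3 same-linkage-group homologs
   along a chromosome, tolerating a bounded number of intruding points)
   and exports dot-plot, block and LG↔chromosome pairing tables;
6. answers the two working-geneticist queries: *where does this
   sequence map?* and *which genes lie near this locus / between these
   two markers?*;
7. ships a **simulator** that generates genome pairs with controlled
   divergence, rearrangements, genetic maps and sequencing reads, plus
   complete ground truth, so every stage is testable offline.

The alignment engine is a built-in seed-and-extend local aligner
(exact 11-mer seeds, banded extension, affine gaps) with Karlin–Altschul
E-values; large external runs can substitute a precomputed 12-column
blast-style hit table (`--hits-in`).

## Quick start

Simulate an input bundle (two chromosomes, fifty ~1 kb genes each, 10%
divergence, markers on 20% of genes) and run the full pipeline:

```
translink simulate --seed 42 -o demo/bundle
translink run \
  --transcripts demo/bundle/ests.fasta \
  --target-genes demo/bundle/target_genes.fasta \
  --target-genomic demo/bundle/target_genomic.fasta \
  --positions demo/bundle/target_genes.gff3 \
  --map demo/bundle/map.tsv \
  --marker-seqs demo/bundle/markers.fasta \
  --marker-assoc demo/bundle/marker_assoc.tsv \
  -o demo/out
```

`demo/out/` then contains the cleaned reads, Unigene membership and
FASTA, annotation, RBH and placement tables, dot-plot/block/pairing
views, a summary and a `manifest.json` recording the configuration
digest. The run above prints `wrote 12 outputs to demo/out` and yields,
for example:

```
$ head -6 demo/out/summary.tsv
statistic	value
total_unigenes	86
unidirectional_total	86
unidirectional_pct	100
reciprocal_total	77
reciprocal_pct	90

$ head -4 demo/out/placements.tsv
unigene_id	linkage_group	cM	status	left_anchor	right_anchor	chromosome	bp
UG00001	LG1	0.0029	interpolated	G0001	G0001	chr1	949
UG00002	LG1	0.0089	interpolated	G0002	G0002	chr1	2951
UG00004	LG1	0.0228	interpolated	G0003	G0010	chr1	7603

$ head -3 demo/out/blocks.tsv
linkage_group	chromosome	block_id	n_points	cm_start	cm_end	bp_start	bp_end	orientation
LG1	chr1	B001	49	0.0029	0.2827	949	94283	plus
LG2	chr2	B002	56	0.0024	0.2890	785	98467	plus
```

Query a sequence's putative map position, or the candidate genes near a
marker:

```
$ translink query-position --sequence CAATAGCCTGGCCGAAGG... \
    --unigenes demo/out/unigenes.fasta --placements demo/out/placements.tsv
query	UG00004	LG1	0.0228	interpolated

$ translink query-candidates --placements demo/out/placements.tsv \
    --map demo/bundle/map.tsv --marker G0003 --window-cm 0.02
UG00001	LG1	0.0029
UG00002	LG1	0.0089
UG00004	LG1	0.0228
UG00006	LG1	0.0323
```

Every stage is also available as its own subcommand (`clean`,
`cluster`, `annotate`, `rbh`, `place`, `synteny`, `summarize`,
`simulate`) and as a Python API:

```python
import translink as tl

bundle = tl.simulate_bundle(tl.SimConfig(seed=42))
unigenes = [tl.Unigene(id=g.id, members=[g.id], representative=g.residues)
            for g in bundle.query.gene_records()]
results = tl.rbh_pipeline(unigenes, bundle.target)
summary = tl.summarize_rbh(results, total_unigenes=len(unigenes))
```

## Tests and acceptance metrics

```
python -m pytest -q tests/          # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script simulates its own data at runtime and writes one
JSON object per metric (`{"value": ..., "n": ...}`): summary-table
arithmetic, RBH recall/precision, placement error versus anchor
spacing, inversion-block recovery, pipeline byte-determinism and
clustering-invariant pass rate. `tests/test_acceptance.py` asserts the
release criteria on the same constructions.

All outputs are deterministic: a fixed seed fixes every simulated byte,
and rerunning the pipeline on identical inputs reproduces identical
files. See `docs/methods.md` for the scientific model, parameter
defaults and their rationale, and known limitations.
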