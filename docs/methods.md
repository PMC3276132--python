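# Methods

This note records the scientific model behind `translink`, the default
parameters and why they were chosen, the scope of the simulator, and
the numerical conventions that affect results.

## Problem setting

A query species has abundant transcript reads and a marker-based
genetic map, but no assembled genome. A related target species has an
annotated genome: predicted gene models, transcript contigs (TCs) from
an EST-assembly index, and pseudo-chromosome/BAC genomic sequence. The
toolkit builds the bridge in three steps: a non-redundant Unigene set
for the query, best reciprocal homologs (RBH) between Unigenes and the
target databases, and a cM↔bp correspondence through anchor markers
that lets any positioned homolog be expressed as a genetic-map
position and vice versa.

## Sequence cleaning and clustering (module `unigene`)

Cleaning order: vector screening → poly-A/T trimming → repeat masking
→ length filter. Vector hits are trimmed only when the matched segment
lies within 50 bp of a read end (internal vector indicates a chimeric
read and is logged, not cut). Poly-A (3′) and poly-T (5′) tails are
removed when the terminal homopolymer run is ≥ 12 nt. Repeats are
masked to `N` when a library entry aligns at ≥ 80% identity over
≥ 40 bp, iterating until no further hit. Reads shorter than 100 nt
after cleaning are dropped. Low-complexity segments (Shannon entropy
< 1.0 bit over 20-nt windows) are reported but not removed, since they
also occur in genuine coding sequence.

Clustering is single-linkage over the overlap graph: two reads are
joined when their best local alignment has ≥ 95% identity over a query
span of ≥ 40 bp (either strand). Connected components become Unigenes;
a component of ≥ 2 reads is a contig, otherwise a singleton. The
representative sequence is the longest member (ties broken
lexicographically by id) — a deliberate simplification versus consensus
calling, adequate at ≤ 1% read error. Annotation searches a ranked
database list and keeps the first hit with E ≤ 1e−15 and ≥ 70%
identity; labels grade the E-value: `similar` (≤ 1e−15),
`very_similar` (< 1e−20), `highly_similar` (< 1e−50). Protein
databases are searched in translated mode (six reading frames,
BLOSUM62, gap open 12 / extend 1, gapped Karlin–Altschul constants
λ = 0.267, K = 0.041).

## Alignment engine and statistics (module `align`)

The built-in aligner is seed-and-extend: exact 11-mer matches are
binned into diagonal bands (width 48), bands with ≥ 2 seeds are merged
into candidate regions (top 8 by seed count), and each region is
aligned with an affine-gap local DP restricted to a window around the
region; pairs below 50,000 DP cells skip seeding and run the full DP
directly. Both strands are searched (the query is reverse-complemented
and coordinates mapped back). Scoring defaults: match +1, mismatch −2,
gap open 5, gap extend 2, so a gap of length L costs 5 + 2L; `N` never
matches. Identity is computed over aligned columns with gap columns
counted as mismatches.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with λ = 1.28,
K = 0.46 (representative of nucleotide scoring near these defaults);
m is the query length, n the summed database length, so hits from the
three target databases are comparable. The thresholds in use — 1e−20
for RBH, 1e−15 for annotation, 1e−50/1e−20 for the annotation tiers —
are operational conventions of the comparative-mapping literature. The
E-value threshold is converted to a minimum raw score before alignment
so regions are scored first and only reconstructed when they can pass.

Correctness of the aligner is established in the test suite against an
independent quadratic-DP Smith–Waterman oracle implemented from
scratch (`tests/dp_oracle.py`), not by comparing the aligner with
itself.

## Best reciprocal homologs (module `rbh`)

The forward search takes the best hit over the union of predicted
genes, TCs and genomic sequence (ties broken by E-value, bitscore,
then category priority predicted gene > TC > genomic, then subject
id). The reverse query is the full subject sequence for gene/TC hits;
for genomic hits it is the matched interval extended by 2 kb on each
side, clamped to the sequence. The pair is reciprocal iff the unique
strict-best reverse hit at E ≤ 1e−20 is the original Unigene; an exact
reverse-score tie with another Unigene rejects the pair as ambiguous
rather than silently asserting a paralog.

Positions on pseudo-chromosomes: predicted genes use their annotated
interval midpoint; genomic hits use the matched-interval midpoint when
the subject is a pseudo-chromosome; TC hits relay through the TC's
best predicted-gene homolog (E ≤ 1e−20). Midpoints are used because
the downstream interpolation needs a single representative coordinate
and the midpoint is symmetric.

Summary statistics follow the conventional report format of
comparative legume mapping (Bordat *et al.* 2011, *G3*,
doi:10.1534/g3.111.000349): the hit rate is
`round_half_up(100·reciprocal/total)`, and the estimated hit rate
for a partially sequenced genome divides the **unrounded** ratio by
the genome-coverage fraction before rounding. This convention
reproduces three of four published species rows exactly; the
*L. japonicus* row prints 60 where the unrounded convention gives 59
(5433/13747 = 39.52%, /0.67 = 58.99) — the published rounding is
internally inconsistent, and this implementation deliberately keeps
the unrounded convention (asserted as 59 in the acceptance suite).

## Map placement (module `placement`)

Anchors are markers with both a map locus (LG, cM) and a genome
position (chromosome, bp). A query position is interpolated linearly
in bp between its immediate flanking anchors when both are on the same
linkage group; equal-bp flanks average their cM (which makes placement
at an anchor's own coordinate return the anchor's cM exactly). When
the flanks disagree on the linkage group — chromosomes syntenic to two
groups — only the chromosome is reported, with the candidate LGs.
Outside the anchored span, the outermost same-LG interval's local
cM/bp rate is continued and the result clamped to [0, LG length]. A
single anchor on a chromosome supports only a chromosome-level call.
When synteny blocks are supplied, interpolation is restricted to the
anchors of the block containing the query position, which insulates
placement from rearranged neighbours.

Forward queries (`query-position`) return the top 5 database hits at
E ≤ 1e−20 with their placements; reverse queries (`query-candidates`)
select placements within ± 5 cM of a marker or (LG, cM) point, or the
closed cM interval between two same-LG markers.

## Synteny blocks (module `synteny`)

Dot-plot points are homolog pairs positioned in both coordinate
systems. Blocks are called per (chromosome, LG) by chaining the LG's
points in bp order, tolerating at most 2 consecutive intruding points
from other LGs (isolated translocated genes should not shatter a
block) and optional bp/cM gap ceilings; chains of < 3 points are
discarded — the customary "at least three homologs" coloring rule.
Orientation is `plus`/`minus` when cM is monotone along the chromosome
(ties from co-segregating markers allowed), else `mixed`.

A chromosome carrying k inverted segments that are mutually adjacent
and touch a chromosome end resolves into exactly k+1 blocks (k minus,
one plus) once a cM-gap ceiling separates the segments; interior
isolated inversions resolve into 2k+1 alternating blocks. The
acceptance suite constructs the end-anchored scenario explicitly via
the simulator's `inversion_spans`.

## Simulator (module `simdata`)

A single ancestor genome (non-overlapping genes with random intergenic
spacers) is mutated independently along two lineages at divergence/2
substitutions and indel_rate/2 short indels per site, giving an
interpretable pairwise divergence. Rearrangements (inversions —
reversing gene order and strand —, translocations, gene losses, tandem
duplications) apply to the target lineage only and are logged to the
truth table. Inversion spans may be drawn randomly (`n_inversions`) or
given explicitly (`inversion_spans`). Genomes are stored as ordered
segment lists so rearranged coordinates stay exact by construction.

The genetic map promotes a random `marker_fraction` of query genes to
markers; true cM is the integral of a piecewise-constant cM/Mb rate
(default 3.0), supporting rate-heterogeneity scenarios. Transcript
reads are sampled per gene from random subintervals with per-base
error, optional poly-A tails and a vector 40-mer, exercising the
cleaning operators. One `numpy` generator seeded from `SimConfig.seed`
drives every stage, so a seed fixes all bytes of the bundle.

Scope and limits: no coalescent or population-genetic realism, no
codon-aware evolution, no realistic repeat families, uniform base
composition, at most one rearrangement class per span. Defaults
(2 chromosomes × 50 genes of 900–1100 bp, divergence 0.10, 2–4 reads
per gene at 1% error) describe a desk-scale scenario that runs in
minutes while leaving alignment identity (~90%) safely above the
clustering threshold and below trivial exactness.

## Determinism and numerical conventions

- Coordinates are 0-based half-open internally; GFF3 (1-based
  inclusive) and blast-style tables (1-based, subject start > end on
  the minus strand) are converted at the I/O boundary.
- Percentages round half-up to integers; cM values print with four
  decimals; E-values with three significant digits.
- All sorts are stable with documented keys; no timestamps appear in
  outputs; the pipeline manifest stores a SHA-256 digest of the
  configuration. Two runs on identical inputs are byte-identical,
  which the test suite and acceptance script verify.

## Known limitations

- The E-value constants are fixed defaults, not fitted to the scoring
  matrix; absolute E-values are conventional, though thresholds behave
  consistently because the same constants are used throughout.
- Unigene representatives are member sequences, not consensus calls.
- RBH positions use interval midpoints; sub-gene resolution is out of
  scope.
- Block detection is a deterministic scan, with no statistical
  significance test on block counts.
- The seed-and-extend aligner requires at least two 11-mer seed
  matches per diagonal band; extremely short or extremely diverged
  (< ~75% identity) homologies can be missed — outside the intended
  operating range of the toolkit.
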