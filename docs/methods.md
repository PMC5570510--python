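# Methods

`rpelinc` reimplements a splice-junction-aware bulk RNA-seq analysis of the
retinal pigment epithelium (RPE) transcriptome: a non-redundant transcript
database, isoform quantification from uniquely-mapped reads with an
isoform-unique junction rule, RPKM-based expression calls and concordance,
and discovery of putative novel genes from intergenic splice junctions.
This note documents the model, its parameters, the synthetic data the
package is validated on, and the numerical choices made where the design
was open.

## Coordinates and junction identity

All coordinates are 0-based half-open internally; GTF (1-based inclusive)
and STAR-style junction tables (1-based inclusive introns, strand codes
0/1/2) are converted at the file boundary. A splice junction is the intron
interval between two consecutive exons. Junction identity is
coordinate-exact with one leniency: an undefined strand (`.`) matches
either defined strand, because aligners occasionally emit junctions with
undetermined strand. `+` and `-` at the same coordinates remain distinct.

## Non-redundant annotation database

Multiple GTF sources (e.g. a comprehensive catalogue plus a lincRNA
catalogue) are merged by exon-chain signature `(chrom, strand, exon
starts/ends)`. Identical chains collapse to a single record — even under
different gene ids — keeping the first source's identifiers and recording
the provenance of every collapsed duplicate. Isoform-id collisions between
sources with *different* chains are resolved by namespacing the later id
with its source label.

From the merged database, each isoform's junction set is derived, along
with the subset of junctions present in exactly one isoform database-wide
(the *isoform-unique* junctions). Uniqueness can alternatively be scoped
within each gene (`scope="gene"`); database-wide is the default because
the unique-junction list is a single database-level artifact.

## Counting model

Raw counts are exon-level: a uniquely-mapped read contributes 1 to an exon
when any aligned block overlaps it by ≥1 bp, and an isoform's raw count is
the sum over its exons. Consequences worth knowing:

* a read spanning k exons of one isoform contributes k (exon counting then
  summation, not per-transcript read counting);
* a read in an exon shared by overlapping isoforms counts toward each of
  them;
* multi-mapping reads are discarded everywhere, and the RPKM denominator
  is the library-wide count of uniquely-mapped read records, not only
  those overlapping annotation.

The **unique-junction zero rule** disambiguates overlapping isoforms: an
isoform that owns at least one unique junction, none of which has any
junction-spanning reads in the sample, is considered not expressed and its
count is set to zero. A single observed unique junction rescues the
isoform (default `all_unobserved`); a stricter variant zeroes an isoform
whenever *any* unique junction is unobserved (`any_unobserved`). Isoforms
owning no unique junction are never zeroed — there is no isoform-specific
evidence either way.

RPKM = count × 10⁹ / (total unique reads × transcript length in bp).

## Expression calls, bins, concordance

An isoform is *expressed* in a condition when its mean RPKM across the
condition's replicates is strictly greater than 1; a gene is expressed
when any isoform is. Distributions are reported on the decade ladder
zero, (0,1], (1,10], (10,100], (100,1000], >1000 (half-open on the left,
so a value of exactly 10 falls in (1,10]).

Concordance is Pearson correlation:

* **intra** (within a condition): mean of pairwise replicate correlations,
  restricted to features expressed in that condition; features with zero
  RPKM in every replicate are excluded (they carry no information and
  would inflate r);
* **inter** (between conditions): correlation of condition-mean values
  over the intersection of the two expressed sets (union mode available);
  the reported overlap is always the intersection size.

Correlations are computed on log2(RPKM+1) by default because raw-RPKM
Pearson is dominated by a few very high expressers; raw mode is a config
switch. Gene-level expression is the sum of the gene's isoform RPKMs.
Undefined correlations (constant vectors, empty overlap) are reported as
such, never silently coerced to 0.

Gene panels (RPE signature genes; photoreceptor/choroid contamination
sets) restrict all of the above to a curated id list; unresolvable ids are
reported but not fatal.

## Novel gene discovery

1. **Filter**: observed junctions are kept when they match no annotated
   junction and their full intron interval overlaps no gene span on either
   strand; depths are pooled across the discovery condition's samples and
   must reach `min_depth` (default 1 — no depth floor).
2. **Cluster**: single-linkage with edge-to-edge intron gap ≤ 2000 bp
   (boundary inclusive), per chromosome and strand. An undefined-strand
   junction may join either strand; when both are in range it is assigned
   to the nearby cluster of larger total depth (tie → `+`).
3. **Assemble**: junction B can follow A when A's intron ends strictly
   before B's begins (strict, because equality would imply a zero-length
   internal exon). The primary isoform starts at the highest-depth
   junction and greedily extends left/right, one *tight* neighbour at a
   time (a compatible junction with nothing insertable between) —
   otherwise the greedy would jump across and silently drop internal
   exons. Internal exons are the gaps between consecutive introns;
   terminal exons are fixed at 500 bp outward (junction data cannot reveal
   transcript ends), truncated at chromosome bounds with a warning.
   Secondary isoforms are the remaining maximal junction chains in
   decreasing total-depth order, deduplicated by exon chain, up to
   `max_isoforms` (default 5).
4. **Enforce ≥3 exons**: clusters that cannot yield a ≥2-junction chain
   are counted as 2-exon candidates and reported, but never emitted.
5. **Quantify**: exon-overlap counting with no zero rule (every model
   junction is unique to it by construction) and *no* RPKM floor for
   detection — a model is detected in a sample when any supporting
   junction or exon read is observed there.

## Synthetic data generator

The generator emits a complete workspace — annotation GTFs (two
overlapping sources, so the non-redundant merge is exercised), per-sample
read tables (BED12-like) and junction tables (STAR dialect), a design
table, chromosome sizes, panel lists, and machine-readable ground truth.
Default study conditions: 200 annotated genes (140 protein-coding, 60
lincRNA), three conditions (fRPE, iPS_RPE, iPS) × three replicates,
150,000 uniquely-mapped reads per sample.

Structure and rationale:

* **Isoform structure**: coding genes carry 1–4 isoforms built as a full
  exon chain plus exon-skip variants, so isoforms share exons while each
  typically owns unique junctions; a small fraction of two-isoform genes
  instead differ only in transcription start, giving isoform pairs with
  *no* unique junctions. lincRNA genes are mostly single-isoform
  (the catalogued ratio is ≈1.04 isoforms/gene).
* **Expression classes**: high expressers (RPKM 100–1500) soak up most of
  the library; broad coding genes (3–80) are active everywhere; signature
  genes (10–150) are active only in the two RPE conditions;
  stem-cell-specific genes only in iPS; contamination-panel genes are
  mostly silent. Active lincRNA targets are log-uniform in [3.2, 7.0], so
  with sampling noise the bulk of expressed lincRNAs land in RPKM (1,10],
  the low-expression regime reported for lincRNA transcriptomes.
* **Condition correlation structure**: each gene gets a log-normal effect
  shared by fRPE and iPS_RPE (σ=0.4) and an independent effect for iPS
  (σ=0.6), so the RPE pair is the most concordant pair by construction —
  a direction the tests assert, not specific correlation values.
* **Counts**: expected count inverts the RPKM formula (count = RPKM ×
  length_kb × depth_M × log-normal replicate factor, σ=0.25) and is
  realised as Poisson. Reads are 100 bp single-block reads placed
  uniformly within exons plus two-block junction-spanning reads (15% of a
  spliced transcript's reads). Junction-table depths are Poisson with
  mean equal to the summed expected count of the isoforms containing the
  junction — the table emulates aligner output on the library and is an
  input in its own right. Libraries are topped up to exactly the
  configured depth with intergenic background reads, plus 5% multi-mapper
  records that consumers must discard. With replicate σ=0 all counts and
  depths become deterministic (`round(mean)`): the zero-noise limit is
  exactly reproducible across replicates.
* **Planted novel genes** (default 10): 3–6 exons with internal exons
  30–400 bp and introns 300–1500 bp, placed intergenically with ≥3.5 kb
  clearance; junction depth mean 8 per active sample; optional lower-depth
  alternative-donor junction creates a second isoform. Decoy junctions
  (default 10) are emitted once, in the first discovery sample, at depth
  exactly 1.
* **Determinism**: per-sample RNG streams are derived independently from
  the master seed, so adding a sample never perturbs earlier ones;
  identical configurations produce byte-identical files.

What the generator does **not** emulate: paired-end structure (pairing
adds nothing to the counting logic tested), sequence content and
sequencing error, GC/positional bias, fragment-length effects, intronic
or antisense transcription, and real lincRNA lengths (synthetic lincRNAs
are 2–4 kb so that low-RPKM isoforms still receive countable reads at
desk-scale depth; real lincRNAs are typically shorter). Passing tests
therefore demonstrate the correctness of the counting/discovery logic
under the stated statistical structure, not performance on real libraries.

## Problem sizes

The validation suite runs the full study at 200 genes × 9 samples ×
150k reads (the default conditions), plus a noise-free recovery study
with 15 planted novel genes and 30 decoys over a smaller annotation, and
file-level determinism checks at a reduced scale (34 genes, 25k reads).
These sizes were chosen so every check, including exhaustive brute-force
oracles, completes in well under a minute each.

## Known limitations

* Exon-summed counting inflates counts for multi-exon transcripts
  relative to per-read counting; RPKM values are comparable within this
  pipeline but not directly against per-read counters.
* The intergenic test is a hard span overlap: a novel junction 1 bp
  inside a gene span is rejected even if unrelated to that gene's
  structure.
* Terminal exons of novel models are a fixed 500 bp convention, not an
  estimate; transcript lengths of novel genes are reported excluding
  terminal exons for that reason.
* The per-condition expression call uses the replicate mean only; no
  variance model, no differential-expression testing, no batch
  correction.
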