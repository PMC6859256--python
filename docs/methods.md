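# Methods

## Annotation model

Four classes of tRNA-derived small RNAs are represented as genomic loci
attached to parent tRNA genes. Internal coordinates are 0-based
half-open; GTF is emitted 1-based inclusive and BED 0-based half-open,
with class, parents, subclass and flags carried in attributes so both
formats round-trip losslessly.

* **5' leader loci** are constructed, not imported: the `leader_len`
  (default 20 nt) region immediately 5' of the gene on its own strand,
  ending exactly at the gene boundary (the RNase P cleavage site). At a
  contig edge the locus is clipped and flagged
  `truncated_at_contig_boundary`; with zero upstream bases it is rejected
  with a diagnostic rather than silently emitted empty. Leaders that
  overlap a neighboring gene are flagged, never resolved — the correct
  resolution is genuinely ambiguous, and flag-only policies keep the
  catalog reproducible.
* **tRF-5 / tRF-3 / tsRNA loci** are imported from coordinate tables
  whose dialect (0-based half-open or 1-based inclusive) the caller must
  declare. `tRF-1` is accepted as an alias of tsRNA — the two names
  denote the same 3'-trailer class. Records violating their class's
  positional definition (e.g. a "trailer" upstream of the gene 3' end)
  are quarantined with reasons; tRF-5/tRF-3 loci outside the canonical
  14–30 nt range are only flagged (`length_out_of_range`), never dropped,
  so filtering decisions stay with the analyst.
* tRNA **introns** are carried for provenance but ignored by locus
  construction: all four classes are defined relative to gene/mature
  ends, not spliced bodies. The tRF-3 CCA is post-transcriptional and
  absent from genomic sequence; it is therefore not part of any locus
  (see sequence flags below).

## Counting

Union-overlap semantics with conservative ambiguity removal. A mapped
read is a candidate for any locus one of its aligned blocks overlaps by
at least `min_overlap` bases (default 1, i.e. plain union mode). Two
kinds of ambiguity are excluded and tallied separately: multi-mapping
reads (NH tag > 1, falling back to duplicate query names when NH is
absent) and feature-ambiguous reads (overlapping ≥ 2 distinct loci).
Default strandedness is same-strand, since small-RNA protocols are
stranded and fragment identity is strand-defined; `opposite` and
`ignore` are available. Per sample the identity

    sum(counts) + n_ambiguous_feature + n_multimapped_discarded
                + n_unassigned = total_mapped

is enforced at construction time, so a violated conservation law is an
error, not a silent bias. Unmapped reads are tallied apart and excluded
from `total_mapped`.

## Normalization and filtering

* RPM uses the **library-wide** mapped-read total as its denominator, so
  RPM column sums over annotation features never reach 1e6 unless every
  mapped read was assigned.
* TPM divides counts by locus length in bp and rescales each sample's
  rates to sum to 1e6; the denominator runs over the features of this
  annotation only (the counting context is the custom catalog, not a
  genome-wide gene set). All-zero samples are emitted as zero columns
  with a warning, never a division by zero.
* The expression filter removes features whose mean over samples of
  log2(TPM + pseudocount) is strictly below the threshold (defaults:
  pseudocount 1, threshold 1). The pseudocount keeps zero-TPM features
  finite and makes the threshold meaningful at TPM = 1
  (log2(1 + 1) = 1); a mean of exactly the threshold is kept. Both knobs
  are exposed on the CLI.

## Subclasses and sequence flags

Length windows (inclusive): tRF-5a 14–16, tRF-5b 22–24, tRF-5c 28–30 nt;
the tRF-3 subclasses are conventionally "about 18" and "about 22" nt,
implemented as ±1 windows tRF-3a 17–19 and tRF-3b 21–23 (configurable via
a rule TSV; rules within a class must not overlap and are validated at
load). Lengths between windows are legitimately unclassified; tsRNA and
leader loci take no subclass. An alternative rule set with the
class-specific caps sometimes used for suspect-length screening (tRF-5 ≤
31, tRF-3 ≤ 25) can be supplied through the same mechanism.

Sequence flags annotate, never filter. tsRNA loci get `polyU_3prime`
when the sense sequence ends in ≥ 3 consecutive T within the final 6 nt
(both parameters configurable) — the DNA template of the poly-U tail
left by RNase Z. For tRF-3s, a genomic check of the CCA is impossible by
construction (CCA is added post-transcriptionally), so the module
records `cca_not_genome_templated` explicitly instead of faking a
positive check; a real CCA test would need mature-space sequences.

## Differential expression

Per-feature two-group linear model on log2-scale expression
(log2(TPM+1) in the pipeline): logFC = mean(group2) − mean(group1),
residual variance s² on d = n₁ + n₂ − 2 df. The variance prior
(d0, s0²) is estimated from the ensemble of s² by moment matching on the
log scale: with e = log s² − ψ(d/2) + log(d/2),

    ψ'(d0/2) = var(e) − ψ'(d/2)
    s0² = exp( mean(e) + ψ(d0/2) − log(d0/2) )

where the trigamma equation is solved by Newton iteration. Shrunken
variances s̃² = (d0·s0² + d·s²)/(d0 + d) give the moderated
t = logFC / (s̃·√(1/n₁ + 1/n₂)) on d0 + d df, with two-sided p-values
and BH FDR. When the observed spread of log variances does not exceed
the sampling spread (homogeneous variances), the moment-matching
equation has no positive solution; d0 is then capped at 1e6 with a
warning, which in practice pins every denominator near s0². The
`prior_df` argument overrides the estimate (0 recovers the ordinary
pooled t; ∞ uses s0² exactly with normal-distribution p-values), which
the tests use to pin the two limits. Zero-variance features are excluded
from prior fitting but still testable, since d0 > 0 keeps their shrunken
denominator positive. Only two-group contrasts are supported; factors
with more levels must be recoded as binary contrasts by the caller.

BH adjustment is the standard step-up rule (order-stable, capped at 1,
cumulative-minimum monotone). Note that BH is *not* idempotent in
general — re-adjusting an adjusted vector can raise values further
(e.g. [1.0, 0.25] → [1.0, 0.5] → [1.0, 1.0]) — so the tests assert
permutation invariance and rank monotonicity, not idempotence.

## Correlation screen

All (feature, covariate) pairs over shared, pairwise-complete samples
(≥ 3 required); Pearson or Spearman (average ranks for ties), p-values
from the t-transform of r, no multiplicity adjustment — the screen is a
reporting rule, not an inference procedure. Only pairs with |r|
**strictly** greater than the threshold (default 0.5) are returned;
zero-variance or too-sparse pairs are skipped with diagnostics rather
than reported as NaN.

## Simulator

The generator emulates the statistical structure the pipeline assumes,
at defaults chosen to resemble a small but realistic library:

* genome: 4 random contigs of 10 kb; 20 tRNA genes of 70–90 bp placed
  one per 250-bp slot with ≥ 45 bp clearance on both sides (enough for
  the 20-nt leader, ≤ 40-nt trailer loci and trailer reads never to
  touch a neighbor), strand drawn at 0.5 minus fraction; 5% of genes are
  deliberately placed at contig edges with < 20 nt upstream to exercise
  leader clipping.
* loci: per gene one tRF-5 (length from the subclass windows), one tRF-3
  (likewise), one tsRNA trailer locus of 20–40 nt starting at the gene
  3' end, and the constructed leader.
* reads: category per read from a single categorical law —
  feature-ambiguous reads straddling the tRF-3/trailer junction (2%),
  multi-mapping reads (NH = 2, 5%), background reads from non-tRNA
  regions (5%), the rest split across fragments by the abundance table
  (uniform unless specified). Fragment reads obey exact class end
  anchors: tRF-5 reads start at the gene 5' end, tRF-3 reads end at the
  gene 3' end, tsRNA reads start at the trailer start (lengths uniform
  on [16,40], possibly running past short loci into intergenic space,
  which union counting still assigns uniquely), leader reads lie inside
  the leader and end at the RNase P site (lengths uniform on [14,20]).
  Substitutions at 0.001 per base; constant quality strings.
* outputs: FASTA, GTF, FASTQ, a coordinate-sorted truth BAM whose single
  alignment per read is the generating interval, and per-read truth
  tables. Byte-identical outputs for identical configs.

What the simulator does **not** emulate: indels and quality decay,
tRNA sequence structure (genes are random sequence, so the tsRNA poly-U
signature appears only at background rates), tiRNA/i-tRF classes,
genuinely multi-locus multi-mapping (NH > 1 is asserted, not realized as
multiple records), and real expression dispersion across samples.
Passing tests therefore demonstrate correctness of the counting,
normalization and inference machinery under the stated generative
model — not performance on real libraries, where alignment artifacts and
annotation overlap are harsher.

## Problem sizes and numerics

The test suite and the acceptance script run at: 200-gene catalogs for
annotation geometry; 1e4 reads × 100 loci for oracle-exact counting;
1e5 reads × 10 fragments for abundance recovery (3σ multinomial bounds,
Pearson > 0.99); 200-feature spiked and 20 × 2000-feature null designs
for the moderated t (oracle agreement at 1e-8; raw-p calibration within
99% binomial bounds of 0.05). These sizes keep the whole suite under a
minute while leaving the statistical checks well-powered. Numerical
choices: trigamma inverse by Newton from x₀ = 0.5 + 1/y (relative
tolerance 1e-10); TPM conservation asserted at 1e-6 relative; BH via the
standard step-up implementation; correlation p by the exact t/beta
transform. Null-calibration data draw per-feature variances from the
model's own scaled inverse-chi-square prior, which is the regime in
which moderated-t p-values are exactly calibrated.
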