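# Methods

This note documents the models behind each analysis, the synthetic
study conditions, numerical choices, and what the package's passing
tests do and do not establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to and from
the 1-based conventions of SAM and GFF3 happens only at I/O boundaries.
Alignments are consumed either as a minimal SAM dialect (single-`M`
CIGAR run, sequence carried so motif counting can read it) or as a
6-column TSV; the simulator emits reads pre-aligned — the true placement
is the alignment — because mapping is outside this package's scope and
exact placements make every coverage oracle exact.

## Read trimming

`trim_read` first removes a fixed `trim3` = 15 nt from the 3′ end
(primer removal), then removes further 3′ bases while the terminal base
quality is below `qmin` = 25.  Quality trimming is applied as 3′
trimming rather than whole-read discard (a discard mode exists behind a
flag): the trimmed data are meant to be retained, and low quality in
short-read tails is overwhelmingly a 3′ phenomenon.  Reads shorter than
`min_len` = 20 nt afterwards are discarded and counted; the floor keeps
degenerate reads out of the coverage tracks.  The fixed-cut-first order
is a declared convention and is configurable by composing the two steps
manually.

## Windows and normalization

"Sliding" windows are implemented as a non-overlapping tiling
(step = width): only under tiling do window values admit a meaningful
per-chromosome total, which both normalizations divide by.  The window
value is the **sum** of per-base depths (means are derivable by dividing
by window length).  Terminal windows may be short and are kept.

- Per-chromosome normalization divides each window by the sample's
  total over that chromosome's windows, so values sum to 1 per sample
  per covered chromosome (enforced to 1e-9 in tests) and are invariant
  to uniform rescaling of a sample's coverage.
- Genome-wide normalization divides by the sample's total over all
  chromosomes, MT included.  Including MT in the denominator means a
  sample with strongly amplified MT has a slightly deflated MT
  fraction: a planted 10× copy number returns a summary ratio of ~9.4,
  not 10.  This is a property of the fraction, not an error.

Normalization uses pseudocount 0 by default; ratio computations in the
screen add their own pseudocount instead, so the normalized values stay
faithful to the plain fraction.

## Enrichment screen

On per-chromosome-normalized windows of exactly three samples, and for
every choice of focal sample, two criteria are evaluated at
`cutoff` = 1.5: *simultaneous* (focal/other ≥ cutoff against each other
sample) and *vs average* (focal / mean of the other two ≥ cutoff);
depletion is the reciprocal condition, making the screen symmetric
under sample swap.  The default `criterion="either"` takes the union
and records which rule fired, so simultaneous-only results remain
recoverable.  Ratios receive a pseudocount of half the smallest
positive normalized value in the table — large enough to keep folds
finite on empty windows, small enough not to reorder occupied ones;
it is configurable and logged.

Adjacent flagged windows with the same focal sample and direction merge
into regions (gap 0).  This merging rule is declared, not derived from
any reference dataset: region counts from real experiments depend on
the merging convention and are not comparable across conventions.

Note one deliberate consequence of the "either" criterion: where one
sample is planted 2× enriched, the *other two* samples sit at ~1/1.5
of the average at the same windows and can be called depleted.  The
truth-based scoring therefore evaluates false calls only on windows
that overlap no planted interval in any sample.

## Telomere and mitochondrial quantification

Telomeric content is counted in read sequences — not the reference,
which would be sample-invariant — grouped by mapped chromosome.  The
operational motif is the 12-mer `TTAGGGTTAGGG` (the hexamer is
available by configuration); counting is non-overlapping by default,
both strands, since reads come from either strand of the array.
Per-million-reads values accompany raw counts for cross-sample
comparability.  The across-sample comparison is a one-way ANOVA using
per-chromosome per-million counts as replicates; chromosomes without
telomeric biology (MT, unmapped) are excluded from the replicate set by
default because an all-zero replicate row only inflates within-group
variance.

Mitochondrial enrichment tiles MT into 500-nt windows normalized
genome-wide; the per-sample summary is the sum of those windows (equal
to MT coverage over total coverage), and ANOVA across samples runs on
the window values.

## Proteomics

Missing LFQ values are an explicit absent marker (NaN), never zero, so
presence/absence set algebra is well-defined.  The differential test
log2-transforms intensities, requires ≥ 2 present values per group per
protein, and uses the Welch *t* statistic (replicate variances are not
assumed equal).  The null distribution comes from group-label
permutations: all distinct splits up to group swap when there are at
most 1,000 (ten for 3v3), otherwise `n_perm` seeded random splits.  The
observed labeling is excluded from the null by default — including it
would add `#obs ≥ t` to the numerator at every threshold and put a hard
floor of 1/n_splits on every q-value.  Permutation rows that leave a
group with fewer than two present values carry no null information and
are dropped from the pool.  The FDR numerator summarizes permutations
by the mean (median selectable); q-values are clipped to [0, 1] and
made monotone non-increasing in |t| by taking, for each protein, the
minimum FDR over all thresholds at or below its own |t|.  No s0
variance-stabilization offset is applied by default (it is a
parameter).  Significance additionally requires a linear fold change of
at least 2 in either direction; an interpretation of the cutoff on the
log2 scale is selectable.

Row z-scores for clustering use the sample standard deviation over
present values (population selectable); constant rows are flagged and
placed last; missing z-scores enter the Euclidean distance as 0 (the
row mean).  Linkage is average (UPGMA), verified in tests against a
brute-force agglomeration oracle.

## Statistical tests

ANOVA, Mann-Whitney and Spearman are written out explicitly so the
package's p-values are fully specified here; scipy supplies only the
F/normal/t tail functions, and scipy.stats serves as an independent
cross-check in the test suite.  Mann-Whitney enumerates all
`C(n+m, n)` splits of the pooled observations whenever that count is at
most 20,000 (which covers n = m = 8 and handles ties exactly), else it
uses the normal approximation with tie correction.  Spearman enumerates
all n! orderings for n ≤ 7, else the t approximation on mid-ranks.
Degenerate inputs (all values tied; constant vectors) are flagged on
the result rather than raised.

## Synthetic study conditions

The generator's defaults define the conditions every headline property
is measured under; they were fixed once, on the following grounds:

- **Genome**: three equal 100 kb autosomes and a 2 kb circular MT
  chromosome, GC 0.41 (human-like).  Equal autosome lengths make
  per-million telomere counts comparable across chromosomes, so the
  ANOVA's within-group variance reflects sampling noise rather than
  layout.  Each autosome carries 600 nt of perfect tandem TTAGGG at the
  5′ end and its reverse complement at the 3′ end (recorded in the
  truth set); perfect repeats give motif counting an exact analytic
  expectation.  MT circularity is recorded but reads do not wrap the
  origin — window math on a linear MT is identical.
- **Reads**: length 100, background depth 10×, placed uniformly with
  per-start sampling intensity multiplied inside planted intervals.
  Read counts are set deterministically from the target depth (total
  emitted bases are exact), so realized mean depth matches the target
  to within the edge effect (L − ℓ + 1)/L — under 0.2% on a 100 kb
  chromosome.  20% of reads get a 3′ quality ramp decaying below Q25.
- **Planted copy-number signal**: per sample, one ×2.0 interval of five
  5,000-nt windows and one ×0.5 interval of ten windows on that
  sample's own chromosome.  The two intervals cancel in expectation
  (+25 kb vs −25 kb of coverage), leaving the per-chromosome
  normalization denominator neutral, so planted windows sit at folds
  2.0 and 0.5 exactly rather than being diluted by their own
  chromosome total.
- **MT copy number**: 10× in the trap-like sample, 1× elsewhere,
  mirroring strong mitochondrial DNA enrichment in trap material.
- **Telomeric read rate**: 2,000 / 2,000 / 6,000 motif-bearing reads
  per million (a 3× contrast).  The absolute level is set so the
  planted contrast stands clearly above the background motif
  occurrences contributed by ordinary reads overlapping the 600-nt
  arrays (~1.4% of a chromosome's reads).
- **LFQ**: 1,000 proteins, log-normal baseline (median 1e7, σ = 1.25
  decades — a span above five orders of magnitude), 50 differential
  proteins at a true 4-fold ratio (half up, half down), multiplicative
  replicate noise at CV 0.15, and missingness only through a
  low-abundance mechanism: probability `missing_rate` × a logistic ramp
  centred on the 20th abundance percentile, ceiling 0.2.

## Calibration experiments

The permutation-FDR calibration (null false-discovery proportion at
nominal 0.05; sensitivity on planted 4-fold effects at CV 0.15) is run
on complete tables (no missingness): it isolates the statistical
behaviour of the test itself.  Missingness is exercised separately.
Under the full default conditions *with* missingness, sensitivity drops
to ~0.89: proteins whose shifted-down group falls below the missingness
ramp lose replicates and fail the min-valid filter.  That is a real
limitation of drop-based missing-value handling — such one-group-absent
proteins are exactly the ones a presence/absence analysis (the
replicate-intersection step) is for — and imputation is left as a
documented extension point rather than silently bolted on.

Problem sizes throughout (100 kb chromosomes, depth 10, 500–1,000
proteins, 20–50 replicate simulations) are chosen so the whole suite
and the acceptance script each run in about a minute on one CPU while
keeping Monte-Carlo noise well inside the asserted tolerances.

## What passing tests do not show

The generator plants clean rectangular copy-number intervals, uniform
coverage, perfect telomeric repeats and log-normal LFQ noise.  Real
trap sequencing has GC and mappability bias, duplicated and soft-clipped
reads, variant telomeric repeats, NUMTs that blur the MT/nuclear
boundary, and LFQ intensities with peptide-level structure none of
which is modelled.  Passing the planted-recovery properties shows the
implementation computes its declared quantities correctly, not that the
1.5-fold screen has any particular sensitivity on real genomes.  Known
non-goals: sequencing-error models, paired ends, PCR duplicates,
BAM/CRAM, telomere length estimation, heteroplasmy, peptide-to-protein
inference, network/GO analysis, and figure-for-figure plot
reproduction.
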