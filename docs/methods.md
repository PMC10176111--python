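# Methods

## Coordinates and annotations

All intervals are 0-based half-open (BED convention).  RepeatMasker `.out`,
GTF and GFF3 records (1-based inclusive) are converted on read; a single
internal convention prevents off-by-one drift between dialects.  Repeat
class strings split at the first `/` into order and family
(`LTR/Gypsy` → order LTR, family Gypsy; `Simple_repeat` → both).  The order
vocabulary is closed (LTR, LINE, DNA, Simple_repeat, Satellite, RC, Other)
so composition tables are always total; unrecognized orders fall into
`Other`.

piRNA precursors are assigned to at most one cluster: the cluster covering
the largest fraction of the precursor, provided that fraction is at least
0.5 of the precursor length, with ties broken to the lexicographically
smallest cluster id.  Threshold and tie-break are package choices made for
determinism; both are exposed as parameters.

Genome-abundance expectations (the null for composition tests) default to
element-count weighting — each annotation record counts once — with
base-pair weighting available by flag, since either reading of "genome
abundance" is defensible and the two differ when repeat classes have very
different length distributions.

## Counting

Reads are streamed with pysam; reference spans come from the CIGAR
(M/D/N/=/X consume reference).  Records that are unmapped, secondary,
supplementary, or below the mapping-quality threshold are excluded;
`min_mapq = 1` implements the "uniquely aligned (mapQ > 0)" criterion as a
strict inequality.  Paired mates sharing a read name collapse to one
fragment, which increments a feature at most once.  Two overlap modes are
provided: `every_overlap` (default; a fragment increments every feature it
touches, the behaviour of probe-based quantitation over overlapping
annotations) and `largest_overlap` (disjoint counting; ties to the
lexicographically smallest feature id).  Counting is unstranded by default
because library strandedness is protocol-dependent; a `stranded` flag
restricts to matching strands.  Reads on chromosomes absent from the
annotation are skipped and tallied rather than failing, so one foreign
contig does not abort a run.  The library size recorded per sample is the
number of retained fragments, not the column sum.

## Differential transcription

The NB model is parameterized mean/dispersion throughout:
`Var = μ + αμ²`.

**Size factors** are median-of-ratios: for each sample, the median over
all-positive features of the ratio to the feature's geometric mean, rescaled
so factors have geometric mean 1.  With no all-positive feature the method
falls back to total-count scaling with a warning.  Median-of-ratios assumes
a majority-unchanged catalogue; see the generator section for how the
synthetic data honours that assumption.

**Dispersion** is per-feature method of moments on normalized counts:
pooled within-group residual variance (N − G denominator) and grand mean
give `α̂ = (s² − μ̄)/μ̄²`, clipped to `[1e-8, 10]`.  By default per-feature
estimates are additionally floored at the cross-feature median.  At typical
replicate numbers (n = 4–7 per group) the raw per-feature estimate is noisy,
and features whose dispersion happens to be underestimated get
anticonservative Wald tests; in null simulations at n = 5+5, μ = 50,
α = 0.1 the empirical type-I error at nominal 0.05 is ≈ 0.088 with raw
per-feature estimates and ≈ 0.045 with the median floor.  The floor
introduces no mean–dispersion trend, and for data near the Poisson limit
the median itself sits at the lower clip, so the floor is inert there.  It
can be switched off (`median_floor=False`).

**Wald test.**  Group means are means of size-factor-normalized counts (the
NB mean MLE at fixed dispersion).  With pseudocount c = 0.5,

    log2FC = log2((μ̂_t + c) / (μ̂_c + c))
    se²    = (1/ln 2)² · [ (1/n_t)(1/(μ̂_t + c) + α) + (1/n_c)(1/(μ̂_c + c) + α) ]

(the delta method on the NB Fisher information), `z = log2FC/se`, two-sided
normal p.  No fold-change shrinkage is applied; estimates are raw
pseudocount-stabilized ratios.  Features with zero counts in both groups
are flagged untested (log2FC 0, p 1) and excluded from the number of tests
in the Benjamini–Hochberg step-up.  Selection of "up-regulated" features
uses strict inequalities (log₂FC > 2, adjusted p < 0.05 by default; a
raw-p switch is provided because either convention is seen in practice).

## Double-control consistency filter

A feature is removed when it is significant (chosen p < α, default adjusted
p < 0.05, no fold-change floor) in *either* the wild-type batch-vs-batch
contrast or the control-genotype-vs-wild-type contrast; the main table is
restricted to the survivors and a report records both criteria per removed
feature.  The union rule and the absence of a fold-change floor are the
stringent reading of "significantly changed in either control"; an optional
`lfc_floor` relaxes it.  The filter is idempotent by construction.

## TE-level analyses

*Composition*: goodness-of-fit chi-square of observed class counts against
genome-abundance expectations, `χ² = Σ (O_k − n e_k)²/(n e_k)`, df = K − 1,
with a two-sample contingency mode for mutant-vs-mutant comparisons.  A
warning is emitted when any expected cell drops below 5.

*Mutant partition*: each feature of the base up-set gets its exact
membership signature over the three knockouts; all 2³ classes are reported,
including `none` and the triple overlap, rather than folding them into the
six single/pairwise classes.

*Genomic context*: a TE overlapping (≥ 1 bp) any gene whose wild-type mean
normalized count is ≥ 10 is `expressed_gene`; overlapping only unexpressed
genes, `unexpressed_gene` (subdivided by whether a host gene is in the
mutant gene up-set); otherwise `intergenic`.  On ambiguity the priority is
expressed > unexpressed > intergenic.  The threshold and priority rule are
package choices, both configurable.

*Density tracks*: features are binned by interval midpoint into half-open
windows (default 100 kb); a midpoint exactly on a boundary belongs to the
right-hand window.  Midpoint binning guarantees each feature is counted in
exactly one window.

## piRNA cluster scoring

Per precursor, the condition mean of size-factor-normalized counts is
computed first (replicate mean); cluster summaries then average over the
cluster's assigned precursors with a t-based 95% CI (degenerate at one
precursor).  Replicate-mean-first is the documented order; it differs from
precursor-mean-first only when size factors are unequal.  Folds over the
control condition are reported both raw and rounded half-away-from-zero to
one decimal — the convention that exactly reproduces all sixteen published
fold values from the published per-cluster means.  The uni- vs dual-strand
contrast is tabulated descriptively (per-cluster and per-mode mean folds);
no hypothesis test is attached.

## ChIP/input enrichment

Replicate counts are averaged before the ratio, matching an
average-enrichment-then-ratio design.  Per feature,

    ratio = ((chip + 0.5)/chip_lib) / ((input + 0.5)/input_lib)

with library-size normalization inside the ratio and a pseudocount guarding
zero coverage.  Class profiles report the mean ratio and a t-based 95% CI
across the features of each class (exons, simple repeats, LINE, LTR, and
n = 10,000 random 80-bp regions by default).  Random regions are sampled
with chromosome probability proportional to length and uniform starts,
deterministic under the seed; chromosomes shorter than the region width are
excluded with a warning.  Counts are not length-normalized before the
ratio: the ratio form and the equal-width background make per-feature
length factors cancel for the comparisons of interest.

## Synthetic data: what it emulates, and what it does not

The generator builds a four-chromosome genome (2.8 Mb total) with a
pericentromeric block (30% of each chromosome) holding 75% of the
retrotransposons, a repeat catalogue of 1,560 elements whose simple-repeat
share (61.5% by element count) matches the genome-abundance share reported
for the real repeat table, 80 genes of known expression state, and four
piRNA clusters (two dual-strand, two uni-strand, 50 precursors each) within
a piRNAdb-like catalogue of 1,200 additional out-of-cluster precursors.
Counts are NB draws, `count ~ NB(s_j · μ_i · 2^lfc, α = 0.1)`, with
lognormal per-sample depth factors (σ = 0.1) and five replicates per
genotype (four for the control genotype), the wild type split into two
batches.

Planted effects mirror the emulated study's structure: TE activation in 8%
of the catalogue for the replacement mutant (log₂FC = 3, sampled with
LTR/LINE bias), 5% / 2.5% / 1.5% for the Set2/NSD/ash1 knockouts with 90%
of each knockout's set nested inside the replacement-mutant set; 50
batch-inconsistent TEs (log₂FC = 2 between wild-type runs); gene activation
(log₂FC = 6) in 30% of unexpressed genes; and cluster folds of 8.0/1.5
(dual/uni) in the replacement mutant, graded down across knockouts.  The
response fractions are deliberately small: median-of-ratios normalization
assumes most features unchanged, which holds in the real data (thousands of
significant features against a catalogue of tens of thousands); planting
much larger fractions at desk scale would bias size factors and compress
every recovered fold — the residual ≈ 10% compression visible in fold
recovery is the honest remnant of that effect at 8%.

Alignments are single-end fixed-length (75 bp) reads placed uniformly
within features, mapping quality 255 (or 0 for a configurable multi-mapper
fraction, default 0).  With disjoint features this makes the counting
round trip exact, which is used as an oracle.  ChIP counts are Poisson
with class multipliers; input counts are noise-free length-proportional
rates with expected-total library sizes, so the per-feature ratio is
unbiased at 1 under uniform signal — without that choice the mean of
count ratios at 80-bp coverage carries a visible Jensen bias that no real
conclusion should depend on.

What the generator does *not* emulate: nucleotide sequence (no aligner
behaviour, no mappability structure), multi-mapper ambiguity between
homologous repeat copies, paired-end fragment-length distributions (the
paired-end code path is tested with handcrafted SAM fixtures instead),
batch effects beyond a planted mean shift, and the empirical
mean–dispersion trend of real RNA-seq.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to alignment artefacts of real repeat data.

## Problem sizes and determinism

Default simulated studies (1,560 repeats, 80 genes, 1,400 precursors, 36
samples) run end to end in under a second; the test suite, including the
10,000-feature null calibration and a 20-replicate fold-recovery study,
completes in well under a minute.  Every emitter and every analysis stage
is deterministic given seeds; identical configs and inputs produce
byte-identical outputs, and output tables carry the package version and a
hash of the effective parameters in a comment header.

## Known limitations

- The Wald test with plug-in dispersion is approximate; its null behaviour
  is calibrated (type-I error ≈ 0.04–0.05 at nominal 0.05 under the
  simulated conditions) but it is not an exact test, and no fold-change
  shrinkage is offered, so extreme fold estimates at low counts rely on the
  pseudocount alone.
- Size factors are computed once on the full matrix; experiments where most
  of a catalogue responds violate the median-of-ratios assumption and will
  compress fold estimates (a warning sign, not a silent failure: the filter
  and control contrasts surface it).
- The overlap index holds all annotations in memory; the pipeline targets
  annotation catalogues up to the low millions of records, not
  whole-genome base-resolution structures.
- `every_overlap` counting double-counts fragments spanning overlapping
  annotations by design; use `largest_overlap` when a partition is needed.
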