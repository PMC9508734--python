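# Methods

This note documents the models, rules and numerical choices behind
`telotype`, and what the synthetic-data generators do and do not
emulate.

## Telomeric read rule and telomere content

A read is telomeric when it contains at least `min_repeats` (default 4)
t-type repeats. Occurrences of TTAGGG and CCCTAA are counted
non-overlappingly, scanning left to right, and **summed**: a sequencing
read is single-stranded, so either orientation evidences telomeric
origin. The hexamer cannot overlap itself, which makes the
non-overlapping scan deterministic and trivially oracle-checkable with
a regular expression.

Content is `telomeric / total × scale` with `scale = 1e6` (reads per
million) for both DNA and RNA; the per-million convention is the one
the TERRA quantification defines, and is reused for WGS content and
tumor-only mode for consistency. Reads are counted regardless of
mapping status or duplicate flags (a raw-read-level definition); for
BAM input, secondary and supplementary records are dropped by default
so reads are not double counted. The sample-level statistic is the
tumor/normal content ratio; when no matched normal exists the
normalized tumor content is used directly — both rank a cohort
identically when normals share one telomere fraction, and the ratio is
undefined (an error pointing at tumor-only mode) for a zero-content
normal.

## TVR counting and singletons

Variant counting is anchored to the telomeric repeat frame: every
TTAGGG occurrence seeds a run that extends in 6-mer steps through
contiguous NNNGGG-compatible hexamers in both directions, and each
hexamer in a run is tallied once under its exact sequence (a `visited`
set prevents double counting where runs overlap). Isolated GGG
triplets outside any run are ignored — variants are only meaningful
*within* telomeric sequence. Reads are canonicalized to the G-rich
strand first (reverse complemented when CCCTAA occurrences outnumber
TTAGGG; ties keep the input), and only reads passing the telomeric
rule are scanned.

A singleton is (TTAGGG)₃–NNNGGG–(TTAGGG)₃ with the variant ≠ TTAGGG.
The scan is overlap-tolerant: flanking repeats may be shared by
adjacent singletons, because the bracketed pattern does not forbid
sharing and an overlap-tolerant definition has an unambiguous
regular-expression oracle (the test suite checks exact agreement on
1,000 random sequences).

Because singleton counts grow with telomere content, the subgroup
statistic is `log2((tumor rate) / (normal rate) / TC ratio)` with
rates per total reads. When either count is zero, a pseudocount of 0.5
is added to both and the value flagged — this keeps sparse simulated
cohorts finite without silently biasing well-covered samples.

## Insertion caller

Anchors: a read pair contributes one anchor when exactly one mate is
telomeric and the other maps outside the user-supplied exclusion
regions (terminal telomeric tracts and centromeres; these intervals
are necessarily an input — there is no universal definition). The
anchor is the 5′ mapping coordinate of the non-telomeric mate, a
deterministic and order-independent choice.

Windows are a fixed (non-sliding) tiling at 0-based multiples of
1,000 bp, half-open; a candidate needs ≥ 3 tumor anchors and 0 normal
anchors. Within candidates, soft clips qualify when ≥ 15 bp with ≥ 2
t-type repeats; same-direction clips are clustered greedily around the
modal start position (ties toward the smaller coordinate) with ± 1 bp
tolerance, and clusters of ≥ 2 reads become breakpoints. Breakpoint
coordinates: for right clips, the reference position of the first
clipped base (= the aligned end); for left clips, the base immediately
left of the first aligned base — the mirrored convention.

The manual review step of the original procedure is replaced by an
automated context filter: a breakpoint is rejected when the reference
± 100 bp around it contains ≥ 2 t-type repeats or a single-nucleotide
run ≥ 20 bp, the two artifact classes such review removes.

Opposite-direction breakpoints within 5,000 bp merge into one
two-sided insertion (nearest-first, each breakpoint used once); all
others are one-sided. The 5 kb pairing distance is a design choice: it
must bridge an insertion locus without joining distant events, and no
published value exists. Tumor-only calling works (empty normal stream)
but the CLI flags it, since matched normals suppress false positives.

## TERRA

A read counts toward a variant v ∈ {TTAGGG, TGAGGG, TCAGGG, TTGGGG}
when it carries ≥ 4 occurrences of v or its reverse complement; a read
may count toward several variants because per-variant counts are
defined independently. The threshold 4 reuses the WGS telomeric-read
rule. Counting operates on raw sequences, so FASTQ is accepted
without alignment. Note the published group means (0.004/0.011/0.002)
may sit on a different normalization scale than reads per million;
the simulator therefore treats them as per-read fractions, which
reproduces their ordering and relative separation.

## Assay quantification

*Mean TRF* integrates over the discrete lane samples exactly as given
(no interpolation or ladder smoothing — image processing is upstream).
It is scale-equivariant in length and invariant to OD rescaling. An
OD-weighted standard deviation (`trf_heterogeneity`) is exposed as an
uncalibrated extension, since ALT telomeres are visibly more
heterogeneous.

*CCA*: th₁ is `signal/reference ≥ 0.05`; th₂ is `≥ 0.20` **and**
`with-polymerase AUC ≥ 4 × polymerase-free AUC`. Signal units are
whatever the dot-blot quantification produced; only the ratio to the
ALT-positive reference (CHLA-90) enters.

*TERT threshold*: a two-component 1-D Gaussian mixture is fitted by EM
(scikit-learn backend), initialized at the 25th/75th percentile means
with pooled SD and equal weights, with 10 seeded-jitter restarts
keeping the best log-likelihood. The threshold is the smallest point
of a 0.01 grid over the observed range whose posterior membership in
the higher-mean component reaches 95 %. The grid is restricted to
values above the low component's mean: with unequal variances the wide
component's posterior can also exceed 95 % in the far *left* tail,
which is not the intended "entry into the high-expression mode" and
would violate the between-means invariant. Component collapse (SD
below 1e-4 of the data range, or weight below 1e-3) and an unreachable
posterior level are errors, not silent answers. Expression
classification itself is a strict inequality against the threshold
(default 7.58, the cohort-derived constant).

## Classification and resolution

The strict rule is exactly the three-subgroup definition: TEL⁺ needs a
telomerase marker and both ALT assays negative; ALT⁺ needs concordant
APB and CCA positivity without telomerase markers; TMM⁻ needs all five
negative. A missing APB or CCA forces `ambiguous` — one cannot assert
concordance or absence against an unmeasured assay. Missing telomerase
marker flags count as absent evidence (cohorts rarely have all three
measured for every sample), but at least one marker from each family
must be non-null or the input is rejected.

Resolution formalizes what published narratives decide case by case,
as an explicit rule order: (1) concordant APB+CCA → ALT⁺; (2) a
genomic telomerase lesion (MNA or TERT RA) → TEL⁺; (3) otherwise count
auxiliary ALT markers over the non-null subset — ATRX mutation,
TC ≥ 1.22, TRF ≥ 9.01 kb, TERRA ≥ the ALT-group mean (0.011),
singleton log₂ ratio ≤ the ALT-group mean (no published value; must
be supplied or computed from cohort data), any insertion — with ≥ 2
hits calling ALT⁺; (4) failing that, high TERT expression or
telomerase activity → TEL⁺; (5) otherwise the sample stays ambiguous
with an explanatory evidence trail. Missing markers are excluded from
the score, never imputed. This rule reproduces all seven reference
ambiguous-case resolutions (2 TEL⁺, 5 ALT⁺). "High telomerase
activity" remains a user-supplied flag — the assay has no published
numeric cutoff.

ROC curves enumerate every observed threshold under the rule
`score ≥ t → positive`; the AUC is the trapezoid over (FPR, TPR),
which equals the pairwise concordance statistic with half credit for
ties (oracle-tested). The proposed threshold maximizes Youden's
J = sensitivity + specificity − 1, with ties broken toward higher
specificity and then the lower threshold — a deterministic rule where
"based on the ROC coordinates" is otherwise ambiguous. Logistic
combination of two predictors uses maximum likelihood (statsmodels); a
constant covariate is dropped so the fit degrades to the
single-covariate model, true collinearity is an error, and perfect
separation is flagged with probabilities capped away from 0/1. Group
comparisons use Kruskal–Wallis followed by Dunn's test (tie-corrected,
Bonferroni-adjusted — the adjustment choice is ours; identical-data
degenerate input returns H = 0, p = 1 rather than an error).

## Synthetic data: what it emulates, and what it does not

The WGS generator plants a per-read telomeric fraction (binomial at
read level, so exact binomial intervals apply), telomeric reads built
from hexamers drawn from a TVR mix with an explicit singleton-planting
rate, and insertion sites emitting the stated numbers of discordant
pairs (anchors inside the site's window) and right-clipped reads at
the exact breakpoint. The reference is ~100 kb over two contigs with
terminal telomeric tracts and interiors scrubbed of t-type repeats,
so exclusion-region logic is exercised and the context filter cannot
reject a cleanly planted site. Deliberately not modeled: sequencing
errors, GC/coverage bias, indel-containing alignments, subtelomeric
variability and unstable karyotypes. Passing recovery tests therefore
demonstrates the caller's logic, not its error tolerance on real data.

Cohort tables draw telomere content and TERRA from lognormals
(non-negative, right-skewed) and TRF from a normal, around the
observed subgroup means (TC 0.87/6.39/0.96; TRF 8.39/10.66/6.36 kb;
TERRA 0.004/0.011/0.002) with subgroup sizes 17/13/31. Dispersions are
fixed once: TC σ = 0.6 and TRF sd = 1.6 kb give the near-complete
separation the TC/TRF ROC analyses show (AUC ≥ 0.9), while TERRA
σ = 1.2 gives the substantial overlap consistent with its weaker
reported discriminability (AUC ≈ 0.83). Assay flags follow the truth
label, with a 10 % discordance rate (one flipped APB/CCA flag —
false-negative in ALT⁺, false-positive otherwise) mirroring the ~10 %
ambiguity rate of real cohorts; ATRX mutations occur in ~46 % of ALT⁺
samples and insertion prevalence is 77 %/32 %/6 % by subgroup. All
assays are present for every simulated sample, which real cohorts do
not achieve; missing-data paths are tested separately.

Densitometry lanes use a log-spaced ladder (2–20 kb) with band signal
defined as Gaussian density × local ladder spacing, so the discrete
OD-weighted mean is unbiased on the non-uniform grid; 1 % seeded
multiplicative noise is added.

All generators are pure functions of their seeded configuration; the
truth records they return are the only ground truth the tests use.

## Problem sizes and tolerances

Default verification sizes: 200,000 reads for content recovery (the
planted fraction 1e-4 puts ~20 telomeric reads in the library, checked
against the exact binomial 99 % interval), 8,000-read tumor/normal
pairs with three planted insertion sites for caller recovery (± 1 bp),
50,000 RNA reads for TERRA, n = 2,000 for the mixture threshold
(± 0.15 against the closed-form posterior crossing of the planted
mixture), n = 5,000 for logistic coefficient recovery (within 3
standard errors), and 20 cohort seeds for the TC-AUC stability check
(> 0.9 in ≥ 18/20). These sizes keep the full suite and the
acceptance script in the seconds-to-a-minute range on one CPU while
leaving the statistical checks well-powered.

## Known limitations

* The caller assumes gapless alignments when inferring clip positions
  from sequence length; pysam-provided `reference_end` is used when
  reading real BAMs, so indels only affect synthetic in-memory reads.
* Singleton and TVR counting do not reimplement read-length-scaled
  repeat thresholds or chromosome-arm attribution found in dedicated
  telomere tools; absolute values can sit on a different scale than
  numbers produced by those tools, while ratios and orderings agree.
* The per-variant "content" of TVR types and the tumor-only content
  unit follow the per-million convention throughout; published
  absolute values on unspecified scales are not asserted.
* C-circle signal background handling is upstream; only
  ratio-to-reference logic is implemented.
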