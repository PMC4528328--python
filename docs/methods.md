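# Methods

## Signal model and feature extraction

A gene's feature vector is built from coverage tracks as follows: the
gene-body interval is the full genomic span (introns included) of the
longest transcript, ties broken by lexicographically smallest transcript id;
per-base coverage is summed over that interval for each track; each mark sum
is divided by the matched input-library sum when an input is supplied, and
by transcript length otherwise; replicate signals are averaged on the
normalized scale and then ranked once — averaging before ranking keeps ranks
well defined when replicates disagree. RNA coverage is integrated by the
same pipeline and normalized to length; an external abundance column (e.g.
FPKM) can substitute for it.

Quantile rank is average-rank/n, giving values in (0, 1]. Any strictly
monotone rescaling of the underlying signal leaves the ranks unchanged (a
tested property), which is what makes a classifier trained on ranks
portable across datasets and platforms. The rank scale is recorded in every
saved model (`feature_scale_tag`) and checked at prediction time, since
mixing rank conventions between training and application would silently
shift the decision boundary.

Genes with an input track but zero input signal are dropped before ranking;
genes whose *mark* signal is zero are kept (they take the lowest ranks).
Autosome restriction uses a configurable regex (default accepts `chr1`…/
bare numerals and excludes X, Y, M). Chromosome names are matched exactly,
with a preflight overlap report instead of silent aliasing.

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
wiggle (1-based) are converted on read.

## ADTree classifier

Two-class boosting over the two mark quantile ranks. Example weights start
at 1; the root prediction and every branch prediction are smoothed log-odds
`½·ln((W₊+1)/(W₋+1))`, which keeps predictions finite on pure partitions.
Each round evaluates every existing precondition against every threshold
(midpoints of consecutive distinct feature values within the precondition)
and adds the condition minimizing the weighted Z criterion; both branches of
the new node become preconditions for later rounds. The smoothed predictions
still lie between 0 and the unsmoothed optimum of the per-branch exponential
loss, so the total weight — the training loss — is non-increasing every
round; this is asserted in tests. A round whose best split does not improve
on the no-split bound stops training early with a logged notice.

Classes are treated with equal misclassification cost (a neutral,
cost-insensitive classifier). The default of 10 boosting rounds is the
common ADTree default and is configurable. A score of exactly 0 is called
BAE: MAE requires strictly positive evidence. Models serialize to versioned
JSON; scores after a save/load round trip are bit-identical (floats are
serialized via their shortest exact decimal representation).

The estimator follows scikit-learn conventions (`fit`, `decision_function`,
`predict`, `get_params`, trailing-underscore fitted attributes) and composes
with sklearn model selection.

## Filters and dataset QC

Filtering happens after classification: genes shorter than 2.5 kb (span of
the longest transcript — the span, not exonic length, is used, consistent
with the length definition in feature extraction) are unreliable for the
chromatin signature; genes with expression quantile rank < 0.5 are below
median expression. Keep is inclusive at exactly 0.5. The median is computed
over assessed genes, i.e. those surviving the input-signal drop. When a gene
trips both filters the short-gene label wins (precedence, not biology).

Dataset QC splits genes into four groups at the median normalized enrichment
of each mark and requires the two anticorrelated groups (low27/high36,
high27/low36) to hold at least 1.5× the genes of the other two. A failing
dataset is refused unless forced, since the classifier's decision region is
meaningless without dynamic range in both marks.

## Allelic-expression calling

SNP counts are summed per gene (per-SNP testing with gene-level combination
would require a SNP-correlation model; summation is the simplest consistent
aggregation). The imbalance test is an exact binomial against 0.5, two-sided
by doubling the smaller tail and capping at 1 — reproducible and
order-stable, unlike minimum-likelihood two-sided definitions which differ
in the third decimal. BH correction runs once across all genes with at least
`min_total` = 20 reads; shallower genes are indeterminate. Monoallelic
requires q < 0.05 *and* major-allele fraction ≥ bias/(bias+1) = 2/3.
Biallelic requires a positive binomial TOST: both one-sided tests against
the bounds (1/3, 2/3) — mirroring the 2:1 monoallelic bias — significant at
alpha. The caller is symmetric under maternal/paternal swap.

Multi-clone aggregation: MAE if monoallelic in any clone; else BAE if
biallelic in any clone; else indeterminate. Concordance between
chromatin-signature and allelic calls is a 2×2 Fisher exact test with the
sample odds ratio (TP·TN)/(FP·FN); a zero margin leaves the OR undefined
(inf/nan) while the p-value is still computed. The conditional-MLE OR would
differ slightly; the sample OR is reported because it is the convention for
such concordance tables.

## Conservation test

Ortholog tables are first restricted to strict one-to-one pairs (any gene
appearing in more than one pair removes all its pairs), then to pairs with a
determinate MAE/BAE call in both species — this defines the universe N
before any counting. The tail is the inclusive upper tail P(X ≥ observed) of
the hypergeometric, the standard enrichment convention, computed by
log-space summation of `logpmf` (scipy) with `logsumexp`; tails of order
1e-131 are far below double underflow so linear-space summation is not an
option. Expected overlap is reported as K·n/N (= p_a·p_b·N), unrounded and
rounded.

## Profile clustering

Gower distance on symmetric binary MAE/BAE profiles reduces to the mismatch
fraction over genes informative (non-missing) in both samples; missingness
is handled pairwise, not by global complete-case reduction, so every sample
pair uses all genes it can. "Informative" means a determinate final call:
filtered genes are missing. UPGMA uses size-weighted average linkage (the
recursive update equal to the unweighted mean over member pairs), merge
height d/2, and deterministic lexicographic tie-breaks (a cluster is
labelled by its smallest leaf name; the minimum-distance pair with the
smallest label pair merges first). Trees export as Newick with branch
lengths derived from merge heights, making leaf-to-leaf path lengths equal
to cophenetic distances.

The tissue-specificity analysis bins genes by their number of expressing
samples and reports, per (bin, sample), the MAE proportion among expressed
determinate genes, plus per-bin quartiles for box plotting.

## Accuracy correction

Each MAE prediction is independently correct with probability a (default
0.73, the MAE confirmation rate measured in the clonal benchmark); BAE
predictions are taken at face value. For a gene predicted MAE in k of n
samples the truly-MAE sample count is Binomial(k, a); only the count matters
(conditioning on which samples are MAE gives the same sums). Expected
per-bin counts sum over genes, conserve the total exactly and satisfy
Σ m·E(m) = a·Σ k; an expected count below 1 is reported as 0. A
generalized mode with a BAE-specificity parameter was deliberately not
defaulted, to keep the single-parameter model.

## Synthetic data generator

The generator emulates the population-level consequences of MAE, not
sequencing reads. Gene classes: MAE (default fraction 0.15, the upper bound
reported for mammalian autosomes), silent (0.30), the rest biallelically
expressed. Mark enrichment is lognormal with class means exp(μ)=5 (high) and
0.3 (low), σ=0.5; MAE genes carry *both* marks at 0.5 dosage — the explicit
population mixture of one silenced and one active allele — and RNA at 0.7
dosage; the input control is lognormal around 1. Per-gene Poisson
quantization (depth 64) adds counting noise. This reproduces the
four-quadrant geometry the classifier relies on and passes the dynamic-range
QC at defaults. Gene lengths are log-uniform on [2.5 kb, 50 kb] with 10%
short genes in [1, 2.5) kb so the length filter is exercised; a small chrX
cohort exercises the autosome restriction.

Allele counts: MAE genes express a clone-fixed allele at fraction 0.95
(maternal or paternal with equal probability), BAE genes at 0.5; 1–20 SNPs
per gene with Poisson per-SNP depths totalling ~100 reads per gene; silent
genes produce no counts. Profiles evolve on a Newick lineage tree (default
balanced six leaves) by per-branch state flips with probability 0.05 —
branch lengths are not used, since the flip probability is a per-division
property in this caricature. Ortholog tables plant an exact shared-MAE
overlap so the conservation worked example (7429/563/580/240) is
reconstructible.

What the generator does *not* model: fragment-length and GC biases, peak
shape, read mappability, isoform-specific SNPs, imprinting, or
allele-specific chromatin at loci other than the planted classes. Passing
tests therefore demonstrate the pipeline's correctness and calibration under
its own assumptions, not its accuracy on real chromatin data, where the
reported odds ratios are far smaller than on this clean planted signal.

One global seed fans out to fixed per-generator substreams, so each data
type regenerates independently and byte-identically.

## Problem sizes and numerical choices

Default analysis sizes were chosen to be comfortably informative at
interactive runtimes: 2000 genes for end-to-end runs and tree recovery,
1000 genes for caller calibration, 10,000 genes for correction recovery,
1000 random instances for the small-universe hypergeometric and UPGMA
cross-checks. The hypergeometric tail agrees with brute-force enumeration to
1e-12 on universes up to N=60. The inclusive upper tail of the conservation
worked example is 10^-130.9; tools differing in tail convention (exclusive
tails, mid-p) print values a few-fold larger, which is within two
significant figures of the log10 tail. Threshold candidates in ADTree
training are midpoints of consecutive distinct values; equal-Z candidates
resolve by fixed iteration order (precondition creation order, feature
order, ascending threshold), making training deterministic.

## Known limitations

- The equivalence-test bounds (1/3, 2/3) and the 20-read indeterminate
  threshold are conventions; both are configurable.
- The 2.5 kb filter uses the longest-transcript genomic span, not exonic
  length.
- BED12 input has no gene attribute; the name field (optionally
  `gene|transcript`) supplies ids.
- The correction's independence assumption across samples ignores shared
  clonal origin of errors.
- bigWig/BAM ingestion is out of scope; tracks must be bedGraph or wiggle
  text.
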