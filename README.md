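# magic-mae

Inference of mosaic monoallelic expression (MAE) from gene-body chromatin
signatures, with allelic-expression benchmarking, cross-species conservation
testing, MAE-profile clustering, and classifier-accuracy correction.

## The problem

A sizable fraction of mammalian autosomal genes — up to ~15% — are expressed
from predominantly one allele per cell, with the active allele chosen
stochastically and maintained through mitosis (mosaic monoallelic expression).
Detecting MAE directly requires allele-resolved RNA-Seq in clonal cell lines
with dense SNPs, which is impossible for most primary tissues. MAE genes,
however, carry a population-level chromatin hallmark: because one allele is
silenced and one transcribed, the gene body is *simultaneously* enriched for
the repressive mark H3K27me3 and the transcription-coupled mark H3K36me3.
This package infers MAE from that signature using only standard ChIP-Seq
coverage tracks, so MAE can be mapped in any cell type with available
chromatin data.

## The method

For each autosomal gene, coverage of each mark is summed over the span of
the longest transcript, normalized to the input (control) library — or to
transcript length when no input exists — averaged over replicates, and
converted to a **quantile rank** `q_i = rank_i / n` (average rank on ties).
Quantile ranks are invariant under monotone rescaling, so a classifier
trained on one dataset transfers to others measured on different scales.

The classifier is an **alternating decision tree** (ADTree) over
`(q_K27me3, q_K36me3)`. Scoring sums a root prediction and the prediction
values of every splitter node whose precondition path the gene satisfies;
`score > 0` calls MAE. Training adds one node per boosting round, choosing
the precondition/threshold pair that minimizes

```
Z = 2·(√(W₊(p∧c)·W₋(p∧c)) + √(W₊(p∧¬c)·W₋(p∧¬c))) + W(¬p)
```

with branch predictions `½·ln((W₊+1)/(W₋+1))` and multiplicative weight
updates `w ← w·exp(−y·r(x))`. After classification, genes shorter than
2.5 kb and genes below median expression are excluded (`not_assessed`), and
a dataset-level QC requires the two mark-anticorrelated gene groups to
outnumber the correlated groups by ≥ 50%.

Downstream analyses: exact binomial + Benjamini–Hochberg allelic-imbalance
calling (monoallelic at FDR < 0.05 with ≥ 2:1 bias; biallelic by binomial
TOST within (1/3, 2/3)); Fisher-exact concordance with the sample odds ratio
(TP·TN)/(FP·FN); hypergeometric upper-tail conservation testing over
one-to-one orthologs (log-space, exact at tails ~1e-131); Gower-distance /
UPGMA clustering of MAE profiles; and binomial accuracy correction of
multi-sample MAE counts at MAE prediction accuracy 0.73.

## Worked example

Everything is runnable end to end on synthetic data with planted MAE
structure (no downloads needed):

```bash
magic simulate --seed 7 --n-genes 2000 --outdir sim/
magic signal --annotation sim/annotation.gtf \
    --k27 sim/k27.bedgraph --k36 sim/k36.bedgraph \
    --input sim/input.bedgraph --rna sim/rna.bedgraph --out features.tsv
magic train --features features.tsv --labels sim/labels.tsv --out model.json
magic classify --features features.tsv --model model.json --out calls.tsv
magic allelic --snps sim/snp_counts.tsv --out allelic.tsv
magic benchmark --calls calls.tsv --allelic allelic.tsv --out concordance.tsv
```

which prints:

```
trained ADTree with 10 nodes -> model.json
MaGIC calls: 126 MAE, 772 BAE, 1102 filtered
QC counts (808, 807, 193, 192), passed=True
tp=119 fp=7 fn=23 tn=680 OR=503 fisher_p=2.54e-110
```

Reading: the dynamic-range QC passes (the two anticorrelated quadrants hold
1615 of 2000 genes); 126 genes are called MAE among the 898 that survive the
length and expression filters; benchmarking those calls against the
allelic-expression calls derived from the simulated SNP counts confirms 119
of 126 MAE calls (94%), an odds ratio of 503 — far above chance because this
clonal synthetic dataset has a clean planted signal.

The library mirrors the CLI: `build_feature_table`, `ADTreeClassifier`
(a scikit-learn estimator: `fit` / `decision_function` / `predict`),
`run_magic`, `call_allelic`, `conservation_test`, `cluster_profiles`,
`corrected_counts`.

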