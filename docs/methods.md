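# Methods

## The composite ubiquity score

The score operationalizes "ubiquitously expressed" as the conjunction of
three measurable properties of a gene across the samples of one expression
matrix: it is *broadly* high (breadth), *robustly* expressed (level), and
*stable* (variation). One criterion per class is chosen and the three
subscores are combined linearly under signed weights; because the composite
is min-max normalized, multiplying all weights by a positive constant leaves
the score unchanged — only weight ratios matter, and "weighted average"
versus "weighted sum" are the same statistic.

Assumptions worth making explicit:

* **One value per gene and sample.** Tissue-aggregated or per-drug-summary
  inputs are treated as ordinary matrices whose "samples" are tissues or
  drug × concentration combinations. No within-matrix aggregation is
  performed.
* **Zeros mean "not detected."** The per-sample thresholds for the breadth
  criterion are computed over *all* values of a sample, zeros included —
  the threshold is a property of the sample, and removing zeros would tie
  it to the sample's detection rate. The level and variation statistics,
  by contrast, use only the gene's strictly positive values, keeping them
  independent of detection breadth.
* **Comparisons.** Percentile/median thresholds use "meets or exceeds"
  (≥); detectability uses strictly greater than zero. All quantiles are
  linear-interpolation quantiles between order statistics (numpy default,
  R type 7).

### Parameters

| parameter | default | meaning |
|---|---|---|
| breadth criterion | `above_p95` | per-sample 95th-percentile threshold; `above_median`, `above_zero` available |
| level criterion | `median` | of positive values; `mean` available |
| variation criterion | `qcv` | (Q3−Q1)/median of positive values; `iqr`, `cv`, `sd` available |
| weights (w_b, w_l, w_v) | +0.50, +0.25, −0.25 | breadth and level reward, variation penalizes |
| top fraction | 0.05 | ubiquity cutoff: exactly ⌊0.05·N⌋ genes |
| bucket fraction | 0.025 | sliding-enrichment bucket size ⌈0.025·N⌉ |
| alpha | 0.05 | drug-significance filter (p ≤ α, inclusive) and FDR level |

### Numerical conventions and degenerate inputs

* Min-max over an all-equal vector maps every entry to 0.5 rather than
  NaN, so a degenerate subscore contributes a constant and the weights
  stay meaningful.
* A gene with no positive values gets level 0 and the dataset's *maximum*
  raw variation: an undetected gene must not outrank expressed genes
  through an undefined-as-zero spread. A gene with exactly one positive
  value has no observable spread and gets variation 0.
* Ranks break score ties by ascending gene ID, making ranks, top-k sets,
  sector labels and all downstream statistics fully deterministic.
  A gene's percentile is the percentage of genes scoring ≤ it
  (the top gene is at the 100th percentile).
* The ubiquity cutoff is count-based (⌊fraction·N⌋), not
  value-interpolated; it is the only convention that makes the ubiquitous
  count a deterministic function of N alone.
* Duplicate gene IDs on input keep the first occurrence, with a warning
  carrying the collapsed count. Ensembl-style `.N` version suffixes are
  stripped on load by default so matrices from different sources join on
  unversioned IDs.

## GeTMM normalization

Raw counts are divided by gene length in kilobases (RPK), per-sample
scaling factors are estimated by a weighted trimmed mean of M-values
against a reference sample, and each column is scaled to
RPK / (column sum × factor) × 1e6. Pinned conventions: the reference is the
sample whose upper quartile of positive values is closest to the mean upper
quartile; genes zero in either member of a pair are excluded from M/A;
trim fractions are 30% (M) and 5% (A) with symmetric rank-based double
trimming; precision weights follow the delta method; factors are rescaled
to geometric mean 1. Non-integer input counts are rejected, which catches
accidentally pre-normalized matrices.

One deliberate property of this implementation: M-values are computed on
the RPK values directly, not on library-size-normalized values. A sample
that is an exact scalar multiple of the reference therefore receives a
factor equal to that scalar (a 2× copy yields factors (1/√2, √2) after the
geometric-mean rescale) rather than a factor of 1. The closed forms in the
test suite are derived from this definition; numeric outputs are
consequently not interchangeable with edgeR's `calcNormFactors`, which
folds sequencing depth into library size before computing M.

## Cross-dataset comparison

Each dataset's ubiquitous set is computed on its full gene list *before*
restricting to the genes shared by the pair, so a dataset's ubiquitous
count is a property of that dataset alone; sector labels are then assigned
on the shared genes. Sector statistics depend only on ranks, so any
monotone rescaling of either score vector leaves them unchanged. Rankings
are compared with Spearman's ρ (average ranks on ties) over shared genes.

## Weight sensitivity

All three weights are varied by a relative ±20% on an 11-point grid per
axis (1,331 triples covering [0.40, 0.60] × [0.20, 0.30] ×
[−0.30, −0.20]); subscores are computed once and only the linear
combination is redone per triple. Stability is the size of the
intersection of all top-k sets divided by k. With a restriction set (e.g.
the sector-11 genes of a comparison), each top set is intersected with it
and the denominator is the default-weight baseline top set intersected
with the same set; this denominator convention is a package choice — the
statistic itself does not dictate one.

## Drug-influence statistics

From per-(gene, drug, concentration) t-test summaries, records with
p ≤ 0.05 (inclusive) are significant; no multiple-testing correction is
applied at this stage (corrections are reserved for enrichment analyses).
A drug *affects* a gene when any of its concentrations is significant.
Per drug, the affected fractions of the ubiquitous set and its complement
(within the genes shared by the scoring and drug datasets) give the bias
ratio prop_nonubiq / prop_ubiq; ratios below 1 mark drugs that
disproportionately hit ubiquitous genes. Group (MOA/ATC) summaries average
member drugs' proportions by default; pooled-count aggregation is
available as an option. The |logFC|-weighted mean score of a drug's
affected genes uses, per gene, the maximum |logFC| across that drug's
significant records (the strongest observed effect; mean collapse
available). Sector-level effect sizes are means of |logFC| over all
significant records grouped by the gene's sector; sectors without records
are reported as missing, never as zero.

## Over-representation analysis

Terms are tested one-sided against the hypergeometric tail P[X ≥ k] with a
custom background — the intersection of ranked genes and all annotated
genes — which counters the annotation bias of well-studied genes. P-values
are adjusted with Benjamini–Hochberg FDR jointly across all terms of a
run. This self-contained backend replaces web-service enrichment tooling
(and its g:SCS correction), so significant-term *counts* are comparable in
pattern but not numerically identical to analyses run through such
services. The sliding variant partitions the ranking into consecutive
buckets of ⌈fraction·N⌉ genes (the last bucket may be smaller — the only
convention under which that property always holds) and tests each bucket
independently; results report, per bucket and annotation source, the
number of significant terms and the number in the highly significant band
(−log10 p_adj ≥ 16).

## Synthetic data: what it emulates, and what it does not

The generator plants four classes on a log-normal detection/level model:
ubiquitous (always detected, log-mean 6.0, log-sd 0.2), specific (detected
in 10% of samples, log-mean 4.0, log-sd 0.5), variable (detection 0.95,
log-mean 5.5, log-sd 1.0) and silent (detection 0.05, log-mean −1.0).
Defaults are 200/600/150/50 genes × 100 samples. A log-normal model was
chosen over count models because the scorer consumes normalized continuous
values and its criteria depend only on breadth, level and spread; raw
counts plus GeTMM remain available to exercise the normalization path
end to end. All draws come from an explicitly seeded generator; there is
no hidden global state.

The *variable* class is deliberately placed at a substantial expression
level with broad detection: its role is to be penalized by the variation
term while retaining enough breadth/level support to rank between the
ubiquitous and specific classes, which is the ordering the classes are
designed to exhibit (mean score ubiquitous > variable > specific >
silent). The paired-dataset generator knocks down a random 30% of the
planted ubiquitous genes in the second dataset (detection 0.15, level
reduced ~12×), the mechanism that moves genes into sector 10.

What passing tests on this data do **not** show: real tissue structure
(GTEx samples are correlated within donors and tissues; synthetic samples
are i.i.d.), microarray/RNA-seq platform differences, realistic zero
inflation, or the empirical score distribution of real data (about 90% of
real genes score low with a sharp knee near the 95th percentile; the
synthetic distribution is stylized). Recovery results demonstrate
correctness of the machinery, not performance on real data.

One structural property matters when interpreting recovery rates: the
planted ubiquitous class is 20% of the synthetic genes, four times larger
than the 5% ubiquity cutoff. The top-5% set (50 genes) is therefore a
strict subset of 200 statistically exchangeable planted genes: its
*purity* is the sharp criterion at that cutoff (measured 100%), while
recall of the full planted class is capped at 25% by arithmetic. Class
recall, knockdown sector-10 recovery and weight-grid overlap are sharp at
the cutoff equal to the planted prevalence (0.2), where the top-set
boundary falls in the separation gap between classes; the test suite and
the acceptance script report both views.

## Problem sizes

The default test suite and the acceptance script run on the synthetic
defaults (1,000 genes × 100 samples; 40 drugs × 1,000 genes; 1,331-triple
weight grids; 100-replicate FDR simulations with 200 terms), sizes chosen
so the whole suite completes in well under a minute while every statistic
is estimated far from its small-sample regime. Full-scale runs (e.g.
55,242 × 17,382 for GTEx) are supported by the same code paths via
`scripts/replicate_full.py`.

## Known limitations

* The TMM M-value convention is self-consistent but not interchangeable
  with edgeR (see above); mixed pipelines should normalize all matrices
  with one tool.
* Gene-ID namespace mapping is out of scope; inputs must already share an
  identifier space (version suffixes excepted).
* The enrichment backend is a plain hypergeometric/BH implementation;
  term databases are user-supplied (GMT-style), none are bundled.
* `above_p95` with very few genes per sample makes the 95th percentile an
  interpolation between the top order statistics; breadth subscores are
  then coarse. At least a few hundred genes per sample are advisable.
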