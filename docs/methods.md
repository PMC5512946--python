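# Methods

This note documents the statistical procedures, parameter defaults and
numerical conventions of `acetylseq`, and what the synthetic-data
generator does and does not emulate.

## Coordinate and data model

All coordinates are 0-based, half-open, everywhere. BED input is native;
the TSV gene dialect is converted at the boundary. For a gene on the +
strand the TSS is `start` and the TTS is `end − 1`; on the − strand the
TSS is `end − 1`. Chromosome names are taken verbatim; a peak on a
chromosome absent from the annotation is an error, never silently
dropped. Each annotation row is treated as one transcription unit (no
locus/transcript distinction). Replicate pooling is plain summation of
mapped-read counts, performed upstream of everything else; all
statistics run on pooled counts.

## Peak annotation

Categories are resolved in priority order TSS200 > 3′UTR > intragenic >
intergenic. The TSS200 window is `[TSS, TSS+200)` read in the direction
of transcription, i.e. `[end−200, end)` for − strand genes. Overlap
means ≥ 1 shared base; adjacent half-open intervals do not overlap.

Nearest-gene assignment uses interval-gap distance between the peak
region and the gene span (not summit-to-TSS): an overlapping gene is at
distance 0, and the 5-kb window applies symmetrically up- and
downstream with the 5000 bp boundary inclusive. When exactly one gene
is within range it is assigned; ties break to the lexicographically
smallest gene id so results are order-independent. Transposable-element
rows are excluded from candidacy (and from classification) but retained
for the gene-vs-TE comparison. The production path uses interval trees;
the test suite holds it to 100% agreement with a brute-force all-pairs
scan on random instances.

## Chromatin states

A gene carries a mark iff at least one peak of that mark is assigned to
it (idempotent in the number of peaks), giving 8 states per gene per
(condition, genotype). States are computed separately per condition;
mixing condition or genotype labels in one input is an error. Overlap
percentages are reported both unrounded and rounded to integer percent;
all overlap statistics are computed at the gene level. A sensitivity
variant retains only peaks above the 80th percentile of count density
(count per kb) before partitioning.

## Expression integration

Quintiles: genes are stably sorted by (RPKM in the reference condition,
gene id) and cut into five contiguous blocks whose sizes differ by at
most one, with larger blocks at higher quintiles; the assignment is
deterministic under input permutation. The reference condition defaults
to the condition under analysis and is configurable.

The DE rule is fold change > 1.5 with an RPKM floor of 1, where the
floor is read as max(RPKM_air, RPKM_eth) > 1 — this keeps up- and
down-calls exactly symmetric under condition exchange, which the
strict-inequality rule alone already guarantees for the ratio part.
Zero denominators are replaced by a 0.01 RPKM pseudocount. Up and down
are mutually exclusive by construction (property-tested).

All group comparisons are two-sided Welch (unequal-variance) t-tests,
on log2(RPKM + 0.01) for expression. When both groups have zero
variance the t statistic is undefined and the comparison degenerates to
equality of constants (p = 1 if the means coincide, 0 otherwise).
Benjamini–Hochberg adjusted p-values are reported alongside raw ones,
never instead of them. Groups with fewer than 2 members are summarised
but excluded from tests. The TSS enrichment window is symmetric, total
width 1000 bp (`[TSS−500, TSS+500)`), clipped at chromosome bounds;
the width is a config parameter.

## Differential enrichment

Common peaks are overlap clusters (≥ 1 bp) across the two conditions of
one mark: a cluster containing peaks from both sides becomes one pair
spanning the union, with counts summed per side; single-sided clusters
are reported as unmatched. Read density is RPKM-style,
`(count + 1) / (breadth_kb × library_millions)`, with the merged
breadth used for both sides (so breadth cancels in M and only affects
A). Library size defaults to the total pooled count of that peak set.

Normalization is ordinary least squares of M on A over the common
peaks, with an optional single trimming pass that refits after dropping
residuals beyond `trim_sigma` standard deviations (off by default).
Rescaled M is the OLS residual, hence mean 0 over the fitted peaks to
floating-point precision, and renormalizing already-rescaled input is
an exact no-op.

Significance per pair is an exact two-sided binomial test: the ethylene
count is rescaled to the air scale by the fitted line,
`k = round(count_eth · 2^{−(β₀+β₁A)})`, and tested as k successes in
`count_air + k` trials against p = ½. For this symmetric null the
minimum-likelihood two-sided p-value equals
`min(1, 2·min(CDF(k), SF(k−1)))`, which is what the vectorized
implementation computes; it is verified against `scipy.stats.binomtest`
term by term. Two zero counts give p = 1. Calls use |M_rescaled| ≥ 0.4
and p ≤ 0.05 with both boundaries inclusive. Because only the ethylene
side is rescaled, pairs whose p-value sits exactly at the 0.05 boundary
can change call under condition relabelling (count rounding); away from
the boundary, relabelling swaps gain and loss exactly.

## Metagene profiles

log2-ratio tracks are per-bin `log2((ChIP+ε)/(IgG+ε))` with ε = 0.1
RPKM. The scale-regions matrix uses 2 kb flanks at 20 bins and a
100-bin body, resampled by mean-within-segment at single-base
resolution; − strand rows are reversed so column 0 is always 5′. A
constant track therefore yields an exactly flat profile, two genes with
the same relative signal shape give identical rows regardless of
length, and mirroring the genome (reflecting coordinates and flipping
strands) leaves every row unchanged. Genes shorter than the body bin
count are dropped with a warning. Defaults (10 bp track bins, 2 kb
flanks, 100/20 bins) are deepTools-comparable and configurable.

## Synthetic-data generator

The generator is counts-first: per-peak Poisson counts are drawn, then
coverage tracks are rendered from those counts, so tracks and peaks can
never disagree. One synthetic chromosome holds the genes with
inter-gene gaps drawn uniformly in [300, 9000] bp — deliberately
straddling the 5-kb assignment threshold — followed by a region of
intergenic background peaks (> 5 kb from any gene) and a TE region.
Each planted peak covers its gene's TSS and is clipped to a territory
that cannot reach a neighbouring gene, so nearest-gene assignment
provably recovers the planted gene–mark map; this is what makes exact
state-recovery checks meaningful.

Planted structure, with defaults:

* expression: lognormal RPKM (ln-mean 1.0, ln-sd 1.5);
* mark presence rises with expression quintile on a logistic scale,
  `P(mark|q) = σ(b + s(q−3))`, with K9Ac most prevalent (b = 0.6) and
  K14Ac rarest (b = −1.6), slopes ≈ 1;
* peak breadth ≈ 700–800 bp base with Gaussian noise (sd 60 bp); K9Ac
  breadth additionally grows 150 bp per quintile;
* counts are Poisson with mean `100 · (1 + 0.5(q−1))` per peak;
* 10% of genes are ethylene-regulated (up:down ≈ 2:3, as observed for
  marked regulated genes), sampled with weight `exp(q−1)` so regulated
  genes concentrate in the upper quintiles, with expression fold
  changes uniform in [1.8, 4] (always beyond the 1.5 rule) and 0.05
  log2 noise elsewhere (never enough to trip the rule), so planted DE
  labels are exactly recoverable;
* ethylene multiplies K14Ac/K23Ac count means by 2^{±1} on up/down
  genes and widens K14Ac/K23Ac peaks on up genes by 1.4×; K9Ac count
  means and intervals are identical between conditions, so the planted
  K9Ac differential is exactly zero;
* the air-condition K9Ac contrast between future up- and down-regulated
  genes is planted as a 1.4× breadth and count-mean multiplier; it is
  applied in both conditions precisely so that it creates no K9Ac
  differential between conditions;
* gene bodies carry a 2.0 RPKM background in the tracks, depleted
  10-fold over TEs, with per-element lognormal noise (σ = 0.2);
* `ein2-5` mode zeroes every ethylene effect (expression response,
  count-mean changes, breadth changes), leaving only Poisson noise
  between conditions.

What the generator does **not** emulate: read-level data (mapping bias,
duplicates, GC effects), overlapping or nested gene models, peaks
shared ambiguously between genes, replicate variability beyond Poisson
(no overdispersion), multi-chromosome genomes, and any direct coupling
between track background and expression. Passing recovery tests
therefore demonstrates correctness of the interval arithmetic, state
logic and statistics under the planted model — not robustness to the
messiness of real ChIP-seq, where peak–gene assignment is genuinely
ambiguous and counts are overdispersed.

## Calibration and simulation designs used by the checks

The differential-caller checks simulate common peaks with per-pair base
enrichment drawn lognormally (median count 100, ln-sd 0.8, a realistic
spread of peak enrichment) and Poisson counts. Under the null the
called fraction sits near 3–4% (the p ≤ 0.05, |M| ≥ 0.4 rule is
conservative because the M threshold bites at moderate counts); with
2-fold gains planted on 10% of 2000 pairs the caller's power exceeds
0.9. The enrichment spread matters: if every pair had identical base
enrichment, A would have almost no variance and the planted cluster
would dominate the OLS normalization line — a regime MA normalization
is not designed for, since it presumes most common peaks are unchanged
and span a wide intensity range.

Structure-recovery checks use 5000 genes; the EIN2-null end-to-end
check uses 800 genes with tracks; metaprofile ordering uses 1000 genes.
Air-vs-ethylene metaprofile concordance in `ein2-5` mode is asserted as
|Δ quintile mean| ≤ 3·SE(Δ) per mark and quintile (observed |z| ≲ 0.3),
rather than as a p > α rule, which would fail by construction ~14% of
the time across 15 true-null contrasts.

## Known limitations

* The binomial significance model conditions on the total count and
  ignores uncertainty in the fitted normalization line; at very low
  counts (< ~10 reads per side) it is conservative.
* OLS normalization is sensitive to heavy contamination by truly
  changed peaks concentrated at one end of the A range; the
  `trim_sigma` option mitigates extreme outliers only.
* One peak is assigned to at most one gene; bidirectional promoters
  shared by two genes are attributed to the nearer (or lexicographically
  first) gene only.
* bedGraph I/O requires fixed-bin, bin-aligned intervals; bigWig is not
  supported.
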