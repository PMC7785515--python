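# Methods

`costim` re-implements, as one tested pipeline, the computational analysis
of a two-signal T-cell activation experiment: naive and memory CD4+ T cells
stimulated across a seven-condition grid of TCR (signal 1) and CD28
(costimulation, signal 2) doses, with bulk RNA-seq as the primary readout
and peak-level chromatin data (ATAC, H3K27ac) as a secondary layer.  This
note records the models, the defaults that matter, what the synthetic data
do and do not emulate, and the design choices made where the design was
genuinely open.

## The stimulation grid

Each sample carries an ordinal TCR dose and CD28 dose in {0, 1, 2}.  Seven
combinations are admitted: resting (0,0), low/low, low/high, high/low,
high/high, high TCR alone and high CD28 alone.  When one stimulus is under
test, every sample that did not receive it contributes at dose 0 — in
particular, high-TCR-alone samples are grouped with resting when testing
CD28, and vice versa.  The other stimulus is not modelled; it is absorbed
by the intercept.  This single-stimulus grouping is the load-bearing
assumption of the whole classification: it buys power (all 7 conditions
enter every test) at the price of ignoring TCRxCD28 interaction, which is
deliberately out of scope.

## Negative-binomial machinery

Counts are modelled as `K_gj ~ NB(mu_gj, alpha_g)` with
`mu_gj = s_j exp(x_j' beta_g)` and `Var = mu + alpha mu^2`.

* **Size factors** `s_j`: median-of-ratios over genes with positive counts
  in every sample, rescaled to geometric mean 1 (falling back to
  positive-entry geometric means when no all-positive gene exists).
* **Dispersions** `alpha_g`: per-gene profile MLE at group-mean fitted
  means (groups = cell type x condition), bounded to [1e-8, 10], then
  shrunk in log space toward a least-squares mean-dispersion trend
  `alpha_tr(mu) = a1/mu + a0` with a normal prior of variance 0.761
  (posterior mode).  This is a transparent simplification of Cox-Reid
  adjusted estimation: estimates differ slightly from DESeq2's, but the
  downstream tests are what matters and they are calibrated (see the
  acceptance suite: type-I error ~0.05, LRT statistic ~ chi-square(1) under
  the null).
* **GLM fits**: iteratively reweighted least squares with log link, fixed
  dispersion, offset `log s_j`, convergence at max |delta beta| < 1e-6 or
  100 iterations, linear predictor clipped to +/-30 to survive all-zero
  groups.  An optional normal prior on non-intercept coefficients
  (variance 0.661 in log2-fold-change units) provides ridge-style LFC
  shrinkage; it is OFF by default because the classification uses
  likelihood-ratio tests, where unshrunk effects are conventional.
* **Tests**: Wald z = beta/SE for pairwise condition-vs-resting contrasts;
  LRT with chi-square reference for the nested dose models.
  Benjamini-Hochberg correction is applied within each (cell type,
  contrast) or (cell type, stimulus, model stage) family.

Genes enter the analysis if they lie on an autosome or chromosome X and
have at least 20 counts in at least 3 samples.  Genes with an all-zero
contrast group get a +0.5-pseudocount fold-change for reporting; the test
p-value still comes from the GLM when the fit converges.

## Sensitivity classification

Per cell type, genes upregulated versus resting in at least one of the six
stimulated conditions (fold-change >= 2, BH FDR <= 5%) are tested per
stimulus:

1. **linear** — dose enters as a numeric 0/1/2 covariate, so "incremental
   fold-change" is a single coefficient; pass requires BH q <= 0.05,
   per-increment fold-change >= 1.5 and a positive coefficient.
2. **switch** — only for genes that failed the linear model; dose is
   replaced by a presence indicator (dose > 0); pass requires q <= 0.05
   and fold-change >= 2.

The linear model has priority by construction: the switch stage never sees
a gene whose linear test passed.  Note a clean on/off gene usually *also*
satisfies the linear gate (a 4-fold jump at dose 1 implies a fitted slope
of ~1 log2-unit per increment), so under prioritisation most sensitive
genes are labelled linear — consistent with linear dominance in this kind
of titration design.  A gene passing both stimuli is labelled "both" and
excluded from the unique-sensitivity set by default; resolving "both" by
the larger effect size is available via `both_resolution: effect_size`.
Switcher genes are those uniquely sensitive to different stimuli in the
two subsets (e.g. TCR in naive, CD28 in memory).

FDR levels: 5% is stated for the pairwise DE step; the same 5% is assumed
for the linear/switch LRT stages, which is the natural reading but not
explicit in the source analysis.

## Preranked gene-set enrichment

The ranking statistic is the linear-model log2 fold-change.  The
enrichment score is the weighted Kolmogorov-Smirnov running sum (weight
p=1): hits add `|stat|^p / sum_set |stat|^p`, misses subtract `1/(N-|S|)`;
ES is the signed extremum.  Significance uses a gene-label permutation
null — random sets of matched size — with `p = (1 + #{same-sign null with
|ES| >= |ES_obs|}) / (1 + #same-sign null)` and `NES = ES / mean |same-sign
null ES|`.  Normalising within the same-sign side (as fgsea does) is
required for null uniformity; dividing by all permutations would halve p.
Defaults: 10,000 permutations (configurable to 1,000,000), set-size
filters 5-500, ties broken by gene id for determinism.  The adaptive
multilevel p-value estimator of fgsea is intentionally not reproduced.

## GWAS-locus enrichment

Loci are built per trait from index SNPs with p < 5e-8 outside the MHC
(default interval chr6:25-34 Mb; the exclusion is standard but its exact
coordinates are a configuration choice).  LD proxies are panel SNPs on the
same chromosome within 1 Mb with dosage r^2 > 0.8; the locus is the proxy
span extended 150 kb per side, merged per trait when overlapping.

Enrichment of a gene set is tested by matched permutation: genes are
binned by (length quintile x mean-expression quintile) on the universe;
each of B draws resamples, per bin, as many universe genes as the query
holds there; the statistic is the count of genes whose *body* intersects
any locus (window flanks are not added — the locus span was already
extended 150 kb), and `p = (1 + #{null >= obs}) / (1 + B)`, one-sided.
Overlap is counted in genes, not loci, reading "genes fell within the
locus boundaries" literally.  Bin granularity (5x5) is a choice; universes
under 25 genes coarsen automatically.

SNP-level annotation: a driver gene (query gene inside a trait locus) is
flagged when any member SNP of its locus falls inside a chromatin peak
within the gene's 150 kb-flanked window (half-open convention: peak start
inclusive, end exclusive).  Allele-level motif disruption replaces a
database lookup with direct scoring: for each allele, the best log-odds
over all motif placements covering the SNP on both strands; a SNP is
"disrupting" when the better allele reaches 80% of the motif's maximal
score and |alt - ref| >= 1 bit.  Both thresholds are configurable and
deliberately conservative.

## Chromatin analytics

Gene windows are the gene body flanked by 150 kb **per side** (the
"150 kb window" phrasing is ambiguous; per-side matches the locus
extension convention, and a total-width alternative is available by
setting the flank to 75 kb).  Window coverage is
`(reads-in-window + 1) / library-total`; condition enrichment is the
per-gene log2 coverage ratio tested against zero with a one-sample t-test
across the gene set (skipped below 3 genes).  Motif enrichment compares
peaks near stimulus-sensitive genes (foreground) with peaks near
non-differentially-expressed genes (background, foreground peaks
excluded): a one-sided binomial test per motif of foreground hit counts at
the background hit rate, treating that rate as known because the
background is much larger in intended use; a zero background rate with
foreground hits is floored at 1/(2|bg|).  PWM log-odds use +1 pseudocount
per cell against a uniform background; scanning covers both strands and
scores ambiguous bases as background (0 log-odds).  QC reports FRiP, the
fraction of peaks with signal value > 10, and paired relative peak-count
differences between groups.

## Synthetic data: what it emulates and what it does not

`simulate_experiment` reproduces the study geometry — 2 cell types x 7
conditions x 4 donors (56 samples), donors split over two sequencing
batches with per-(batch, gene) log-normal effects (sd 0.2 log2), relative
library depths in [0.7, 1.4] — with NB counts around log2-normal baselines
(mean 6, sd 1.5 log2; dispersions log-normal around 0.1).  Planted truth
classes: per-stimulus linear (1 log2 unit per dose increment) and switch
(2 log2 units on presence) responders, dual responders, nulls, and
switcher genes whose stimulus flips between subsets.  The synthetic genome
is 4 chromosomes (>= 50 Mb, grown as needed) with genes >= 100 kb apart so
window/locus overlap is unambiguous; GWAS power simulations use 400 kb
spacing so each extended locus covers exactly its target gene, keeping the
planted enrichment factor interpretable as a rate ratio.  LD proxies copy
the index haplotypes with per-haplotype flip probability (0.02 in
LD-intact scenarios, giving E[r^2] ~ 0.9); trait loci target
stimulus-sensitive genes with a configurable placement weight.  Chromatin
simulation plants peaks near TSSs, multiplies window masses of responsive
genes by a factor (default 2) in matching conditions with 20% log-normal
noise, scales masses and totals jointly by library depth (so
normalisation cancels depth exactly, as it should), and embeds consensus
motif instances in a configurable fraction of sensitive-gene peaks.

Not emulated: read-level data, fragment-size structure, realistic
haplotype/recombination models, correlated gene-gene expression, donor
random effects, and composition extremes.  Passing recovery tests on this
generator therefore demonstrates the *procedures* are correct and
calibrated under their stated model, not that the model captures every
property of real libraries.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately compact configurations — 
2,000-gene calibration and recovery simulations, 1,000-gene universes with
30-100 loci, 500-10,000 permutations, 200 calibration replicates — sizes
at which every statistical property being asserted is already measurable
with comfortable margins.  Numerical details worth knowing: dispersion
optimisation is a bounded scalar search on log alpha (tolerance 1e-4);
IRLS falls back to least-squares solves on singular weighted normal
equations; the running-sum extremum takes the first index at exact ties;
GSEA null pools are shared across sets of equal size; permutation p-values
use the add-one estimator and can never be 0; all randomness derives from
`numpy.random.default_rng` seeded with (seed, fixed-offset) tuples so each
simulated artifact has an independent, reproducible stream.

## Known limitations

* Dispersion shrinkage uses a two-parameter 1/mu trend; datasets with
  non-monotone mean-dispersion relationships will be under-fit.
* Wald tests on groups with very low counts rely on the +/-30 linear
  predictor clip; fold-changes for all-zero groups are reported from
  pseudocounts and are not test statistics.
* The permutation enrichment treats loci as fixed; uncertainty in LD
  expansion is not propagated.
* The motif binomial test assumes peak sequences are exchangeable within
  foreground/background; GC or length covariates are not modelled (peaks
  of equal width in the simulator).
* With 4 donors per condition the switch/linear distinction is powered
  for effects >= ~1.5-2x; weaker planted effects will mostly land in
  "none".
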