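# costim

Dose-response classification of TCR- and CD28-sensitive genes in naive and
memory CD4+ T cells, with GWAS-locus, gene-set and chromatin analytics.

T-cell activation needs two coordinated signals: antigen recognition
through the T-cell receptor (TCR, signal 1) and CD28 costimulation
(signal 2).  Titrating the two signals independently across a
seven-condition grid — resting, low/high combinations of both, and each
signal alone — makes it possible to ask, gene by gene, *which* signal an
activation-induced gene actually listens to, and whether it responds
gradually or like a switch.  `costim` is for computational immunologists
and statistical-genetics analysts who want that classification, and its
downstream disease-genetics and chromatin interpretation, as a
reproducible pipeline that runs end-to-end on synthetic data with known
truth.

## The model

Counts for gene *g* in sample *j* follow a negative binomial,

    K_gj ~ NB(mu_gj, alpha_g),    mu_gj = s_j exp(x_j' beta_g),
    Var(K) = mu + alpha mu^2,

with median-of-ratios size factors `s_j` and per-gene dispersions shrunk
toward a mean-dispersion trend.  Genes upregulated versus resting in any
condition (fold-change >= 2, BH FDR <= 5%) are then tested per stimulus
with likelihood-ratio tests of nested GLMs over all seven conditions
(samples without the stimulus under test count as dose 0):

* **linear**: `log mu = b0 + b1 * dose + batch`, pass if q <= 0.05 and the
  per-increment fold-change `2^(b1/ln 2) >= 1.5`;
* **switch**: `log mu = b0 + b1 * [dose > 0] + batch`, tested only where
  the linear model failed, pass if q <= 0.05 and fold-change >= 2.

Each gene ends up TCR-sensitive, CD28-sensitive, "both", or "none", per
cell type; genes whose stimulus flips between naive and memory cells are
*switchers*.  Sensitive gene sets feed three downstream analyses: a
preranked permutation GSEA on the linear-model fold-change ranking; a
matched-gene permutation test of overlap with LD-defined GWAS loci (index
SNPs at p < 5e-8, r^2 > 0.8 proxies, +/-150 kb, MHC excluded, null draws
matched on gene length and expression quintiles); and chromatin
window-coverage and motif enrichment around sensitive genes.  See
`docs/methods.md` for the full account.

## Worked example

The `run-all` subcommand simulates a compact dataset (300 genes: 30
TCR-linear, 30 CD28-linear, 10+10 switch, 5 dual, 215 null; 2 cell types x
7 conditions x 4 donors) and runs every stage:

```sh
costim run-all --seed 3 --out results/
```

`results/sensitivity_summary.tsv` then contains

```text
cell_type  n_upregulated  n_TCR  n_CD28  n_both  n_none  frac_unique  frac_linear
memory     85             40     40      5       0       0.941        1.0
naive      85             40     40      5       0       0.941        0.9875
```

— the 85 genes with a planted response were all detected as upregulated,
each of the 40 TCR- and 40 CD28-responsive genes was assigned its true
stimulus, the 5 dual-responders landed in "both" (excluded from the
unique-sensitivity fraction, hence 0.941), and almost all sensitive genes
follow the linear model, as expected when on/off responses also clear the
linear gate.  `results/gsea.tsv` shows the planted pathway recovered on
the CD28 fold-change ranking (ES 0.81, permutation p 0.0022, q 0.013),
and `results/gwas_enrichment.tsv` reports the locus-overlap test for the
sensitive set (observed 13 genes in loci versus 6.37 +/- 1.9 expected,
permutation p 0.002 at B = 500).  Every output table carries a header with
the package version, seed and configuration hash; rerunning with the same
seed reproduces all tables byte-for-byte.

The same stages are available as a library (`costim.classify.run_classification`,
`costim.gsea.gsea_test`, `costim.gwas.permutation_enrichment`, ...) and as
file-driven subcommands (`simulate`, `classify`, `gsea`, `gwas-enrich`,
`chromatin`).

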