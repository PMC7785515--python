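"""Synthetic-data generation with known ground truth.

Emulates the study design the pipeline expects: two CD4+ T-cell subsets
(naive, memory) stimulated across the 7-condition TCR x CD28 dose grid in
~4 donors, RNA-seq counts drawn from a negative binomial with planted
linear / switch dose effects and a two-batch structure; a genotype panel
with LD blocks around trait index SNPs; and condition-specific chromatin
peaks with planted motif instances and window read masses.

The synthetic genome is 4 chromosomes (>= 50 Mb each, grown when the gene
count demands) with genes spaced >= 100 kb apart so locus/window overlap
is unambiguous.  All randomness flows from ``numpy.random.default_rng``
seeded with (seed, fixed-offset) pairs, one stream per artifact, so
regenerating one artifact never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITION_GRID, Pwm, validate_design

GENE_CLASSES = (
    "tcr_linear", "cd28_linear", "tcr_switch", "cd28_switch", "both", "null",
    "switcher_tcr_cd28", "switcher_cd28_tcr",
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Study conditions for the expression simulation.

    ``class_counts`` gives the number of genes per truth class (see
    ``GENE_CLASSES``); per-increment and switch effects are log2
    fold-changes.  ``library_size_range`` holds relative sequencing-depth
    factors.  Dispersions are log-normal around ``dispersion_mean`` with
    log-sd ``dispersion_sd_log`` (0 pins all genes to the mean).
    """

    class_counts: dict = field(default_factory=lambda: {
        "tcr_linear": 150, "cd28_linear": 150, "tcr_switch": 50,
        "cd28_switch": 50, "both": 50, "null": 550,
    })
    n_donors: int = 4
    per_increment_log2fc: float = 1.0
    switch_log2fc: float = 2.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    dispersion_mean: float = 0.1
    dispersion_sd_log: float = 0.3
    batch_effect_sd: float = 0.2
    library_size_range: tuple = (0.7, 1.4)
    gene_spacing: int = 100_000
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.class_counts) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if self.n_donors < 2:
            raise ValueError("need >= 2 donors")
        for name in ("baseline_log2_sd", "dispersion_sd_log", "batch_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gene_spacing < 100_000:
            raise ValueError("gene_spacing must be >= 100 kb")

    @property
    def n_genes(self) -> int:
        return int(sum(self.class_counts.values()))

    @classmethod
    def from_fractions(cls, n_genes: int, class_fractions: dict, **kw) -> "SimulationParams":
        tot = sum(class_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {tot}, not 1")
        counts, assigned = {}, 0
        items = sorted(class_fractions.items())
        for name, frac in items[:-1]:
            counts[name] = int(round(n_genes * frac))
            assigned += counts[name]
        counts[items[-1][0]] = n_genes - assigned
        return cls(class_counts=counts, **kw)


@dataclass
class SimulatedExperiment:
    counts: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    chrom_sizes: dict


def _place_genes(n_genes: int, rng: np.random.Generator, spacing: int = 100_000):
    """Genes on 4 chromosomes, >= ``spacing`` (min 100 kb) apart.

    Chromosomes start at 50 Mb and grow when the gene count demands; wide
    spacing keeps locus/window-to-gene assignment unambiguous.
    """
    spacing = max(spacing, 100_000)
    lengths = rng.integers(2_000, 20_001, size=n_genes)
    n_chrom = 4
    per_chrom = -(-n_genes // n_chrom)
    need = per_chrom * (spacing + 25_000) + 200_000
    chrom_len = max(50_000_000, int(need))
    chroms, starts, ends = [], [], []
    cursor, ci = 100_000, 0
    for g in range(n_genes):
        if g > 0 and g % per_chrom == 0:
            ci += 1
            cursor = 100_000
        chroms.append(f"chr{ci + 1}")
        starts.append(cursor)
        ends.append(cursor + int(lengths[g]))
        cursor = ends[-1] + spacing + int(rng.integers(0, 5_000))
    ann = pd.DataFrame({
        "gene_id": [f"G{g:05d}" for g in range(n_genes)],
        "chrom": chroms,
        "start": starts,
        "end": ends,
        "strand": rng.choice(["+", "-"], size=n_genes),
    })
    ann["length"] = ann["end"] - ann["start"]
    sizes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    return ann.set_index("gene_id", drop=False), sizes


def _class_per_cell_type(cls: str, cell_type: str):
    """(stimulus, model) effect active for this class in this cell type."""
    table = {
        "tcr_linear": [("TCR", "linear")],
        "cd28_linear": [("CD28", "linear")],
        "tcr_switch": [("TCR", "switch")],
        "cd28_switch": [("CD28", "switch")],
        "both": [("TCR", "linear"), ("CD28", "linear")],
        "null": [],
    }
    if cls == "switcher_tcr_cd28":
        return [("TCR", "linear")] if cell_type == "naive" else [("CD28", "linear")]
    if cls == "switcher_cd28_tcr":
        return [("CD28", "linear")] if cell_type == "naive" else [("TCR", "linear")]
    return table[cls]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, Var mu + alpha mu^2); Poisson at negligible alpha."""
    alpha = np.broadcast_to(np.asarray(alpha, float)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        k = 1.0 / alpha[~tiny]
        p = k / (k + mu[~tiny])
        out[~tiny] = rng.negative_binomial(k, p)
    return out


def simulate_experiment(params: SimulationParams) -> SimulatedExperiment:
    """Counts + design + annotation + per-gene truth for the 7-condition grid."""
    rng_struct = np.random.default_rng([params.seed, 0])
    rng_gene = np.random.default_rng([params.seed, 1])
    rng_counts = np.random.default_rng([params.seed, 2])

    n_genes = params.n_genes
    annotation, chrom_sizes = _place_genes(n_genes, rng_struct, params.gene_spacing)
    gene_ids = annotation.index

    classes = np.concatenate([
        np.repeat(name, k) for name, k in sorted(params.class_counts.items())
    ])
    classes = classes[rng_gene.permutation(n_genes)]

    baseline = rng_gene.normal(params.baseline_log2_mean, params.baseline_log2_sd, n_genes)
    alpha = params.dispersion_mean * np.exp(
        rng_gene.normal(0.0, params.dispersion_sd_log, n_genes)
        - 0.5 * params.dispersion_sd_log ** 2
    )

    # sample sheet: 2 cell types x 7 conditions x donors; donors split in 2 batches
    rows = []
    donors = [f"d{i + 1}" for i in range(params.n_donors)]
    for ct in ("naive", "memory"):
        for (tcr, cd28), cond in CONDITION_GRID.items():
            for d in donors:
                batch = "b1" if donors.index(d) < params.n_donors // 2 else "b2"
                rows.append((f"{ct}_{cond}_{d}", ct, tcr, cd28, d, batch))
    design = validate_design(pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "tcr_dose", "cd28_dose", "donor", "batch"]
    ))
    n_samples = design.shape[0]
    lib = rng_gene.uniform(*params.library_size_range, n_samples)
    batch_levels = sorted(design["batch"].unique())
    batch_eff = {
        b: rng_gene.normal(0.0, params.batch_effect_sd, n_genes) for b in batch_levels
    }
    # batch effects centred per gene so they do not shift baselines
    mean_be = np.mean([batch_eff[b] for b in batch_levels], axis=0)
    for b in batch_levels:
        batch_eff[b] = batch_eff[b] - mean_be

    dose = {"TCR": design["tcr_dose"].to_numpy(), "CD28": design["cd28_dose"].to_numpy()}
    ct_arr = design["cell_type"].to_numpy()
    log2_mu = np.tile(baseline[:, None], (1, n_samples))
    for ct in ("naive", "memory"):
        mask = ct_arr == ct
        for g in range(n_genes):
            for stim, model in _class_per_cell_type(classes[g], ct):
                d = dose[stim][mask]
                if model == "linear":
                    log2_mu[g, mask] += params.per_increment_log2fc * d
                else:
                    log2_mu[g, mask] += params.switch_log2fc * (d > 0)
    for j, b in enumerate(design["batch"]):
        log2_mu[:, j] += batch_eff[b]

    mu = lib[None, :] * np.exp2(log2_mu)
    counts = pd.DataFrame(_nb_draw(rng_counts, mu, alpha), index=gene_ids,
                          columns=design.index)

    def truth_label(cls, ct):
        eff = _class_per_cell_type(cls, ct)
        if not eff:
            return "none"
        if len(eff) > 1:
            return "both"
        return f"{eff[0][0]}:{eff[0][1]}"

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "true_class": classes,
        "truth_naive": [truth_label(c, "naive") for c in classes],
        "truth_memory": [truth_label(c, "memory") for c in classes],
        "baseline_log2_mean": baseline,
        "dispersion": alpha,
        "per_increment_log2fc": np.where(
            np.isin(classes, ["tcr_linear", "cd28_linear", "both",
                              "switcher_tcr_cd28", "switcher_cd28_tcr"]),
            params.per_increment_log2fc, 0.0),
    }).set_index("gene_id", drop=False)
    return SimulatedExperiment(counts, design, annotation, truth, chrom_sizes)


def simulate_pathways(truth: pd.DataFrame, n_random_sets: int = 5,
                      set_size: int = 30, seed: int = 0) -> dict:
    """Gene sets for enrichment tests: one set of sensitive genes + random sets."""
    rng = np.random.default_rng([seed, 5])
    genes = truth.index.to_numpy()
    sensitive = truth.index[truth["true_class"] != "null"].to_numpy()
    sets = {}
    if len(sensitive) >= 5:
        k = min(set_size, len(sensitive))
        sets["PLANTED_SENSITIVE"] = set(rng.choice(sensitive, k, replace=False))
    for i in range(n_random_sets):
        sets[f"RANDOM_{i + 1}"] = set(rng.choice(genes, min(set_size, len(genes)),
                                                 replace=False))
    return sets


def demo_pwms() -> list:
    """Two synthetic motifs: a sharp 8-mer and a softer 6-mer.

    Purely synthetic stand-ins for a motif database, for simulations and
    demonstrations only.
    """
    sharp = np.full((4, 8), 1.0)
    for j, b in enumerate("TGACTCAG"):
        sharp["ACGT".index(b), j] = 40.0
    soft = np.full((4, 6), 5.0)
    for j, b in enumerate("CACGTG"):
        soft["ACGT".index(b), j] = 20.0
    return [Pwm("SYN_SHARP_TGACTCAG", sharp), Pwm("SYN_SOFT_CACGTG", soft)]


# ---------------------------------------------------------------------------
# GWAS panel


@dataclass
class GwasSim:
    panel: pd.DataFrame       # samples x SNPs dosages
    variants: pd.DataFrame    # snp_id, chrom, pos (0-based)
    snps: pd.DataFrame        # GWAS index-SNP table (0-based pos)
    locus_truth: pd.DataFrame


def simulate_gwas_panel(n_loci: int, n_traits: int, proxies_per_index: int,
                        flip_prob: float, enrichment_factor: float,
                        genes: pd.DataFrame, truth: pd.DataFrame,
                        n_samples: int = 200, n_null_snps: int = 5,
                        seed: int = 0) -> GwasSim:
    """Index SNPs + LD proxies on the synthetic genome.

    Proxy haplotypes are copies of the index haplotypes with per-sample
    flip probability ``flip_prob`` (expected r^2 decreases with
    flip_prob).  Loci target genes sampled with weight
    ``enrichment_factor`` for stimulus-sensitive genes versus 1 for the
    rest; index p-values are all genome-wide significant.
    """
    if not (0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if n_loci > genes.shape[0]:
        raise ValueError("more loci requested than genes on the synthetic genome")
    rng = np.random.default_rng([seed, 3])

    sensitive = (truth["true_class"] != "null").reindex(genes.index).fillna(False)
    w = np.where(sensitive.to_numpy(), enrichment_factor, 1.0)
    targets = rng.choice(genes.index.to_numpy(), n_loci, replace=False, p=w / w.sum())

    dosages, var_rows, snp_rows, truth_rows = {}, [], [], []
    for i, gid in enumerate(targets):
        g = genes.loc[gid]
        trait = f"trait{1 + i % n_traits}"
        pos = int((g["start"] + g["end"]) // 2)
        rsid = f"rs{i + 1:05d}_idx"
        maf = rng.uniform(0.1, 0.5)
        hap = rng.random((2, n_samples)) < maf
        dosages[rsid] = hap.sum(axis=0).astype(np.int8)
        var_rows.append((rsid, g["chrom"], pos))
        ref, alt = rng.choice(list("ACGT"), 2, replace=False)
        snp_rows.append((trait, rsid, g["chrom"], pos, ref, alt,
                         float(10.0 ** -rng.uniform(8.5, 30.0))))
        truth_rows.append((trait, rsid, gid, bool(sensitive.loc[gid])))
        for k in range(proxies_per_index):
            off = int(rng.integers(1, 50_001)) * int(rng.choice([-1, 1]))
            prsid = f"rs{i + 1:05d}_p{k + 1}"
            flips = rng.random((2, n_samples)) < flip_prob
            dosages[prsid] = (hap ^ flips).sum(axis=0).astype(np.int8)
            var_rows.append((prsid, g["chrom"], max(0, pos + off)))

    # non-significant background SNPs exercise the p-value filter downstream
    for k in range(n_null_snps):
        gid = targets[int(rng.integers(0, len(targets)))]
        g = genes.loc[gid]
        rsid = f"rs_null{k + 1}"
        pos = int(g["start"]) + int(rng.integers(0, g["length"]))
        ref, alt = rng.choice(list("ACGT"), 2, replace=False)
        snp_rows.append((snp_rows[0][0], rsid, g["chrom"], pos, ref, alt,
                         float(rng.uniform(1e-4, 1.0))))

    panel = pd.DataFrame(dosages, index=[f"s{i + 1}" for i in range(n_samples)])
    variants = pd.DataFrame(var_rows, columns=["snp_id", "chrom", "pos"]
                            ).set_index("snp_id", drop=False)
    snps = pd.DataFrame(snp_rows, columns=["trait", "rsid", "chrom", "pos",
                                           "ref", "alt", "pvalue"])
    locus_truth = pd.DataFrame(truth_rows,
                               columns=["trait", "rsid", "target_gene", "sensitive"])
    return GwasSim(panel, variants, snps, locus_truth)


# ---------------------------------------------------------------------------
# chromatin


@dataclass
class ChromatinSim:
    peaks: dict               # condition -> peak table
    window_mass: pd.DataFrame  # genes x conditions, reads in 150 kb window
    library_totals: pd.Series
    sequences: dict           # peak name -> sequence
    planted_motif: str | None


def simulate_chromatin(conditions: list, genes: pd.DataFrame, truth: pd.DataFrame,
                       pwms: list[Pwm], planted_motif_rate: float = 0.5,
                       bg_motif_rate: float = 0.05, coverage_factor: float = 2.0,
                       noise_sd: float = 0.2, peak_width: int = 400,
                       peaks_per_gene: int = 2, seed: int = 0) -> ChromatinSim:
    """Condition-tagged peaks near gene TSS with planted motifs and masses.

    Window read mass for a stimulus-sensitive gene is multiplied by
    ``coverage_factor`` in conditions where that stimulus is present (with
    log-normal multiplicative noise of sd ``noise_sd``); consensus motif
    instances of ``pwms[0]`` are embedded in a ``planted_motif_rate``
    fraction of sensitive-gene peaks and ``bg_motif_rate`` of the rest.
    """
    if not (0.0 <= planted_motif_rate <= 1.0):
        raise ValueError("planted_motif_rate must be in [0, 1]")
    rng = np.random.default_rng([seed, 4])
    grid = {v: k for k, v in CONDITION_GRID.items()}
    for c in conditions:
        if c not in grid:
            raise ValueError(f"unknown condition {c!r}")

    sens_stim = truth["truth_naive"].str.split(":").str[0].reindex(genes.index)
    motif = pwms[0] if pwms else None
    consensus = motif.consensus if motif is not None else None

    peak_tables, sequences = {}, {}
    masses = pd.DataFrame(index=genes.index, columns=conditions, dtype=float)
    base_mass = np.exp(rng.normal(np.log(1000.0), 0.3, genes.shape[0]))
    # per-library sequencing depth scales window masses and totals alike,
    # so library normalisation cancels it exactly
    depth = dict(zip(conditions, np.exp(rng.normal(0.0, 0.05, len(conditions)))))
    for cond in conditions:
        tcr, cd28 = grid[cond]
        present = {"TCR": tcr > 0, "CD28": cd28 > 0}
        rows = []
        for gi, (gid, g) in enumerate(genes.iterrows()):
            tss = g["start"] if g["strand"] == "+" else g["end"]
            stim = sens_stim.loc[gid]
            boosted = stim in present and present[stim]
            for k in range(peaks_per_gene if peaks_per_gene > 0 else 0):
                center = int(tss) + int(rng.integers(-20_000, 20_001))
                start = max(0, center - peak_width // 2)
                name = f"{cond}_{gid}_pk{k + 1}"
                score = float(rng.uniform(2, 30)) * (2.0 if boosted else 1.0)
                rows.append((g["chrom"], start, start + peak_width, name, score))
                seq = "".join(rng.choice(_BASES, peak_width))
                rate = planted_motif_rate if stim != "none" else bg_motif_rate
                if consensus is not None and rng.random() < rate:
                    off = int(rng.integers(0, peak_width - len(consensus) + 1))
                    seq = seq[:off] + consensus + seq[off + len(consensus):]
                sequences[name] = seq
            noise = np.exp(rng.normal(0.0, noise_sd) - 0.5 * noise_sd ** 2)
            m = base_mass[gi] * (coverage_factor if boosted else 1.0) * noise
            masses.loc[gid, cond] = float(np.round(m * depth[cond]))
        peak_tables[cond] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score"]
        ).sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    # library totals are dominated by genome-wide background reads, so the
    # boosted windows do not inflate their own normaliser
    totals = pd.Series(
        {c: float(np.round(base_mass.sum() * 3.0 * depth[c])) for c in conditions})
    return ChromatinSim(peak_tables, masses, pd.Series(totals, name="library_total"),
                        sequences, motif.name if motif is not None else None)
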