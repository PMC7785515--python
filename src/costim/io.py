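"""Readers, writers, run configuration and shared domain types.

All coordinates are 0-based half-open internally.  BED input is native;
gene and SNP tables declared 1-based in the configuration are converted on
read.  Every writer emits plain TSV; result writers prepend ``#`` header
lines recording the package version, the seed and a configuration hash so
outputs are reproducible byte-for-byte from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

logger = logging.getLogger("costim")


class FormatError(ValueError):
    """Malformed input file; message carries the offending line/cell."""


class ReconciliationError(ValueError):
    """Two inputs that must agree (e.g. counts vs design sheet) do not."""


# the seven-condition stimulation grid: (tcr_dose, cd28_dose) -> label
CONDITION_GRID = {
    (0, 0): "resting",
    (1, 1): "lowTCR_lowCD28",
    (1, 2): "lowTCR_highCD28",
    (2, 1): "highTCR_lowCD28",
    (2, 2): "highTCR_highCD28",
    (2, 0): "highTCR",
    (0, 2): "highCD28",
}
STIMULATED_CONDITIONS = [c for c in CONDITION_GRID.values() if c != "resting"]
CELL_TYPES = ("naive", "memory")
STIMULI = ("TCR", "CD28")

# chromosomes excluded by the autosome+X gene filter
_EXCLUDED_CHROMS = {"Y", "chrY", "M", "MT", "chrM", "chrMT"}


def condition_label(tcr_dose: int, cd28_dose: int) -> str:
    try:
        return CONDITION_GRID[(int(tcr_dose), int(cd28_dose))]
    except KeyError:
        raise ValueError(f"({tcr_dose},{cd28_dose}) is not one of the 7 grid conditions")


@dataclass
class RunConfig:
    """Thresholds, priors and conventions for a pipeline run.

    Fold-change thresholds are on the natural (not log) scale.  The two
    prior variances are the log2-scale normal prior widths used for
    optional LFC shrinkage and for dispersion shrinkage toward the
    mean-dispersion trend.
    """

    de_fc: float = 2.0
    de_fdr: float = 0.05
    linear_fc: float = 1.5
    switch_fc: float = 2.0
    ld_r2: float = 0.8
    locus_extend: int = 150_000
    gwas_p: float = 5e-8
    n_perm_gwas: int = 10_000
    n_perm_gsea: int = 10_000
    window_flank: int = 150_000
    beta_prior_var: float = 0.661
    dispersion_prior_var: float = 0.761
    alpha_min: float = 1e-8
    alpha_max: float = 10.0
    pwm_pseudocount: float = 1.0
    pwm_background: tuple = (0.25, 0.25, 0.25, 0.25)
    pwm_hit_frac: float = 0.8
    pwm_delta_min: float = 1.0
    ld_search_radius: int = 1_000_000
    mhc_chrom: str = "chr6"
    mhc_start: int = 25_000_000
    mhc_end: int = 34_000_000
    gene_table_one_based: bool = False
    allow_custom_grid: bool = False
    both_resolution: str = "exclude"  # or "effect_size"
    window_flank_per_side: bool = True
    coverage_pseudo_reads: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    seed: int = 0

    def __post_init__(self):
        for name in ("de_fc", "linear_fc", "switch_fc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("de_fdr", "ld_r2", "gwas_p", "locus_extend", "n_perm_gwas",
                     "window_flank", "beta_prior_var", "dispersion_prior_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.both_resolution not in ("exclude", "effect_size"):
            raise ValueError("both_resolution must be 'exclude' or 'effect_size'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pwm_background" in raw:
            raw["pwm_background"] = tuple(raw["pwm_background"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pwm_background"] = list(d["pwm_background"])
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# counts + design


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise FormatError(f"{path}: no genes")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    body = df.drop(columns=gene_col)
    out = {}
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}: non-integer or negative count {body[col].iloc[i]!r} "
                f"at gene {genes.iloc[i]!r}, sample {col!r}"
            )
        out[col] = vals.astype(np.int64)
    counts = pd.DataFrame(out)
    counts.index = pd.Index(genes, name="gene_id")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


_DESIGN_COLS = ["sample_id", "cell_type", "tcr_dose", "cd28_dose", "donor", "batch"]


def validate_design(design: pd.DataFrame, allow_custom_grid: bool = False) -> pd.DataFrame:
    missing = [c for c in _DESIGN_COLS if c not in design.columns]
    if missing:
        raise FormatError(f"design sheet missing columns {missing}")
    design = design.copy()
    if design["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design sheet")
    bad_ct = set(design["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise FormatError(f"unknown cell_type values {sorted(bad_ct)}")
    design["tcr_dose"] = design["tcr_dose"].astype(int)
    design["cd28_dose"] = design["cd28_dose"].astype(int)
    combos = set(zip(design["tcr_dose"], design["cd28_dose"]))
    if not allow_custom_grid:
        off = combos - set(CONDITION_GRID)
        if off:
            raise FormatError(f"dose combinations outside the 7-condition grid: {sorted(off)}")
        design["condition"] = [
            CONDITION_GRID[(t, c)] for t, c in zip(design["tcr_dose"], design["cd28_dose"])
        ]
    else:
        design["condition"] = [
            CONDITION_GRID.get((t, c), f"tcr{t}_cd28{c}")
            for t, c in zip(design["tcr_dose"], design["cd28_dose"])
        ]
    return design.set_index("sample_id", drop=False)


def read_design(path, allow_custom_grid: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return validate_design(df, allow_custom_grid)


def write_design(design: pd.DataFrame, path) -> None:
    design[_DESIGN_COLS].to_csv(path, sep="\t", index=False)


def reconcile(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    """Counts columns and design sample ids must coincide."""
    c, d = set(counts.columns), set(design["sample_id"])
    if c != d:
        raise ReconciliationError(
            f"samples differ between counts and design: "
            f"counts-only={sorted(c - d)[:5]}, design-only={sorted(d - c)[:5]}"
        )


# ---------------------------------------------------------------------------
# gene annotation


def read_annotation(path, one_based: bool = False) -> pd.DataFrame:
    """Gene table (gene_id, chrom, start, end, strand); adds length.

    ``one_based`` declares the source convention; coordinates are converted
    to 0-based half-open on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    need = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in annotation")
    df = df.copy()
    df["start"] = df["start"].astype(int) - (1 if one_based else 0)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
        raise FormatError(f"{path}: start >= end for gene {bad}")
    df["length"] = df["end"] - df["start"]
    return df.set_index("gene_id", drop=False)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["gene_id", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


def autosome_or_x(chrom: pd.Series) -> pd.Series:
    return ~chrom.isin(_EXCLUDED_CHROMS)


# ---------------------------------------------------------------------------
# peaks (BED3 / narrowPeak)


def read_peaks(path) -> pd.DataFrame:
    """Read BED3+ / narrowPeak into a sorted half-open peak table.

    narrowPeak signalValue (column 7) becomes ``score``; plain BED gets 0.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{lineno}"
            score = float(f[6]) if len(f) >= 7 else 0.0
            rows.append((chrom, start, end, name, score))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return peaks.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_peaks(peaks: pd.DataFrame, path) -> None:
    """Write narrowPeak-style BED (score in signalValue column 7)."""
    with open(path, "w") as fh:
        for r in peaks.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t{r.score:g}\n")


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style count matrices)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class Pwm:
    """Position count matrix with a log-odds view.

    ``counts`` is 4 x L in row order A,C,G,T.  Log-odds use pseudocount
    ``epsilon`` per cell: log2(((c+eps)/(colsum+4 eps)) / background).
    """

    name: str
    counts: np.ndarray
    epsilon: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise FormatError(f"PWM {self.name}: need 4 rows (A,C,G,T)")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0, keepdims=True)
        probs = (self.counts + self.epsilon) / (col_tot + 4 * self.epsilon)
        return np.log2(probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name, self.counts[::-1, ::-1], self.epsilon, self.background[::-1])


def read_pwms(path, epsilon: float = 1.0, background=(0.25, 0.25, 0.25, 0.25)) -> list:
    """Read JASPAR .pfm motifs: '>' header then 4 rows A/C/G/T of counts."""
    bg = np.asarray(background, dtype=float)
    motifs, name, rows = [], None, []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise FormatError(f"{path}: motif {name}: expected 4 rows, got {len(rows)}")
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise FormatError(f"{path}: motif {name}: ragged rows {sorted(lens)}")
        motifs.append(Pwm(name, np.array(rows), epsilon, bg))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
                continue
            body = line
            if body[0] in _BASES and not body[0].isdigit():
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(x) for x in body.split()])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unparseable PWM row")
    flush()
    return motifs


# ---------------------------------------------------------------------------
# SNP table, dosage panel, FASTA, GMT


def read_snp_table(path) -> pd.DataFrame:
    """GWAS index-SNP TSV (trait, rsid, chrom, pos, ref, alt, pvalue).

    Positions are 1-based in the file and converted to 0-based here.
    Multi-allelic rows (comma-separated alt) are split into biallelic
    records.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    need = ["trait", "rsid", "chrom", "pos", "ref", "alt", "pvalue"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: SNP table missing columns {missing}")
    df = df.assign(alt=df["alt"].str.split(",")).explode("alt", ignore_index=True)
    bad = (df["ref"].str.len() != 1) | (df["alt"].str.len() != 1)
    if bad.any():
        raise FormatError(f"{path}: non single-base allele at rsid {df.loc[bad, 'rsid'].iloc[0]}")
    if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
        raise FormatError(f"{path}: p-value outside (0,1]")
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_snp_table(snps: pd.DataFrame, path) -> None:
    out = snps.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out[["trait", "rsid", "chrom", "pos", "ref", "alt", "pvalue"]].to_csv(
        path, sep="\t", index=False
    )


def read_dosage_panel(path) -> pd.DataFrame:
    """Samples x SNPs dosage TSV with values in {0,1,2}."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    vals = df.to_numpy()
    if not np.isin(vals, [0, 1, 2]).all():
        raise FormatError(f"{path}: dosages must be 0/1/2")
    return df.astype(np.int8)


def write_dosage_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index_label="sample_id")


def read_variant_table(path) -> pd.DataFrame:
    """Panel-variant coordinates (snp_id, chrom, pos; 0-based TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    need = ["snp_id", "chrom", "pos"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: variant table missing columns {missing}")
    return df.set_index("snp_id", drop=False)


def write_variant_table(variants: pd.DataFrame, path) -> None:
    variants[["snp_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    from Bio import SeqIO

    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_gmt(path) -> dict:
    """Hallmark-style GMT: name <tab> description <tab> gene1 <tab> ..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[f[0]] = set(g for g in f[2:] if g)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# result tables


def write_results(df: pd.DataFrame, path, config: RunConfig | None = None,
                  seed: int | None = None, index: bool = False) -> None:
    """Write a results TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# costim {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config: {config.hash()}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def setup_logging(level=logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


__all__ = [
    "RunConfig", "FormatError", "ReconciliationError", "Pwm",
    "CONDITION_GRID", "STIMULATED_CONDITIONS", "CELL_TYPES", "STIMULI",
    "condition_label", "read_counts", "write_counts", "read_design",
    "write_design", "validate_design", "reconcile", "read_annotation",
    "write_annotation", "autosome_or_x", "read_peaks", "write_peaks",
    "read_pwms", "read_snp_table", "write_snp_table", "read_dosage_panel",
    "write_dosage_panel", "read_variant_table", "write_variant_table",
    "read_fasta", "write_fasta", "read_gmt", "write_gmt", "write_results",
    "setup_logging",
]
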