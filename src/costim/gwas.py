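"""GWAS disease-locus construction and matched-gene permutation enrichment.

Disease loci are built per trait from genome-wide significant index SNPs
(p < 5e-8, MHC excluded) by LD expansion: panel SNPs on the same
chromosome within a search radius with r^2 > 0.8 define the LD span,
which is extended 150 kb on each side and merged with overlapping loci of
the same trait.  Stimulus-sensitive gene sets are then tested for locus
overlap against a null of gene sets matched on gene length and mean
expression (quintile x quintile bins), with an add-one one-sided
permutation p-value.  Locus SNPs are annotated with chromatin-peak
overlap and PWM allele-disruption scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Pwm
from .chromatin import best_scores_over_position

logger = logging.getLogger("costim.gwas")

MHC_DEFAULT = ("chr6", 25_000_000, 34_000_000)


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors (NaN if constant)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.size < 3:
        raise ValueError("dosage vectors must have equal length >= 3")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return float("nan")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def _merge_intervals(iv: list) -> list:
    """Merge overlapping/touching half-open (start, end) tuples."""
    out = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_loci(index_snps: pd.DataFrame, panel: pd.DataFrame,
               variants: pd.DataFrame, r2_min: float = 0.8,
               extend: int = 150_000, p_max: float = 5e-8,
               mhc_interval: tuple = MHC_DEFAULT, search_radius: int = 1_000_000,
               chrom_sizes: dict | None = None) -> pd.DataFrame:
    """LD-expanded, extended and per-trait-merged disease loci.

    Index SNPs absent from the panel become singleton loci (their own
    position, still extended).  Returns one row per merged locus with the
    member SNP ids that defined it.
    """
    mhc_chrom, mhc_s, mhc_e = mhc_interval
    snps = index_snps[index_snps["pvalue"] < p_max].copy()
    in_mhc = (snps["chrom"] == mhc_chrom) & (snps["pos"] >= mhc_s) & (snps["pos"] < mhc_e)
    if in_mhc.any():
        logger.info("excluding %d index SNPs inside the MHC interval", int(in_mhc.sum()))
    snps = snps[~in_mhc]
    if snps.empty:
        raise ValueError("no index SNPs left after p-value and MHC filters")

    raw = []  # (trait, chrom, start, end, member snp ids, index rsid)
    for row in snps.itertuples(index=False):
        members = [row.rsid]
        positions = [row.pos]
        if row.rsid in panel.columns:
            g_idx = panel[row.rsid].to_numpy()
            near = variants[
                (variants["chrom"] == row.chrom)
                & (variants["pos"] >= row.pos - search_radius)
                & (variants["pos"] <= row.pos + search_radius)
            ]
            for v in near.itertuples(index=False):
                if v.snp_id == row.rsid or v.snp_id not in panel.columns:
                    continue
                r2 = ld_r2(g_idx, panel[v.snp_id].to_numpy())
                if np.isfinite(r2) and r2 > r2_min:
                    members.append(v.snp_id)
                    positions.append(v.pos)
        else:
            logger.warning("index SNP %s not in panel; singleton locus", row.rsid)
        start = min(positions) - extend
        end = max(positions) + 1 + extend
        start = max(0, start)
        if chrom_sizes and row.chrom in chrom_sizes:
            end = min(end, chrom_sizes[row.chrom])
        raw.append((row.trait, row.chrom, start, end, members, row.rsid))

    rows = []
    df = pd.DataFrame(raw, columns=["trait", "chrom", "start", "end", "members", "index"])
    for (trait, chrom), grp in df.groupby(["trait", "chrom"], sort=True):
        grp = grp.sort_values("start", kind="stable")
        cur = None
        for r in grp.itertuples(index=False):
            if cur is not None and r.start <= cur["end"]:
                cur["end"] = max(cur["end"], r.end)
                cur["members"] += r.members
                cur["index_snps"].append(r.index)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"trait": trait, "chrom": chrom, "start": r.start,
                       "end": r.end, "members": list(r.members),
                       "index_snps": [r.index]}
        if cur is not None:
            rows.append(cur)
    loci = pd.DataFrame(rows, columns=["trait", "chrom", "start", "end",
                                       "members", "index_snps"])
    loci.insert(0, "locus_id", [f"{r.trait}_L{i + 1}" for i, r in
                                enumerate(loci.itertuples(index=False))])
    return loci


def loci_to_bed(loci: pd.DataFrame) -> pd.DataFrame:
    return loci[["chrom", "start", "end", "trait"]].rename(columns={"trait": "name"})


def genes_in_loci(annotation: pd.DataFrame, loci: pd.DataFrame) -> pd.Series:
    """True where the gene body intersects any locus (half-open overlap)."""
    hit = pd.Series(False, index=annotation.index)
    for chrom, grp in loci.groupby("chrom"):
        sub = annotation[annotation["chrom"] == chrom]
        if sub.empty:
            continue
        s = sub["start"].to_numpy()[:, None]
        e = sub["end"].to_numpy()[:, None]
        ls = grp["start"].to_numpy()[None, :]
        le = grp["end"].to_numpy()[None, :]
        hit.loc[sub.index] |= ((s < le) & (ls < e)).any(axis=1)
    return hit


def assign_match_bins(annotation: pd.DataFrame, mean_expression: pd.Series,
                      n_size_bins: int = 5, n_expr_bins: int = 5) -> pd.Series:
    """(gene-length quintile, expression quintile) matching bins.

    Universes below 25 genes coarsen to fewer bins so every bin can still
    be drawn from.
    """
    universe = annotation.index
    if mean_expression.reindex(universe).isna().any():
        raise ValueError("mean expression missing for some universe genes")
    if len(universe) < n_size_bins * n_expr_bins:
        n_size_bins = n_expr_bins = max(1, int(np.sqrt(len(universe) // 2)) or 1)
        logger.warning("small universe: coarsening match bins to %dx%d",
                       n_size_bins, n_expr_bins)
    size_bin = pd.qcut(annotation["length"].rank(method="first"), n_size_bins,
                       labels=False)
    expr_bin = pd.qcut(mean_expression.reindex(universe).rank(method="first"),
                       n_expr_bins, labels=False)
    return (size_bin.astype(str) + "_" + expr_bin.astype(str)).rename("bin")


@dataclass
class PermEnrichResult:
    gene_set: str
    trait: str
    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_perm: int


def permutation_enrichment(query, loci: pd.DataFrame, universe,
                           bins: pd.Series, annotation: pd.DataFrame,
                           n_perm: int = 10_000, seed: int = 0,
                           gene_set_name: str = "query",
                           trait: str = "all") -> PermEnrichResult:
    """Matched-gene permutation test of locus overlap (one-sided, add-one).

    Each draw resamples, within every matching bin, the same number of
    universe genes as the query holds there; the null statistic is the
    count of drawn genes whose body intersects any locus.
    """
    query = sorted(set(query))
    universe = pd.Index(sorted(set(universe)))
    if not set(query) <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    if loci.empty:
        raise ValueError("no loci to test against")
    rng = np.random.default_rng(seed)
    in_locus = genes_in_loci(annotation.loc[universe], loci)
    observed = int(in_locus.loc[query].sum())

    bin_of = bins.reindex(universe)
    null = np.zeros(n_perm, dtype=np.int64)
    for b, q_genes in pd.Series(query).groupby(bin_of.loc[query].to_numpy()):
        k = len(q_genes)
        pool = in_locus[bin_of == b].to_numpy()
        if k > pool.size:
            raise ValueError(f"bin {b} has {pool.size} universe genes but {k} query genes")
        for i in range(n_perm):
            null[i] += pool[rng.choice(pool.size, k, replace=False)].sum()
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermEnrichResult(gene_set_name, trait, observed,
                            float(null.mean()), float(null.std()), float(p), n_perm)


def driver_genes(query, loci: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Query genes intersecting each trait's loci, with the locus id."""
    rows = []
    sub = annotation.loc[sorted(set(query) & set(annotation.index))]
    for loc in loci.itertuples(index=False):
        g = sub[(sub["chrom"] == loc.chrom) & (sub["start"] < loc.end)
                & (loc.start < sub["end"])]
        for gid in g.index:
            rows.append({"trait": loc.trait, "locus_id": loc.locus_id, "gene_id": gid})
    return pd.DataFrame(rows, columns=["trait", "locus_id", "gene_id"])


def snp_peak_overlap(drivers: pd.DataFrame, loci: pd.DataFrame,
                     snp_positions: pd.DataFrame, peaks: pd.DataFrame,
                     annotation: pd.DataFrame, flank: int = 150_000):
    """Per driver gene: does >= 1 locus SNP fall inside a peak in its window?

    ``snp_positions`` maps snp_id -> (chrom, pos); peak overlap uses the
    half-open convention (start inclusive, end exclusive).  Returns the
    per-gene indicator table and the summary fraction.
    """
    loc_by_id = loci.set_index("locus_id")
    rows = []
    for r in drivers.itertuples(index=False):
        g = annotation.loc[r.gene_id]
        w_start, w_end = max(0, g["start"] - flank), g["end"] + flank
        found = False
        for snp_id in loc_by_id.loc[r.locus_id, "members"]:
            if snp_id not in snp_positions.index:
                continue
            v = snp_positions.loc[snp_id]
            if not (v["chrom"] == g["chrom"] and w_start <= v["pos"] < w_end):
                continue
            cand = peaks[(peaks["chrom"] == v["chrom"]) & (peaks["start"] <= v["pos"])
                         & (v["pos"] < peaks["end"])]
            if len(cand):
                found = True
                break
        rows.append({"gene_id": r.gene_id, "trait": r.trait,
                     "locus_id": r.locus_id, "snp_in_peak": found})
    table = pd.DataFrame(rows, columns=["gene_id", "trait", "locus_id", "snp_in_peak"])
    frac = float(table["snp_in_peak"].mean()) if len(table) else 0.0
    return table, frac


@dataclass
class TfbsDisruption:
    snp_id: str
    pwm: str
    ref_score: float
    alt_score: float
    delta: float
    disrupting: bool
    flag: str  # 'ok' or 'ref_mismatch'


def tfbs_disruption(snp: pd.Series, pwm: Pwm, window_seq: str, window_start: int,
                    hit_frac: float = 0.8, delta_min: float = 1.0) -> TfbsDisruption:
    """Allele-specific PWM disruption score at a SNP.

    For each allele the best log-odds over all motif placements (both
    strands) covering the SNP; disrupting iff max(ref, alt) reaches
    ``hit_frac`` of the motif's maximal score and |alt - ref| >=
    ``delta_min`` bits.
    """
    off = int(snp["pos"]) - int(window_start)
    L = pwm.length
    if off < 0 or off >= len(window_seq):
        raise ValueError("SNP outside the provided sequence window")
    if off < L - 1 or off > len(window_seq) - L:
        raise ValueError("window too short: need pos +/- (motif length - 1)")
    if window_seq[off] != snp["ref"]:
        logger.warning("reference allele mismatch for %s; skipping", snp["rsid"])
        return TfbsDisruption(snp["rsid"], pwm.name, np.nan, np.nan, np.nan,
                              False, "ref_mismatch")
    region = window_seq[off - (L - 1): off + L]
    alt_region = region[: L - 1] + snp["alt"] + region[L:]
    ref_best = best_scores_over_position(region, pwm)
    alt_best = best_scores_over_position(alt_region, pwm)
    delta = alt_best - ref_best
    disrupting = max(ref_best, alt_best) >= hit_frac * pwm.max_score \
        and abs(delta) >= delta_min
    return TfbsDisruption(snp["rsid"], pwm.name, ref_best, alt_best,
                          float(delta), bool(disrupting), "ok")
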