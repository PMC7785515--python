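"""Post-peak-call chromatin analytics.

Gene windows are the gene body flanked by 150 kb on each side (half-open,
clipped at chromosome bounds).  Window read-mass enrichment between a
stimulated and the resting state is the per-gene log2 ratio of
library-normalised coverage (with one pseudo-read added before
normalisation) tested against zero with a paired t-test.  Motif content
of peaks near stimulus-sensitive genes is compared with peaks near
non-differentially-expressed genes via a one-sided binomial test per PWM;
peak-set QC reports FRiP, the fraction of peaks with signal above 10 and
paired peak-count comparisons between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Pwm, _COMPLEMENT

logger = logging.getLogger("costim.chromatin")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def gene_window(gene: pd.Series, flank: int = 150_000,
                chrom_sizes: dict | None = None) -> tuple:
    """[start - flank, end + flank) clipped to [0, chromosome length)."""
    start = max(0, int(gene["start"]) - flank)
    end = int(gene["end"]) + flank
    if chrom_sizes and gene["chrom"] in chrom_sizes:
        end = min(end, chrom_sizes[gene["chrom"]])
    return gene["chrom"], start, end


def build_windows(annotation: pd.DataFrame, flank: int = 150_000,
                  chrom_sizes: dict | None = None) -> pd.DataFrame:
    rows = [gene_window(g, flank, chrom_sizes) for _, g in annotation.iterrows()]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"],
                        index=annotation.index)


def coverage_enrichment(mass_stim: pd.Series, total_stim: float,
                        mass_rest: pd.Series, total_rest: float,
                        gene_set=None, pseudo_reads: float = 1.0):
    """Per-gene log2 coverage ratio (stimulated/resting) and a paired t-test.

    Coverage = (mass + pseudo_reads) / library total.  The t-test is a
    one-sample test of the log-ratios against 0 across the gene set,
    skipped (p = NaN) below 3 genes.
    """
    genes = list(gene_set) if gene_set is not None else list(mass_stim.index)
    ms = mass_stim.reindex(genes).astype(float)
    mr = mass_rest.reindex(genes).astype(float)
    if ms.isna().any() or mr.isna().any():
        raise ValueError("coverage missing for some genes in the set")
    cov_s = (ms + pseudo_reads) / float(total_stim)
    cov_r = (mr + pseudo_reads) / float(total_rest)
    ratios = np.log2(cov_s / cov_r).rename("log2_ratio")
    if len(genes) >= 3:
        t, p = stats.ttest_1samp(ratios.to_numpy(), 0.0)
        t, p = float(t), float(p)
    else:
        logger.warning("gene set < 3: t-test skipped")
        t, p = float("nan"), float("nan")
    return ratios, t, p


# ---------------------------------------------------------------------------
# PWM scanning


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> 4."""
    return np.array([_BASE_INDEX.get(c, 4) for c in str(seq).upper()], dtype=np.int64)


@dataclass
class MotifHit:
    pos: int      # 0-based start on the forward strand
    strand: str
    score: float


def _scores_one_strand(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every placement; ambiguous bases contribute 0 log-odds."""
    L = log_odds.shape[1]
    lut = np.vstack([log_odds, np.zeros((1, L))])  # row 4 = N
    win = np.lib.stride_tricks.sliding_window_view(enc, L)
    return lut[win, np.arange(L)].sum(axis=1)


def scan_pwm(seq: str, pwm: Pwm, threshold_frac: float = 0.8) -> list:
    """Motif hits on both strands at >= threshold_frac of the maximal score.

    Minus-strand hits are reported at their forward-strand start
    coordinate.
    """
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    enc = _encode(seq)
    thr = threshold_frac * pwm.max_score
    hits = []
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        scores = _scores_one_strand(enc, lo)
        for pos in np.nonzero(scores >= thr)[0]:
            hits.append(MotifHit(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def best_scores_over_position(seq: str, pwm: Pwm) -> float:
    """Max log-odds over every placement in ``seq``, both strands."""
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    enc = _encode(seq)
    best = -np.inf
    for lo in (pwm.log_odds, pwm.reverse_complement().log_odds):
        best = max(best, float(_scores_one_strand(enc, lo).max()))
    return best


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# motif enrichment and peak selection


def motif_enrichment(fg_seqs: dict, bg_seqs: dict, pwms: list,
                     threshold_frac: float = 0.8) -> pd.DataFrame:
    """One-sided binomial test of motif presence in foreground peaks.

    A peak "has" a motif if it contains >= 1 hit.  The background hit
    rate is treated as known; a zero background rate with foreground hits
    is floored at 1/(2 |bg|).
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background peak sets must be non-empty")
    if set(fg_seqs) & set(bg_seqs):
        raise ValueError("foreground and background peak ids overlap")
    rows = []
    for pwm in pwms:
        fg_hits = sum(1 for s in fg_seqs.values() if scan_pwm(s, pwm, threshold_frac))
        bg_hits = sum(1 for s in bg_seqs.values() if scan_pwm(s, pwm, threshold_frac))
        bg_rate = bg_hits / len(bg_seqs)
        if bg_rate == 0 and fg_hits > 0:
            bg_rate = 1.0 / (2.0 * len(bg_seqs))
        if bg_rate == 0:
            p = 1.0
        else:
            p = float(stats.binomtest(fg_hits, len(fg_seqs), min(bg_rate, 1.0),
                                      alternative="greater").pvalue)
        rows.append({"motif": pwm.name, "fg_hits": fg_hits, "fg_n": len(fg_seqs),
                     "bg_hits": bg_hits, "bg_n": len(bg_seqs),
                     "fg_rate": fg_hits / len(fg_seqs), "bg_rate": bg_hits / len(bg_seqs),
                     "p": p})
    res = pd.DataFrame(rows)
    from .expression import bh_adjust

    res["q"] = bh_adjust(res["p"].to_numpy())
    return res.set_index("motif", drop=False)


def _peaks_in_windows(peaks: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(peaks), dtype=bool)
    for chrom, w in windows.groupby("chrom"):
        m = (peaks["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        ps = peaks.loc[m, "start"].to_numpy()[:, None]
        pe = peaks.loc[m, "end"].to_numpy()[:, None]
        ws = w["start"].to_numpy()[None, :]
        we = w["end"].to_numpy()[None, :]
        hit[m] |= ((ps < we) & (ws < pe)).any(axis=1)
    return hit


def select_fg_bg_peaks(peaks: pd.DataFrame, windows_sensitive: pd.DataFrame,
                       windows_non_de: pd.DataFrame):
    """Foreground = peaks in sensitive-gene windows; background = peaks in
    non-DE-gene windows not already foreground (foreground precedence)."""
    fg_mask = _peaks_in_windows(peaks, windows_sensitive)
    if not fg_mask.any():
        raise ValueError("no peaks intersect the sensitive-gene windows")
    bg_mask = _peaks_in_windows(peaks, windows_non_de) & ~fg_mask
    return peaks[fg_mask].reset_index(drop=True), peaks[bg_mask].reset_index(drop=True)


def top_peaks(peaks: pd.DataFrame, n: int) -> pd.DataFrame:
    """Score-ranked truncation to the n most significant peaks."""
    return peaks.sort_values("score", ascending=False, kind="stable").head(n) \
        .sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# QC


def frip(peaks: pd.DataFrame, reads: pd.DataFrame) -> float:
    """Fraction of reads whose interval overlaps any peak."""
    if len(reads) == 0:
        raise ValueError("zero reads")
    hit = np.zeros(len(reads), dtype=bool)
    for chrom, pk in peaks.groupby("chrom"):
        m = (reads["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        rs = reads.loc[m, "start"].to_numpy()[:, None]
        re_ = reads.loc[m, "end"].to_numpy()[:, None]
        ps = pk["start"].to_numpy()[None, :]
        pe = pk["end"].to_numpy()[None, :]
        hit[m] |= ((rs < pe) & (ps < re_)).any(axis=1)
    return float(hit.mean())


def peak_qc_stats(peaks_by_sample: dict, reads_by_sample: dict,
                  signal_threshold: float = 10.0) -> pd.DataFrame:
    """Per-sample peak QC: n_peaks, FRiP, fraction of peaks with score > 10."""
    rows = []
    for sample in sorted(peaks_by_sample):
        pk = peaks_by_sample[sample]
        rows.append({
            "sample": sample,
            "n_peaks": len(pk),
            "frip": frip(pk, reads_by_sample[sample]),
            "frac_signal_gt_10": float((pk["score"] > signal_threshold).mean())
            if len(pk) else float("nan"),
        })
    return pd.DataFrame(rows).set_index("sample", drop=False)


def compare_peak_counts(counts_a, counts_b):
    """Relative peak-count excess (a-b)/b per matched pair, with paired t.

    Returns (mean relative difference, t statistic, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("groups must be matched, non-empty")
    rel = (a - b) / b
    if a.size >= 2:
        t, p = stats.ttest_rel(a, b)
        t, p = float(t), float(p)
    else:
        t, p = float("nan"), float("nan")
    return float(rel.mean()), t, p
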