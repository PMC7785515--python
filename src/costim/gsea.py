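"""Preranked gene-set enrichment on the linear-model fold-change ranking.

The statistic is the standard weighted Kolmogorov-Smirnov running sum:
walking down the ranking, hits add ``|stat|^p / sum_set |stat|^p`` and
misses subtract ``1/(N - |set|)``; the enrichment score (ES) is the
signed extremum and the leading edge is the hit prefix up to it.
Significance comes from a gene-label permutation null (random sets of
matched size), with NES = ES / mean |same-sign null ES| and BH correction
across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import bh_adjust

logger = logging.getLogger("costim.gsea")


def make_ranking(stat: pd.Series) -> pd.Series:
    """Sort descending by statistic, ties broken by gene id (stable)."""
    if stat.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    df = stat.rename("stat").rename_axis("gene").reset_index()
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    return df.set_index("gene")["stat"]


def enrichment_score(ranking: pd.Series, gene_set, weight: float = 1.0):
    """ES, running sum and leading-edge genes for one set.

    ``ranking`` must be sorted descending.  Requires
    0 < |set intersect ranking| < N.
    """
    genes = ranking.index
    hit = np.asarray(genes.isin(set(gene_set)))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("set not represented in the ranking")
    if n_hit == len(genes):
        raise ValueError("set covers the entire ranking")
    w = np.abs(ranking.to_numpy(dtype=float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit.astype(float)  # all-zero stats: unweighted fallback
        denom = hit_w.sum()
    inc = hit_w / denom
    dec = (~hit).astype(float) / (len(genes) - n_hit)
    running = np.cumsum(inc - dec)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext + 1:], hit[i_ext + 1:]) if h]
    return es, running, leading


def _es_only(w: np.ndarray, hit_idx: np.ndarray, N: int) -> float:
    """ES from hit positions only (O(|S|) after the shared |stat|^p array)."""
    m = hit_idx.size
    hw = w[hit_idx]
    denom = hw.sum()
    if denom == 0:
        gains = np.arange(1, m + 1) / m
    else:
        gains = np.cumsum(hw) / denom
    dec = 1.0 / (N - m)
    # the path rises only at hits: maxima sit just after a hit, minima just
    # before a hit or at the end of the ranking
    after = gains - (hit_idx - np.arange(m)) * dec
    before = np.concatenate([[0.0], gains[:-1]]) - (hit_idx - np.arange(m)) * dec
    end_val = gains[-1] - (N - m) * dec  # == 0 up to float error
    lo = min(before.min(), end_val)
    hi = after.max()
    return float(hi if hi >= -lo else lo)


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list


def gsea_test(ranking: pd.Series, sets: dict, n_perm: int = 10_000, seed: int = 0,
              weight: float = 1.0, min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Permutation preranked GSEA over a dict of gene sets.

    p = (1 + #{same-sign null with |ES| >= |ES_obs|}) / (1 + n_perm); the
    null reuses one pool of ``n_perm`` random sets per distinct set size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranking = make_ranking(ranking)
    N = len(ranking)
    w = np.abs(ranking.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)

    obs = {}
    for name in sorted(sets):
        members = set(sets[name]) & set(ranking.index)
        m = len(members)
        if m < min_size or m > max_size:
            logger.warning("skipping set %s (size %d outside [%d, %d])",
                           name, m, min_size, max_size)
            continue
        es, _, leading = enrichment_score(ranking, members, weight)
        obs[name] = (m, es, leading)

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name in sorted(obs):
        m, es, leading = obs[name]
        if m not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                idx = np.sort(rng.choice(N, m, replace=False))
                null[b] = _es_only(w, idx, N)
            null_cache[m] = null
        null = null_cache[m]
        same = null >= 0 if es >= 0 else null < 0
        # normalise within the same-sign side of the null, as fgsea does;
        # normalising by all permutations would halve p under the null
        p = (1.0 + np.sum(same & (np.abs(null) >= abs(es)))) / (1.0 + np.sum(same))
        mean_abs = np.abs(null[same]).mean() if same.any() else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        rows.append({"name": name, "size": m, "es": es, "nes": nes, "p": p,
                     "leading_edge": ",".join(leading)})
    res = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p", "leading_edge"])
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
        res = res[["name", "size", "es", "nes", "p", "q", "leading_edge"]]
    return res.set_index("name", drop=False)
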