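"""Classification of activation-upregulated genes as TCR- or CD28-sensitive.

For each cell type, genes upregulated in any stimulated-vs-resting
contrast (FC >= 2, BH FDR <= 5%) are tested per stimulus under two nested
negative-binomial models against a reduced intercept+batch model:

* **linear** — expression grows with stimulus dose (numeric 0/1/2
  covariate); pass requires BH q <= 0.05 and per-increment fold-change
  >= 1.5 with a positive coefficient.
* **switch** — on/off response to stimulus presence (indicator dose > 0);
  only genes failing the linear model are tested (linear priority); pass
  requires q <= 0.05 and fold-change >= 2.

When testing one stimulus, all seven grid conditions are used and samples
without that stimulus (resting and the other-stimulus-alone condition)
share dose 0, so the other signal is absorbed by the intercept.  A gene
passing both stimuli is labelled "both" and by default excluded from the
unique-sensitivity set; switcher genes are those uniquely sensitive to
different stimuli in the two cell subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import expression as expr
from .io import RunConfig, STIMULATED_CONDITIONS, STIMULI

logger = logging.getLogger("costim.classify")

LN2 = np.log(2.0)


def dose_vector(design: pd.DataFrame, stimulus: str) -> pd.Series:
    """Per-sample ordinal dose of the stimulus under test (0/1/2)."""
    if stimulus not in STIMULI:
        raise ValueError(f"stimulus must be one of {STIMULI}")
    col = "tcr_dose" if stimulus == "TCR" else "cd28_dose"
    return design[col].astype(int).rename("dose")


def upregulated_gene_set(de_results: dict, de_fc: float = 2.0,
                         de_fdr: float = 0.05) -> set:
    """Union of genes upregulated in >= 1 stimulated-vs-resting contrast."""
    missing = [c for c in STIMULATED_CONDITIONS if c not in de_results]
    if missing:
        raise ValueError(f"missing DE contrast(s) vs resting: {missing}")
    out: set = set()
    for cond in STIMULATED_CONDITIONS:
        res = de_results[cond]
        hit = (res["log2fc"] >= np.log2(de_fc)) & (res["q"] <= de_fdr)
        out |= set(res.index[hit.fillna(False)])
    return out


def _stage_lrt(counts: pd.DataFrame, X_full, X_red, s, alphas: pd.Series,
               reduced_ll: dict) -> pd.DataFrame:
    """Per-gene LRT of X_full vs X_red; caches reduced-model logliks."""
    mat = counts.to_numpy(dtype=float)
    betas = np.empty(mat.shape[0])
    stats_ = np.empty(mat.shape[0])
    for g, gid in enumerate(counts.index):
        a = float(alphas.loc[gid])
        full = expr.fit_nb_glm(mat[g], X_full, s, a)
        if gid not in reduced_ll:
            reduced_ll[gid] = expr.fit_nb_glm(mat[g], X_red, s, a).loglik
        betas[g] = full.beta[1]
        stats_[g] = max(0.0, 2.0 * (full.loglik - reduced_ll[gid]))
    p = stats.chi2.sf(stats_, 1)
    return pd.DataFrame({"beta": betas, "stat": stats_, "p": p}, index=counts.index)


def test_linear(counts: pd.DataFrame, design: pd.DataFrame, size_factors: pd.Series,
                alphas: pd.Series, genes, stimulus: str, linear_fc: float = 1.5,
                fdr: float = 0.05, _reduced_ll: dict | None = None) -> pd.DataFrame:
    """Dose-linear model for one cell type's samples.

    Returns per-gene (effect_log2 per dose increment, p, q, passed).
    """
    genes = [g for g in counts.index if g in set(genes)]
    if not genes:
        return pd.DataFrame(columns=["effect_log2", "p", "q", "passed"])
    dose = dose_vector(design, stimulus)
    if dose.nunique() < 2:
        raise ValueError(f"dose for {stimulus} has < 2 distinct values")
    X_full, _ = expr.build_design_matrix(design, covariate=dose.astype(float))
    X_red, _ = expr.build_design_matrix(design)
    s = size_factors.loc[design.index].to_numpy()
    res = _stage_lrt(counts.loc[genes, design.index], X_full, X_red, s, alphas,
                     {} if _reduced_ll is None else _reduced_ll)
    out = pd.DataFrame(index=res.index)
    out["effect_log2"] = res["beta"] / LN2
    out["p"] = res["p"]
    out["q"] = expr.bh_adjust(res["p"].to_numpy())
    out["passed"] = (out["q"] <= fdr) & (out["effect_log2"] >= np.log2(linear_fc)) \
        & (res["beta"] > 0)
    return out


def test_switch(counts: pd.DataFrame, design: pd.DataFrame, size_factors: pd.Series,
                alphas: pd.Series, genes, stimulus: str, switch_fc: float = 2.0,
                fdr: float = 0.05, _reduced_ll: dict | None = None) -> pd.DataFrame:
    """On/off (presence-indicator) model for genes that failed the linear model."""
    genes = [g for g in counts.index if g in set(genes)]
    if not genes:
        return pd.DataFrame(columns=["effect_log2", "p", "q", "passed"])
    dose = dose_vector(design, stimulus)
    if dose.nunique() < 2:
        raise ValueError(f"dose for {stimulus} has < 2 distinct values")
    present = (dose > 0).astype(float).rename("present")
    X_full, _ = expr.build_design_matrix(design, covariate=present)
    X_red, _ = expr.build_design_matrix(design)
    s = size_factors.loc[design.index].to_numpy()
    res = _stage_lrt(counts.loc[genes, design.index], X_full, X_red, s, alphas,
                     {} if _reduced_ll is None else _reduced_ll)
    out = pd.DataFrame(index=res.index)
    out["effect_log2"] = res["beta"] / LN2
    out["p"] = res["p"]
    out["q"] = expr.bh_adjust(res["p"].to_numpy())
    out["passed"] = (out["q"] <= fdr) & (out["effect_log2"] >= np.log2(switch_fc)) \
        & (res["beta"] > 0)
    return out


def classify_cell_type(counts: pd.DataFrame, design: pd.DataFrame,
                       size_factors: pd.Series, alphas: pd.Series,
                       cell_type: str, upregulated: set,
                       config: RunConfig | None = None) -> pd.DataFrame:
    """Per-gene sensitivity calls for one cell type.

    For each stimulus: model = linear if the linear test passes, else
    switch if the switch test passes, else none.  The gene-level stimulus
    label is the single passing stimulus, "both" when both pass, "none"
    when neither does; "both" genes carry ``unique=False``.
    """
    cfg = config or RunConfig()
    sub = design[design["cell_type"] == cell_type]
    genes = sorted(upregulated)
    stage = {}
    reduced_ll: dict = {}
    for stim in STIMULI:
        lin = test_linear(counts, sub, size_factors, alphas, genes, stim,
                          cfg.linear_fc, cfg.de_fdr, _reduced_ll=reduced_ll)
        failed = [g for g in genes if g in lin.index and not lin.loc[g, "passed"]]
        sw = test_switch(counts, sub, size_factors, alphas, failed, stim,
                         cfg.switch_fc, cfg.de_fdr, _reduced_ll=reduced_ll)
        stage[stim] = (lin, sw)

    rows = []
    for g in genes:
        per_stim = {}
        for stim in STIMULI:
            lin, sw = stage[stim]
            if g in lin.index and lin.loc[g, "passed"]:
                per_stim[stim] = ("linear", lin.loc[g, "effect_log2"],
                                  lin.loc[g, "p"], lin.loc[g, "q"])
            elif g in sw.index and sw.loc[g, "passed"]:
                per_stim[stim] = ("switch", sw.loc[g, "effect_log2"],
                                  sw.loc[g, "p"], sw.loc[g, "q"])
            else:
                src = lin if g in lin.index else sw
                rec = src.loc[g] if g in src.index else None
                per_stim[stim] = ("none",
                                  np.nan if rec is None else rec["effect_log2"],
                                  np.nan if rec is None else rec["p"],
                                  np.nan if rec is None else rec["q"])
        passing = [s for s in STIMULI if per_stim[s][0] != "none"]
        if len(passing) == 2:
            if cfg.both_resolution == "effect_size":
                stim = max(passing, key=lambda s: per_stim[s][1])
                model, eff, p, q = per_stim[stim]
                unique = True
            else:
                stim, unique = "both", False
                best = max(passing, key=lambda s: per_stim[s][1])
                model, eff, p, q = per_stim[best]
        elif len(passing) == 1:
            stim = passing[0]
            model, eff, p, q = per_stim[stim]
            unique = True
        else:
            stim, model, eff, p, q, unique = "none", "none", np.nan, np.nan, np.nan, False
        rows.append({
            "gene_id": g, "cell_type": cell_type, "stimulus": stim, "model": model,
            "effect_log2": eff, "p": p, "q": q, "unique": unique and stim != "none",
            "TCR_model": per_stim["TCR"][0], "TCR_effect_log2": per_stim["TCR"][1],
            "TCR_q": per_stim["TCR"][3],
            "CD28_model": per_stim["CD28"][0], "CD28_effect_log2": per_stim["CD28"][1],
            "CD28_q": per_stim["CD28"][3],
        })
    cols = ["gene_id", "cell_type", "stimulus", "model", "effect_log2", "p", "q",
            "unique", "TCR_model", "TCR_effect_log2", "TCR_q", "CD28_model",
            "CD28_effect_log2", "CD28_q"]
    return pd.DataFrame(rows, columns=cols).set_index("gene_id", drop=False)


def find_switchers(calls_naive: pd.DataFrame, calls_memory: pd.DataFrame) -> dict:
    """Genes with unique sensitivity that changes stimulus between subsets."""
    def uniq(calls, stim):
        m = (calls["stimulus"] == stim) & calls["unique"]
        return set(calls.index[m])

    return {
        "tcr_to_cd28": uniq(calls_naive, "TCR") & uniq(calls_memory, "CD28"),
        "cd28_to_tcr": uniq(calls_naive, "CD28") & uniq(calls_memory, "TCR"),
    }


def summarize_sensitivity(calls: pd.DataFrame, upregulated: dict) -> pd.DataFrame:
    """Per-cell-type counts of TCR/CD28/both/none and composition fractions."""
    rows = []
    for ct, sub in calls.groupby("cell_type"):
        n_up = len(upregulated[ct])
        n = {s: int((sub["stimulus"] == s).sum()) for s in ("TCR", "CD28", "both", "none")}
        # genes in the upregulated set but absent from calls are unclassified
        n["none"] += n_up - len(sub)
        uniq = n["TCR"] + n["CD28"]
        sens = sub[sub["unique"]]
        n_lin = int((sens["model"] == "linear").sum())
        rows.append({
            "cell_type": ct, "n_upregulated": n_up, "n_TCR": n["TCR"],
            "n_CD28": n["CD28"], "n_both": n["both"], "n_none": n["none"],
            "frac_unique": uniq / n_up if n_up else np.nan,
            "frac_linear": n_lin / len(sens) if len(sens) else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class ClassificationRun:
    calls: pd.DataFrame                 # both cell types concatenated
    upregulated: dict                   # cell type -> gene set
    de_results: dict                    # (cell type, condition) -> DE table
    summary: pd.DataFrame
    switchers: dict
    size_factors: pd.Series
    dispersions: "expr.DispersionEstimates"


def run_classification(counts: pd.DataFrame, design: pd.DataFrame,
                       annotation: pd.DataFrame,
                       config: RunConfig | None = None) -> ClassificationRun:
    """Full pipeline: filter, normalise, DE vs resting, classify, summarise."""
    cfg = config or RunConfig()
    counts = expr.filter_genes(counts, annotation)
    sf = expr.estimate_size_factors(counts)
    groups = design["cell_type"].astype(str) + "." + design["condition"].astype(str)
    disp = expr.estimate_dispersions(counts, sf, groups=groups.loc[counts.columns],
                                     prior_var=cfg.dispersion_prior_var)
    de_results, upregulated, calls = {}, {}, []
    for ct in ("naive", "memory"):
        if not (design["cell_type"] == ct).any():
            continue
        per_cond = {}
        for cond in STIMULATED_CONDITIONS:
            per_cond[cond] = expr.wald_de_test(
                counts, design, sf, disp.alpha, ct, cond,
                de_fc=cfg.de_fc, de_fdr=cfg.de_fdr)
            de_results[(ct, cond)] = per_cond[cond]
        upregulated[ct] = upregulated_gene_set(per_cond, cfg.de_fc, cfg.de_fdr)
        logger.info("%s: %d upregulated genes", ct, len(upregulated[ct]))
        calls.append(classify_cell_type(counts, design, sf, disp.alpha, ct,
                                        upregulated[ct], cfg))
    non_empty = [c for c in calls if len(c)]
    all_calls = pd.concat(non_empty) if non_empty else pd.DataFrame(
        columns=["gene_id", "cell_type", "stimulus", "model", "unique"])
    summary = summarize_sensitivity(all_calls, upregulated)
    if len(calls) == 2:
        switchers = find_switchers(calls[0], calls[1])
    else:
        switchers = {"tcr_to_cd28": set(), "cd28_to_tcr": set()}
    return ClassificationRun(all_calls, upregulated, de_results, summary,
                             switchers, sf, disp)
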