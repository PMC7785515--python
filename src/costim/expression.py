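"""Negative-binomial GLM machinery for the stimulation-grid RNA-seq counts.

The model for gene g in sample j is ``K_gj ~ NB(mean = s_j * q_gj,
dispersion = alpha_g)`` with ``log q_gj = x_j' beta_g`` — variance
``mu + alpha * mu^2``.  Size factors come from median-of-ratios
normalisation; per-gene dispersions are maximum-likelihood estimates
optionally shrunk in log space toward a mean-dispersion trend
``alpha_tr(mu) = a1/mu + a0``; coefficients are fitted by iteratively
reweighted least squares.  Wald tests serve pairwise differential
expression, likelihood-ratio tests serve the dose-response models.

This is a deliberately transparent re-derivation of the standard RNA-seq
GLM stack: gene-wise MLE dispersions with log-normal shrinkage stand in
for Cox-Reid adjusted estimation, so estimates differ slightly from
DESeq2's while the tests remain calibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import autosome_or_x

logger = logging.getLogger("costim.expression")

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0


class DesignError(ValueError):
    pass


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


# ---------------------------------------------------------------------------
# filtering and normalisation


def filter_genes(counts: pd.DataFrame, annotation: pd.DataFrame,
                 min_count: int = 20, min_samples: int = 3) -> pd.DataFrame:
    """Keep autosome/X genes with >= min_count in >= min_samples samples."""
    known = counts.index.intersection(annotation.index)
    dropped = counts.shape[0] - len(known)
    if dropped:
        logger.warning("dropping %d unannotated genes", dropped)
    counts = counts.loc[known]
    on_ok_chrom = autosome_or_x(annotation.loc[known, "chrom"])
    expressed = (counts.to_numpy() >= min_count).sum(axis=1) >= min_samples
    keep = on_ok_chrom.to_numpy() & expressed
    if not keep.any():
        raise ValueError("all genes filtered")
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame, fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors rescaled to geometric mean 1.

    Reference genes are those with positive counts in every sample; with
    ``fallback`` the per-gene geometric mean is taken over positive
    entries only when no such gene exists.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        ref = mat[all_pos]
        log_geo = np.log(ref).mean(axis=1)
        log_ratios = np.log(ref) - log_geo[:, None]
    elif fallback:
        any_pos = (mat > 0).any(axis=1)
        if not any_pos.any():
            raise ValueError("count matrix is all zero")
        ref = mat[any_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        log_ratios = logs - log_geo[:, None]
    else:
        raise ValueError("no gene with positive counts in all samples")
    log_s = np.nanmedian(log_ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


def log_norm(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x samples."""
    return np.log2(counts / size_factors + 1.0)


# ---------------------------------------------------------------------------
# NB likelihood and IRLS


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with Var = mu + alpha mu^2 (Poisson limit at tiny alpha)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    if alpha < 1e-8:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    k = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + k) - special.gammaln(k) - special.gammaln(y + 1)
            + k * np.log(k / (k + mu)) + y * np.log(mu / (k + mu))
        )
    )


@dataclass
class NBFit:
    beta: np.ndarray        # natural-log scale coefficients
    cov: np.ndarray         # asymptotic covariance of beta
    loglik: float
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov), 0.0))


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify aliased columns via QR pivoting on the diagonal
        _, r = np.linalg.qr(X)
        aliased = [j for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise DesignError(f"design matrix rank deficient; aliased columns {aliased}")


def fit_nb_glm(y, X, size_factors, alpha: float, max_iter: int = 100,
               tol: float = 1e-6, beta_prior_var: float | None = None) -> NBFit:
    """Fit one gene's NB GLM with log link and fixed dispersion.

    ``mu_j = s_j * exp(X beta)_j``; IRLS with working weights
    ``mu/(1+alpha*mu)``, converged when max |delta beta| < tol.  An
    optional normal prior (variance ``beta_prior_var`` in log2-FC units)
    on non-intercept coefficients turns the update into ridge IRLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    _check_rank(X)
    offset = np.log(s)
    # penalty in natural-log coefficient units (prior stated on log2 scale)
    P = np.zeros((X.shape[1], X.shape[1]))
    if beta_prior_var is not None:
        pen = 1.0 / (beta_prior_var * LN2 ** 2)
        P[1:, 1:] = np.eye(X.shape[1] - 1) * pen

    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X + P
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, XtW @ z, rcond=None)[0]
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    A = (X.T * W) @ X + P
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
    return NBFit(beta, cov, nb_loglik(y, mu, alpha), converged, it)


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionEstimates:
    alpha: pd.Series            # final (possibly shrunk) dispersions
    alpha_mle: pd.Series
    method: str                 # 'mle' or 'shrunk'
    trend_coef: tuple | None    # (a1, a0) of alpha_tr(mu) = a1/mu + a0
    flags: pd.Series            # 'ok', 'all_zero', 'boundary'


def _gene_alpha_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile MLE of alpha for one gene at fixed fitted means."""

    def nll(log_a):
        return -nb_loglik(y, mu, float(np.exp(log_a)))

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def estimate_dispersions(counts: pd.DataFrame, size_factors: pd.Series,
                         groups=None, shrink: bool = True,
                         prior_var: float = 0.761) -> DispersionEstimates:
    """Gene-wise dispersion MLEs, optionally shrunk toward the trend.

    ``groups`` (per-sample labels, e.g. cell type x condition) define the
    mean model: fitted means are group averages of normalised counts
    scaled back by the size factors.  Shrinkage maximises the log
    posterior with a normal prior of variance ``prior_var`` on log alpha
    centred at the trend value.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples to estimate dispersions")
    mat = counts.to_numpy(dtype=float)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    norm = mat / s
    if groups is None:
        q = norm.mean(axis=1, keepdims=True)
        mu = np.broadcast_to(q * s, mat.shape)
    else:
        groups = pd.Series(np.asarray(groups), index=counts.columns)
        codes, uniq = pd.factorize(groups)
        q = np.empty((mat.shape[0], len(uniq)))
        for k in range(len(uniq)):
            q[:, k] = norm[:, codes == k].mean(axis=1)
        mu = q[:, codes] * s

    n_genes = mat.shape[0]
    alpha_mle = np.empty(n_genes)
    flags = np.array(["ok"] * n_genes, dtype=object)
    base_mu = norm.mean(axis=1)
    for g in range(n_genes):
        if mat[g].sum() == 0:
            alpha_mle[g] = ALPHA_MAX
            flags[g] = "all_zero"
            continue
        alpha_mle[g] = _gene_alpha_mle(mat[g], np.maximum(mu[g], 1e-8))
        if alpha_mle[g] <= ALPHA_MIN * 1.01 or alpha_mle[g] >= ALPHA_MAX * 0.99:
            flags[g] = "boundary"

    trend = None
    alpha_final = alpha_mle.copy()
    if shrink:
        ok = flags == "ok"
        if ok.sum() >= 10:
            A = np.column_stack([1.0 / np.maximum(base_mu[ok], 1e-8), np.ones(ok.sum())])
            coef, _ = optimize.nnls(A, alpha_mle[ok])
            a1, a0 = float(coef[0]), float(coef[1])
        else:
            a1, a0 = 0.0, float(np.median(alpha_mle))
        a0 = max(a0, ALPHA_MIN)
        trend = (a1, a0)
        alpha_tr = np.maximum(a1 / np.maximum(base_mu, 1e-8) + a0, ALPHA_MIN)
        for g in range(n_genes):
            if flags[g] == "all_zero":
                continue
            log_tr = np.log(alpha_tr[g])
            y_g, mu_g = mat[g], np.maximum(mu[g], 1e-8)

            def npost(log_a):
                return -nb_loglik(y_g, mu_g, float(np.exp(log_a))) + \
                    (log_a - log_tr) ** 2 / (2.0 * prior_var)

            res = optimize.minimize_scalar(
                npost, bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)),
                method="bounded", options={"xatol": 1e-4},
            )
            alpha_final[g] = float(np.exp(res.x))

    idx = counts.index
    return DispersionEstimates(
        alpha=pd.Series(alpha_final, index=idx, name="alpha"),
        alpha_mle=pd.Series(alpha_mle, index=idx, name="alpha_mle"),
        method="shrunk" if shrink else "mle",
        trend_coef=trend,
        flags=pd.Series(flags, index=idx, name="flag"),
    )


# ---------------------------------------------------------------------------
# design helpers


def build_design_matrix(design: pd.DataFrame, covariate: pd.Series | None = None,
                        batch: bool = True):
    """Intercept + optional numeric covariate + batch dummies.

    Returns (X, column names).  Batch dummies are dropped when only one
    batch is present in the subset.
    """
    n = design.shape[0]
    cols, names = [np.ones(n)], ["intercept"]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
        names.append(covariate.name or "covariate")
    if batch:
        levels = sorted(design["batch"].unique())
        for lv in levels[1:]:
            cols.append((design["batch"] == lv).to_numpy(dtype=float))
            names.append(f"batch_{lv}")
    return np.column_stack(cols), names


def _is_nested(X_full: np.ndarray, X_reduced: np.ndarray) -> bool:
    proj, *_ = np.linalg.lstsq(X_full, X_reduced, rcond=None)
    return bool(np.allclose(X_full @ proj, X_reduced, atol=1e-8))


# ---------------------------------------------------------------------------
# tests


def wald_de_test(counts: pd.DataFrame, design: pd.DataFrame, size_factors: pd.Series,
                 alphas: pd.Series, cell_type: str, condition: str,
                 reference: str = "resting", de_fc: float = 2.0,
                 de_fdr: float = 0.05) -> pd.DataFrame:
    """Wald test of ``condition`` vs ``reference`` within one cell type.

    Per gene: z = beta/SE from the NB GLM (intercept + condition indicator
    + batch), two-sided normal p, BH q across genes.  ``upregulated``
    requires log2FC >= log2(de_fc) and q <= de_fdr.
    """
    sub = design[(design["cell_type"] == cell_type)
                 & (design["condition"].isin([condition, reference]))]
    for grp in (condition, reference):
        if (sub["condition"] == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has < 2 samples in cell type {cell_type!r}")
    ids = sub.index
    ind = pd.Series((sub["condition"] == condition).astype(float), index=ids, name="group")
    X, _ = build_design_matrix(sub, covariate=ind)
    s = size_factors.loc[ids].to_numpy()
    mat = counts[ids].to_numpy(dtype=float)
    grp_mask = ind.to_numpy() == 1.0

    rows = []
    for g in range(mat.shape[0]):
        y = mat[g]
        fit = fit_nb_glm(y, X, s, float(alphas.iloc[g]))
        beta, se = fit.beta[1], fit.se[1]
        lfc = beta / LN2
        if y[grp_mask].sum() == 0 or y[~grp_mask].sum() == 0:
            # degenerate group: report pseudo-count LFC, keep GLM p if sane
            m1 = (y[grp_mask] / s[grp_mask]).mean() + 0.5
            m0 = (y[~grp_mask] / s[~grp_mask]).mean() + 0.5
            lfc = np.log2(m1 / m0)
        if se <= 0 or not np.isfinite(se) or not fit.converged:
            rows.append((lfc, np.nan, np.nan, np.nan))
            continue
        z = beta / se
        rows.append((lfc, se / LN2, z, 2.0 * stats.norm.sf(abs(z))))
    res = pd.DataFrame(rows, columns=["log2fc", "se", "stat", "p"], index=counts.index)
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["upregulated"] = (res["log2fc"] >= np.log2(de_fc)) & (res["q"] <= de_fdr)
    return res


def lrt_test(counts: pd.DataFrame, X_full: np.ndarray, X_reduced: np.ndarray,
             size_factors: np.ndarray, alphas: np.ndarray) -> pd.DataFrame:
    """Likelihood-ratio test of nested NB GLMs, chi-square reference.

    Returns per gene the full-model coefficients are not kept here — use
    :func:`fit_nb_glm` for effect sizes; this reports (stat, df, p).
    """
    X_full = np.asarray(X_full, float)
    X_reduced = np.asarray(X_reduced, float)
    if not _is_nested(X_full, X_reduced):
        raise DesignError("reduced design is not nested in the full design")
    df = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced)
    if df <= 0:
        df = 0
    s = np.asarray(size_factors, float)
    mat = counts.to_numpy(dtype=float)
    stats_out = np.empty(mat.shape[0])
    for g in range(mat.shape[0]):
        a = float(alphas[g])
        ll_full = fit_nb_glm(mat[g], X_full, s, a).loglik
        ll_red = fit_nb_glm(mat[g], X_reduced, s, a).loglik
        stats_out[g] = max(0.0, 2.0 * (ll_full - ll_red))
    p = stats.chi2.sf(stats_out, df) if df > 0 else np.ones_like(stats_out)
    return pd.DataFrame({"stat": stats_out, "df": df, "p": p}, index=counts.index)


# ---------------------------------------------------------------------------
# variance decomposition and PCA


def variance_explained(log_norm_counts: pd.DataFrame, design: pd.DataFrame,
                       factor: str) -> float:
    """Mean per-gene R^2 of a one-factor linear model on log-normal counts."""
    labels = design.loc[log_norm_counts.columns, factor]
    levels = labels.unique()
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    Z = pd.get_dummies(labels).to_numpy(dtype=float)
    Y = log_norm_counts.to_numpy(dtype=float).T  # samples x genes
    Yc = Y - Y.mean(axis=0)
    hat, *_ = np.linalg.lstsq(Z, Yc, rcond=None)
    fitted = Z @ hat
    sst = (Yc ** 2).sum(axis=0)
    ok = sst > 1e-12
    if not ok.all():
        logger.warning("excluding %d constant genes from variance decomposition",
                       int((~ok).sum()))
    r2 = (fitted[:, ok] ** 2).sum(axis=0) / sst[ok]
    return float(r2.mean())


def regress_out_batch(log_norm_counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene removal of batch means (covariate substitute for ComBat)."""
    batches = design.loc[log_norm_counts.columns, "batch"]
    out = log_norm_counts.copy()
    grand = out.mean(axis=1)
    for b in batches.unique():
        cols = batches.index[batches == b]
        out[cols] = out[cols].sub(out[cols].mean(axis=1) - grand, axis=0)
    return out


def pca(log_norm_counts: pd.DataFrame, design: pd.DataFrame | None = None,
        batch_adjust: bool = False):
    """Sample PCA of gene-centred log-normal counts.

    Returns (scores DataFrame samples x PCs, variance fractions).
    """
    if log_norm_counts.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = log_norm_counts
    if batch_adjust:
        if design is None:
            raise ValueError("batch_adjust requires the design sheet")
        X = regress_out_batch(X, design)
    M = X.to_numpy(dtype=float).T
    M = M - M.mean(axis=0)
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    scores = U * S
    total = (S ** 2).sum()
    frac = (S ** 2) / total if total > 0 else np.zeros_like(S)
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=X.columns, columns=cols), frac
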