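"""Differential-expression engine for the screening workflow.

Given a labeled expression dataset it performs, per target-vs-other-group
comparison: low-expression filtering, trimmed-mean-of-M-values (TMM)
scaling normalization, optional mean-variance precision weighting for
count data, gene-wise weighted linear modeling on a group-means design
with batch as a fixed-effect covariate, empirical-Bayes variance
moderation, and either the moderated t-test (fold-change threshold 0) or
a threshold test against a nonzero log-fold-change bound.  P-values are
Benjamini-Hochberg adjusted within each comparison.

The variance-moderation machinery (inverse-chi-square prior fitted by
matching moments of log variances, posterior variance shrinkage, and the
two-tailed shifted-null threshold test) follows the published method
descriptions of the standard bulk RNA-seq workflow these steps come from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import rankdata, t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .datatypes import RAW_COUNTS, DEResult, ExpressionDataset


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """Group-means design with optional batch indicator columns."""

    matrix: pd.DataFrame  # samples x columns
    group_labels: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def contrast(self, target: str, other: str) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[self.matrix.columns.get_loc(f"group_{target}")] = 1.0
        c[self.matrix.columns.get_loc(f"group_{other}")] = -1.0
        return c


def build_design(annotations: pd.DataFrame) -> DesignMatrix:
    """Build a group-means design matrix, appending batch columns.

    Each sample gets exactly one group-indicator column set to 1; batch
    enters as fixed-effect dummy columns (reference batch omitted).  A
    batch perfectly confounded with group makes the matrix rank deficient
    and is rejected.
    """
    groups = annotations["Group"].astype(str)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    cols = {f"group_{g}": (groups == g).astype(float) for g in labels}
    if "Batch" in annotations.columns:
        batches = annotations["Batch"].astype(str)
        blevels = sorted(batches.unique())
        for b in blevels[1:]:  # reference batch omitted
            cols[f"batch_{b}"] = (batches == b).astype(float)
    X = pd.DataFrame(cols, index=annotations.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (batch confounded with group?)")
    return DesignMatrix(matrix=X, group_labels=labels)


# ---------------------------------------------------------------------------
# expression filtering


def filter_low_expression(
    dataset: ExpressionDataset,
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> pd.Series:
    """Keep genes with worthwhile counts for DE (counts route).

    A gene survives when its counts-per-million exceed the CPM equivalent
    of ``min_count`` (at the median library size) in at least k samples,
    k being the smallest group size, and its total count is at least
    ``min_total``.  Returns a boolean mask indexed by gene.
    """
    if dataset.scale != RAW_COUNTS:
        raise ValueError("expression filtering by counts requires raw_counts scale")
    counts = dataset.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    k = dataset.groups.value_counts().min()
    cpm_cutoff = min_count / np.median(lib) * 1e6
    cpm = counts / lib * 1e6
    tol = 1e-14
    keep = ((cpm >= cpm_cutoff).sum(axis=1) >= k - tol) & (counts.sum(axis=1) >= min_total - tol)
    return pd.Series(keep, index=dataset.values.index, name="keep")


def filter_log_expression(
    dataset: ExpressionDataset,
    min_mean: float = 1.0,
    floor: float = 1.0,
) -> pd.Series:
    """Threshold filter for log-expression input: keep genes whose mean
    log-expression is at least ``min_mean`` and which exceed ``floor`` in
    at least smallest-group-size samples."""
    x = dataset.values.to_numpy(dtype=float)
    k = dataset.groups.value_counts().min()
    keep = (x.mean(axis=1) >= min_mean) & ((x > floor).sum(axis=1) >= k)
    return pd.Series(keep, index=dataset.values.index, name="keep")


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05,
              weighted: bool = True) -> float:
    """Scaling factor for one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        M = np.log2(p_obs / p_ref)
        A = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic variance of M (binomial delta method)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(M) & np.isfinite(A) & (A > -1e10)
    M, A, v = M[ok], A[ok], v[ok]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(M[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame | np.ndarray,
                logratio_trim: float = 0.3, sum_trim: float = 0.05,
                weighted: bool = True, ref_column: int | None = None) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric mean normalized to 1.

    Each factor is the weighted mean of gene-wise log-ratios (M-values)
    against a reference sample, after trimming the most extreme 30% of
    M-values and 5% of average log-abundances (A-values), with
    inverse-asymptotic-variance weights.  The reference sample is the one
    whose 75th CPM percentile sits closest to the mean across samples.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >=2 samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero total count")
    if ref_column is None:
        f75 = np.quantile(X / lib, 0.75, axis=0)
        if np.median(f75) < 1e-20:
            ref_column = int(np.argmax(np.sqrt(X).sum(axis=0)))
        else:
            ref_column = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair(X[:, j], X[:, ref_column], lib[j], lib[ref_column],
                  logratio_trim, sum_trim, weighted)
        for j in range(X.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(counts: np.ndarray, factors: np.ndarray | None = None,
            prior_count: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a small offset, on effective library sizes."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * factors
    return np.log2((counts + prior_count) / (lib + 1.0) * 1e6)


# ---------------------------------------------------------------------------
# precision weights (mean-variance modeling for counts)


def precision_weights(
    counts: pd.DataFrame | np.ndarray,
    design: DesignMatrix,
    factors: np.ndarray | None = None,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-observation precision weights for count data.

    Counts are converted to log2-CPM (0.5 offset); gene-wise linear models
    give residual standard deviations; a lowess of sqrt(SD) against mean
    log2-count captures the mean-variance trend; each observation's weight
    is the inverse fourth power of the trend interpolated at its fitted
    log2-count.  Returns ``(weights, log_expression)`` matrices.
    """
    X = np.asarray(counts, dtype=float)
    G, S = X.shape
    D = design.matrix.to_numpy()
    if S - D.shape[1] < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    lib = X.sum(axis=0)
    if factors is not None:
        lib = lib * factors
    y = np.log2((X + 0.5) / (lib + 1.0) * 1e6)
    # OLS per gene (common design => one pseudoinverse)
    pinv = np.linalg.pinv(D)
    beta = y @ pinv.T
    fitted = beta @ D.T
    resid = y - fitted
    df_resid = S - D.shape[1]
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    smooth = lowess(sy, sx, frac=span, return_sorted=True)
    # piecewise-linear trend, constant beyond the data range
    xs, ys = smooth[:, 0], smooth[:, 1]
    fitted_cpm = 2.0 ** fitted
    fitted_count = 1e-6 * fitted_cpm * (lib + 1.0)
    fitted_logcount = np.log2(fitted_count)
    trend = np.interp(fitted_logcount, xs, ys)
    trend = np.clip(trend, 1e-6, None)
    w = 1.0 / trend ** 4
    return w, y


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(
    s2: np.ndarray,
    df: float,
    covariate: np.ndarray | None = None,
    span: float = 0.5,
) -> tuple[np.ndarray | float, float]:
    """Fit a scaled inverse-chi-square prior to gene-wise sample variances.

    Moment matching on log variances: the prior scale s2_0 and prior
    degrees of freedom d0 are chosen so that log(s2) has the mean and
    excess variance implied by an F(df, d0) sampling distribution around
    s2_0.  With a covariate, the prior scale follows a lowess trend of the
    log variances against it (mean-trended prior).  Returns
    ``(s2_prior, df_prior)``; df_prior may be ``inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evalid = e[ok]
    n = evalid.size
    if covariate is not None:
        smooth = lowess(evalid, np.asarray(covariate)[ok], frac=span, return_sorted=True)
        emean_valid = np.interp(np.asarray(covariate)[ok], smooth[:, 0], smooth[:, 1])
        emean = np.interp(np.asarray(covariate), smooth[:, 0], smooth[:, 1])
        resid = evalid - emean_valid
    else:
        emean = float(np.mean(evalid))
        resid = evalid - emean
    if n < 2:
        return np.exp(emean), np.inf
    evar = float(np.sum(resid ** 2) / (n - 1)) - float(_trigamma(df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(emean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return s2_prior, float(df_prior)


def squeeze_variances(s2: np.ndarray, df: float, s2_prior, df_prior: float) -> np.ndarray:
    """Posterior (shrunken) variances under the fitted prior."""
    if np.isinf(df_prior):
        return np.broadcast_to(np.asarray(s2_prior, dtype=float), s2.shape).copy()
    return (df_prior * np.asarray(s2_prior) + df * s2) / (df_prior + df)


def fit_and_test(
    log_expr: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
    weights: np.ndarray | None = None,
    lfc_threshold: float = 0.0,
    trend: bool = False,
    prior_df: float | None = None,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Gene-wise weighted least squares with moderated inference.

    Fits each gene's linear model, shrinks residual variances toward the
    empirical-Bayes prior (common scale, or mean-trended when ``trend``),
    and tests the contrast.  With ``lfc_threshold == 0`` this is the
    moderated t-test; with a positive threshold the null becomes
    |true logFC| <= threshold and the p-value conservatively combines
    both shifted-null tails.  ``prior_df`` overrides the estimated prior
    degrees of freedom (0 disables moderation entirely).

    Returns a DataFrame with columns logFC, t, p_value, adj_p_value,
    mean_expression.
    """
    y = np.asarray(log_expr, dtype=float)
    G, S = y.shape
    D = design.matrix.to_numpy()
    p = D.shape[1]
    df_resid = S - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    c = np.asarray(contrast, dtype=float)

    coefs = np.empty(G)
    unscaled = np.empty(G)
    s2 = np.empty(G)
    if weights is None:
        XtX_inv = np.linalg.inv(D.T @ D)
        H = XtX_inv @ D.T
        beta = y @ H.T
        resid = y - beta @ D.T
        s2[:] = (resid ** 2).sum(axis=1) / df_resid
        coefs[:] = beta @ c
        unscaled[:] = np.sqrt(c @ XtX_inv @ c)
    else:
        W = np.asarray(weights, dtype=float)
        for g in range(G):
            wg = W[g]
            Xw = D * wg[:, None]
            XtWX = D.T @ Xw
            XtWX_inv = np.linalg.inv(XtWX)
            beta_g = XtWX_inv @ (Xw.T @ y[g])
            r = y[g] - D @ beta_g
            s2[g] = np.sum(wg * r ** 2) / df_resid
            coefs[g] = c @ beta_g
            unscaled[g] = np.sqrt(c @ XtWX_inv @ c)

    amean = y.mean(axis=1)
    if prior_df is None:
        s2_prior, d0 = fit_variance_prior(s2, df_resid, covariate=amean if trend else None)
    elif prior_df == 0:
        s2_prior, d0 = 0.0, 0.0
    else:
        d0 = prior_df
        s2_prior = float(np.exp(np.mean(np.log(s2[s2 > 0]))))
    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = squeeze_variances(s2, df_resid, s2_prior, d0)
        df_total = min(df_resid + d0, G * df_resid)

    se = unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coefs / se
    if lfc_threshold == 0:
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    else:
        acoef = np.abs(coefs)
        t_right = (acoef - lfc_threshold) / se
        t_left = (acoef + lfc_threshold) / se
        pvals = t_dist.sf(t_right, df_total) + t_dist.sf(t_left, df_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    adj = multipletests(pvals, method="fdr_bh")[1]
    idx = genes if genes is not None else pd.RangeIndex(G)
    return pd.DataFrame(
        {
            "logFC": coefs,
            "t": tstat,
            "p_value": pvals,
            "adj_p_value": adj,
            "mean_expression": amean,
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# the full pairwise DE stage


def run_pairwise_de(dataset: ExpressionDataset, config: RunConfig) -> list[DEResult]:
    """Run target-vs-other DE for every non-target group (n-1 comparisons).

    Counts input takes the filtering -> TMM -> precision-weighting route;
    log-expression input takes the threshold-filtering -> trend-moderation
    route.  Both end in the same moderated/threshold test.
    """
    groups = dataset.groups
    labels = sorted(groups.unique())
    if config.target_group not in labels:
        raise ValueError(f"target group {config.target_group!r} not in data "
                         f"(groups: {labels})")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    design = build_design(dataset.annotations)

    if dataset.scale == RAW_COUNTS:
        mask = filter_low_expression(
            dataset, min_count=config.filter_min_count, min_total=config.filter_min_total
        )
        counts = dataset.values.loc[mask].to_numpy(dtype=float)
        genes = dataset.values.index[mask]
        factors = tmm_factors(counts)
        weights, y = precision_weights(counts, design, factors)
        trend = False
    else:
        mask = filter_log_expression(
            dataset, min_mean=config.logexpr_min_mean, floor=config.logexpr_floor
        )
        y = dataset.values.loc[mask].to_numpy(dtype=float)
        genes = dataset.values.index[mask]
        weights = None
        trend = True

    results = []
    for other in labels:
        if other == config.target_group:
            continue
        table = fit_and_test(
            y,
            design,
            design.contrast(config.target_group, other),
            weights=weights,
            lfc_threshold=config.lfc_threshold,
            trend=trend,
            genes=genes,
        )
        results.append(DEResult(target_group=config.target_group, other_group=other, table=table))
    return results
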