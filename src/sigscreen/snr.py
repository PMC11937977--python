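"""Background-expression refinement via a percentile-based
signal-to-noise ratio.

The idea: markers selected against other sorted populations may still be
ubiquitously expressed in the tissue microenvironment the signature will
be applied to (e.g. bulk tumor).  To compare a signal dataset and a
background dataset without joint renormalization, each sample's
log-expression vector is reduced to within-sample relative expression:
a normal distribution N(mu_s, sigma_s^2) is fitted per sample by maximum
likelihood, and each gene's value is mapped to its Gaussian percentile
Phi((x - mu_s) / sigma_s).  Percentiles are invariant to per-sample
affine shifts/scalings of the log-expression, which is exactly what makes
signal and background comparable across datasets and normalizations.

Per gene, a normal fit across the signal samples' percentiles gives a
median x_S (= the fitted mean, since the median of a normal is its mean);
likewise x_B and sigma_B for the background.  The Cohen's-d-style score

    snr = (x_S - x_B) / sigma_B

is large for genes high in the target population but quiet in the
background; genes below the cutoff are dropped — except marker-pool
genes, which are protected as biologically vetted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import (
    RAW_COUNTS,
    ExpressionDataset,
    GeneSetCollection,
    Signature,
    SnrTable,
)
from .de import log_cpm


def fit_sample_normal(values: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood normal fit to one sample's log-expression vector.

    Returns (mu, sigma) with the population (divide-by-n) standard
    deviation, i.e. the exact MLE.  A constant vector has no spread to
    standardize against and is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("need >=2 distinct values for a normal fit")
    mu = float(np.mean(x))
    sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
    return mu, sigma


def percentile_transform(dataset: ExpressionDataset) -> pd.DataFrame:
    """Within-sample Gaussian percentiles of log-expression.

    Count-scale input is converted to log2-CPM (0.5 offset) first.  Entry
    (g, s) is Phi((x_gs - mu_s) / sigma_s) with that sample's fitted
    parameters; strictly increasing in x within each sample, and
    invariant to per-sample affine maps a*x + b (a > 0).
    """
    if dataset.scale == RAW_COUNTS:
        x = log_cpm(dataset.values.to_numpy(dtype=float))
    else:
        x = dataset.values.to_numpy(dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        mu, sigma = fit_sample_normal(x[:, j])
        out[:, j] = norm.cdf((x[:, j] - mu) / sigma)
    return pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)


def compute_snr(
    signal_percentiles: pd.DataFrame,
    background_percentiles: pd.DataFrame,
) -> SnrTable:
    """Per-gene SNR between signal-sample and background-sample percentiles.

    Gene universes are reconciled by intersection.  For each gene the
    normal fit across the signal samples' percentiles yields the median
    x_S (the fitted mean); the background fit yields x_B and sigma_B, and
    snr = (x_S - x_B) / sigma_B.  Because the median of a normal equals
    its mean, this is exactly (mean - mean) / SD of the percentile
    vectors.  A single sample on either side degenerates the fit to a
    point value (sigma = 0 on the background side flags the gene).
    """
    common = signal_percentiles.index.intersection(background_percentiles.index)
    if len(common) == 0:
        raise ValueError("no common genes between signal and background")
    S = signal_percentiles.loc[common].to_numpy(dtype=float)
    B = background_percentiles.loc[common].to_numpy(dtype=float)
    if S.shape[1] == 1:
        warnings.warn("single signal sample: median falls back to the point value")
    x_s = S.mean(axis=1)
    x_b = B.mean(axis=1)
    sd_b = np.sqrt(np.mean((B - x_b[:, None]) ** 2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = (x_s - x_b) / sd_b
    degenerate = sd_b == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} gene(s) have zero background spread; "
                      "their SNR is undefined and resolved by the sign of the "
                      "signal-background difference")
        snr = np.where(degenerate, np.where(x_s > x_b, np.inf, -np.inf), snr)
    table = pd.DataFrame(
        {"x_signal": x_s, "x_background": x_b, "sd_background": sd_b, "snr": snr},
        index=common,
    )
    return SnrTable(table=table)


def filter_by_snr(
    signature: Signature,
    snr_table: SnrTable,
    threshold: float = 1.0,
    pool: GeneSetCollection | None = None,
) -> Signature:
    """Drop signature genes whose SNR falls below the threshold.

    Marker-pool genes are always retained (flagged ``protected``), as are
    genes absent from the background data (they cannot be assessed; a
    warning is emitted).
    """
    protected = set(pool.all_genes()) if pool is not None else set()
    snr = snr_table.table["snr"]
    keep = []
    flags = {}
    missing = 0
    for g in signature.genes:
        if g not in snr.index:
            keep.append(g)
            flags[g] = "no_background"
            missing += 1
        elif snr.loc[g] >= threshold:
            keep.append(g)
        elif g in protected:
            keep.append(g)
            flags[g] = "protected"
    if missing:
        warnings.warn(f"{missing} signature gene(s) absent from the background data "
                      "were retained unassessed")
    table = signature.table.loc[keep].copy()
    if flags:
        table["snr_flag"] = pd.Series(flags).reindex(table.index).fillna("")
    return Signature(table=table)
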