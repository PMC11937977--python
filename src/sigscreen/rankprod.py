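"""Rank-product scoring across comparisons with a permutation null.

The screening statistic for gene g is the rank product

    RP_g = sum_i ln(rank_{g,i})

where rank_{g,i} is gene g's rank (1 = most significant, ties averaged)
in the i-th comparison's list.  Significance is assessed by a bootstrap
permutation test: within each comparison the rank vector is shuffled
independently (a random bijection genes -> ranks), the permuted rank
product rp is recomputed, and

    score_g = P(rp < RP_g)

is estimated as the empirical fraction over K permutations (strict
inequality, no pseudocount by default).  Smaller scores mean the gene is
more consistently top-ranked across all comparisons than chance allows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import RunConfig
from .datatypes import DEResult, RankProductResult


def rank_genes(de_results: list[DEResult], statistic: str = "p_value") -> pd.DataFrame:
    """Rank the common gene universe within each comparison.

    Genes are ranked ascending in the statistic (1 = smallest p), with
    ties averaged; for ``logFC`` the ranking is descending in |logFC| so
    that rank 1 is the strongest change.  The universe is the
    intersection of the result tables.  Returns a genes x comparisons
    DataFrame of ranks.
    """
    if statistic not in ("p_value", "adj_p_value", "logFC"):
        raise ValueError(f"unsupported rank statistic {statistic!r}")
    if not de_results:
        raise ValueError("no DE results supplied")
    common = de_results[0].table.index
    for r in de_results[1:]:
        common = common.intersection(r.table.index)
    if len(common) == 0:
        raise ValueError("empty common gene universe across comparisons")
    common = de_results[0].table.index[de_results[0].table.index.isin(common)]
    ranks = {}
    for r in de_results:
        vals = r.table.loc[common, statistic].to_numpy(dtype=float)
        if statistic == "logFC":
            ranks[r.comparison] = rankdata(-np.abs(vals))
        else:
            ranks[r.comparison] = rankdata(vals)
    return pd.DataFrame(ranks, index=common)


def compute_rp(ranks: pd.DataFrame) -> pd.Series:
    """Sum of natural-log ranks across comparisons (RP_g)."""
    if ranks.shape[1] < 1:
        raise ValueError("need at least one comparison")
    return pd.Series(np.log(ranks.to_numpy(dtype=float)).sum(axis=1),
                     index=ranks.index, name="rank_product")


def permutation_score(
    ranks: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int | None = None,
    smoothed: bool = False,
) -> RankProductResult:
    """Empirical permutation probability for each gene's rank product.

    For each of K permutations the rank vector of every comparison is
    shuffled independently and the permuted rank product compared against
    the observed one; ``score_g`` is the fraction of permutations whose
    rp falls strictly below RP_g.  With ``smoothed`` the estimator becomes
    (#{rp < RP_g} + 1) / (K + 1), avoiding exact zeros.  Fully
    reproducible given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    R = ranks.to_numpy(dtype=float)
    G, C = R.shape
    rp_obs = np.log(R).sum(axis=1)
    rng = np.random.default_rng(seed)
    log_R = np.log(R)
    hits = np.zeros(G, dtype=np.int64)
    for _ in range(n_permutations):
        rp_perm = np.zeros(G)
        for i in range(C):
            rp_perm += log_R[rng.permutation(G), i]
        hits += rp_perm < rp_obs
    if smoothed:
        score = (hits + 1.0) / (n_permutations + 1.0)
    else:
        score = hits / float(n_permutations)
    table = pd.DataFrame({"rank_product": rp_obs, "score": score}, index=ranks.index)
    return RankProductResult(
        table=table,
        n_permutations=n_permutations,
        seed=seed,
        per_comparison_ranks=ranks,
    )


def exhaustive_score(ranks: pd.DataFrame) -> pd.Series:
    """Exact permutation probability by enumerating every combination of
    within-comparison shuffles.  Feasible only for tiny instances
    (G!^C combinations); used for exact inference and as a reference in
    validation.
    """
    import math
    from itertools import permutations, product

    R = ranks.to_numpy(dtype=float)
    G, C = R.shape
    if math.factorial(G) ** C > 10 ** 6:
        raise ValueError("instance too large for exhaustive enumeration")
    rp_obs = np.log(R).sum(axis=1)
    log_cols = [np.log(R[:, i]) for i in range(C)]
    hits = np.zeros(G, dtype=np.int64)
    count = 0
    for perm_combo in product(*(permutations(range(G)) for _ in range(C))):
        rp = np.zeros(G)
        for i, perm in enumerate(perm_combo):
            rp += log_cols[i][list(perm)]
        hits += rp < rp_obs
        count += 1
    return pd.Series(hits / count, index=ranks.index, name="score")


def select_genes(
    rp_result: RankProductResult,
    config: RunConfig,
    direction_logfc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select genes whose permutation score clears the threshold.

    Genes with score below ``score_threshold`` are selected with reason
    ``rp``.  When ``keep_group`` names comparisons, the top ``keep_top``
    genes of each named comparison's own ranking are force-included with
    reason ``keep_top`` regardless of score — an escape hatch for
    closely related groups whose comparison would otherwise dominate the
    rank product.  ``direction_logfc`` (genes x comparisons of logFC)
    restricts selection to target-up genes unless the config asks for
    two-sided markers.
    """
    table = rp_result.table
    selected = table["score"] < config.score_threshold
    reason = pd.Series(np.where(selected, "rp", ""), index=table.index)
    if config.keep_group:
        ranks = rp_result.per_comparison_ranks
        if ranks is None:
            raise ValueError("per-comparison ranks unavailable for keep_top")
        for comp in config.keep_group:
            matches = [c for c in ranks.columns if c == comp or c.endswith(f"-{comp}")]
            if not matches:
                raise ValueError(f"keep_group names unknown comparison {comp!r}")
            for col in matches:
                top = ranks[col].nsmallest(config.keep_top).index
                for g in top:
                    if not selected.loc[g]:
                        selected.loc[g] = True
                        reason.loc[g] = "keep_top"
    out = table.loc[selected].copy()
    out["selected_by"] = reason.loc[selected]
    if direction_logfc is not None and not config.two_sided_markers:
        up = (direction_logfc.reindex(out.index) > 0).all(axis=1)
        # keep_top rescues are exempt from the direction restriction
        out = out[up | (out["selected_by"] == "keep_top")]
    if out.empty:
        warnings.warn("no genes selected at the current score threshold")
    return out.sort_values(["score", "rank_product"], kind="mergesort")
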