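"""Signature assembly: constrain selected genes to the marker pool and
aggregate signatures identified on multiple datasets."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom

from .datatypes import GeneSetCollection, Signature


def constrain_to_pool(selected: pd.DataFrame, pool: GeneSetCollection | None) -> Signature:
    """Intersect the selected genes with the marker pool.

    Without a pool this is a pass-through.  Score order is preserved; an
    empty intersection yields an empty signature with a warning rather
    than an error.
    """
    table = selected.copy()
    if "selected_by" not in table.columns:
        table["selected_by"] = "rp"
    if pool is not None:
        pool_genes = set(pool.all_genes())
        keep = table.index.isin(pool_genes)
        if not keep.any():
            warnings.warn("signature is empty after constraining to the marker pool")
        table = table.loc[keep]
    return Signature(table=table)


def rra_score(rank_lists: pd.DataFrame) -> pd.Series:
    """Robust-rank-aggregation significance score per gene.

    ``rank_lists`` holds normalized ranks r in (0, 1] per gene (rows) and
    list (columns); genes absent from a list carry r = 1.  For each gene
    with sorted normalized ranks r(1) <= ... <= r(m) over m lists, the
    score is min_k P(Binomial(m, r(k)) >= k), Bonferroni-corrected by m
    and capped at 1 — small under the null of uncorrelated lists only
    when the gene sits consistently higher than chance expects.
    """
    if rank_lists.shape[1] == 0:
        raise ValueError("no rank lists supplied")
    R = rank_lists.to_numpy(dtype=float)
    if np.any((R <= 0) | (R > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    m = R.shape[1]
    R_sorted = np.sort(R, axis=1)
    ks = np.arange(1, m + 1)
    # P(Binom(m, r_(k)) >= k), vectorized over genes and k
    tail = binom.sf(ks - 1, m, R_sorted)
    rho = tail.min(axis=1)
    return pd.Series(np.minimum(rho * m, 1.0), index=rank_lists.index, name="rra_score")


def _normalized_rank_lists(signatures: dict[str, Signature]) -> pd.DataFrame:
    """Per-dataset normalized ranks over the union universe.

    Each dataset contributes its signature genes ranked by ascending
    score; the normalized rank is rank / (list length).  Genes absent
    from a dataset's list get the worst value 1.
    """
    universe: dict[str, None] = {}
    for sig in signatures.values():
        for g in sig.genes:
            universe.setdefault(g)
    genes = list(universe)
    cols = {}
    for name, sig in signatures.items():
        ordered = sig.table.sort_values("score", kind="mergesort").index
        n = len(ordered)
        col = pd.Series(1.0, index=genes)
        for i, g in enumerate(ordered, start=1):
            col.loc[g] = i / n
        cols[name] = col
    return pd.DataFrame(cols, index=genes)


def aggregate_signatures(
    signatures: dict[str, Signature],
    method: str = "union",
    rra_threshold: float = 0.05,
) -> Signature:
    """Combine per-dataset signatures into one.

    ``union`` keeps every gene selected anywhere; ``intersect`` keeps
    genes selected in every dataset; ``RRA`` keeps genes whose
    robust-rank-aggregation score over the per-dataset score rankings
    falls below ``rra_threshold``.  Union/intersect order genes by their
    best (minimum) per-dataset score; RRA orders by the RRA score.
    """
    if method not in ("union", "intersect", "RRA"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if not signatures:
        raise ValueError("no signatures supplied")
    if method in ("intersect", "RRA") and len(signatures) < 2:
        raise ValueError(f"{method} aggregation needs at least 2 dataset signatures")

    best_score: dict[str, float] = {}
    best_rp: dict[str, float] = {}
    sources: dict[str, list[str]] = {}
    for name, sig in signatures.items():
        for g in sig.genes:
            s = float(sig.table.loc[g, "score"])
            if g not in best_score or s < best_score[g]:
                best_score[g] = s
                best_rp[g] = float(sig.table.loc[g].get("rank_product", np.nan))
            sources.setdefault(g, []).append(name)

    if method == "union":
        genes = list(best_score)
    elif method == "intersect":
        genes = [g for g, src in sources.items() if len(src) == len(signatures)]
    else:
        lists = _normalized_rank_lists(signatures)
        rra = rra_score(lists)
        genes = list(rra[rra < rra_threshold].index)
        table = pd.DataFrame(
            {
                "score": rra.loc[genes],
                "rank_product": [best_rp.get(g, np.nan) for g in genes],
                "selected_by": "rra",
                "datasets": [",".join(sources.get(g, [])) for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        ).sort_values("score", kind="mergesort")
        if table.empty:
            warnings.warn("RRA aggregation selected no genes")
        return Signature(table=table)

    table = pd.DataFrame(
        {
            "score": [best_score[g] for g in genes],
            "rank_product": [best_rp[g] for g in genes],
            "selected_by": "rp",
            "datasets": [",".join(sources[g]) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    ).sort_values("score", kind="mergesort")
    if table.empty:
        warnings.warn(f"{method} aggregation produced an empty signature")
    return Signature(table=table)
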