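"""Core in-memory containers shared across the screening pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG_EXPRESSION = "log_expression"
_SCALES = (RAW_COUNTS, LOG_EXPRESSION)


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with per-sample annotations.

    ``values`` is a genes x samples DataFrame.  ``scale`` declares whether
    entries are raw integer counts or already log-normalized expression;
    the two scales are routed through different processing pipelines
    downstream.  ``annotations`` is indexed by sample and must contain a
    ``Group`` column; a ``Batch`` column is optional (absent means a
    single-batch design).
    """

    values: pd.DataFrame
    scale: str
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if "Group" not in self.annotations.columns:
            raise ValueError("sample annotations must contain a 'Group' column")
        missing = [s for s in self.values.columns if s not in self.annotations.index]
        if missing:
            raise ValueError(f"samples missing from annotation sheet: {missing[:5]}")
        # align annotation rows to matrix column order
        self.annotations = self.annotations.loc[self.values.columns]
        grp = self.annotations["Group"]
        if grp.isna().any() or (grp.astype(str).str.len() == 0).any():
            raise ValueError("every sample needs a non-empty Group label")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == RAW_COUNTS:
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integral")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.annotations["Group"].astype(str)

    @property
    def batches(self) -> pd.Series | None:
        if "Batch" in self.annotations.columns:
            return self.annotations["Batch"].astype(str)
        return None

    def subset_samples(self, samples) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values.loc[:, list(samples)],
            scale=self.scale,
            annotations=self.annotations.loc[list(samples)],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with per-gene provenance.

    ``sets`` maps set name -> ordered unique member list.  ``provenance``
    maps gene -> list of source set names (every source the gene appeared
    in, in input order).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) != len(set(members)):
                raise ValueError(f"set {name!r} has duplicate members")
        if not self.provenance:
            self.provenance = {
                g: [name for name, members in self.sets.items() if g in members]
                for g in self.all_genes()
            }

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class DEResult:
    """Per-gene statistics for one target-vs-other comparison."""

    target_group: str
    other_group: str
    table: pd.DataFrame  # index gene; columns logFC, t, p_value, adj_p_value, mean_expression

    @property
    def comparison(self) -> str:
        return f"{self.target_group}-{self.other_group}"


@dataclass
class RankProductResult:
    """Rank-product scores with their permutation probabilities.

    ``table`` is indexed by gene with columns ``rank_product`` (sum of
    natural-log ranks across comparisons) and ``score`` (empirical
    probability that a permuted rank product falls strictly below the
    observed one; smaller = more consistently top-ranked).
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    per_comparison_ranks: pd.DataFrame | None = None  # genes x comparisons


@dataclass
class Signature:
    """An ordered marker list (ascending score) with selection metadata."""

    table: pd.DataFrame  # index gene; columns score, rank_product, selected_by

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("signature contains duplicate genes")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SnrTable:
    """Per-gene signal/background summary on the percentile scale.

    Columns: ``x_signal`` (median of the normal fit to the gene's signal
    percentiles), ``x_background``, ``sd_background`` and ``snr`` =
    (x_signal - x_background) / sd_background.
    """

    table: pd.DataFrame
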