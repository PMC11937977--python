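"""Run configuration: defaults, validation, normalization."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

RANK_STATISTICS = ("p_value", "adj_p_value", "logFC")
AGGREGATIONS = ("RRA", "union", "intersect")


@dataclass
class RunConfig:
    """All tunables of the screening workflow.

    Defaults follow the recommended settings: permutation-score threshold
    0.05, no fold-change threshold in the DE test, K=1000 permutations,
    genes ranked by p-value, union aggregation across datasets, SNR
    cutoff 1 for background refinement.
    """

    target_group: str = ""
    rank_statistic: str = "p_value"
    score_threshold: float = 0.05
    lfc_threshold: float = 0.0
    n_permutations: int = 1000
    seed: int | None = None
    keep_top: int | None = None
    keep_group: tuple[str, ...] | None = None
    aggregation: str = "union"
    snr_threshold: float = 1.0
    smoothed_score: bool = False
    two_sided_markers: bool = False
    # expression filtering (counts route)
    filter_min_count: float = 10.0
    filter_min_total: float = 15.0
    # expression filtering (log-expression route)
    logexpr_min_mean: float = 1.0
    logexpr_floor: float = 1.0

    def __post_init__(self) -> None:
        if not self.target_group:
            raise ValueError("target_group is required")
        if self.rank_statistic not in RANK_STATISTICS:
            raise ValueError(f"rank_statistic must be one of {RANK_STATISTICS}")
        if not (0 < self.score_threshold <= 1):
            raise ValueError("score_threshold must lie in (0, 1]")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be non-negative")
        if self.keep_top is not None:
            if self.keep_top < 1:
                raise ValueError("keep_top must be a positive integer")
            if not self.keep_group:
                raise ValueError("keep_top requires keep_group")
        if self.keep_group is not None:
            self.keep_group = tuple(self.keep_group)


def validate_config(raw: dict) -> RunConfig:
    """Normalize a raw config mapping into a RunConfig with defaults filled.

    Unknown keys are rejected rather than ignored, so typos fail loudly.
    """
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
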