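"""Synthetic multi-group bulk-expression data with known ground truth.

Generates negative-binomial counts with log-normal base means — the
standard generative family for bulk RNA-seq — with planted group-specific
marker genes (multiplied by 2^lfc in their group), optional multiplicative
batch noise, and matched background datasets in which a chosen fraction
of the planted markers are also highly expressed (ubiquitous).  Every
stage of the screening workflow can thereby be tested against truth
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import RAW_COUNTS, ExpressionDataset


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    marker_genes: dict[str, list[str]]  # group -> planted marker genes
    ubiquitous_genes: list[str] = field(default_factory=list)
    base_means: pd.Series | None = None
    lfc: float = 0.0
    batch_sd: float = 0.0
    dispersion: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        all_markers = [g for ms in self.marker_genes.values() for g in ms]
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("marker sets must be disjoint across groups")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = m + d*m^2)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(
    n_groups: int = 4,
    n_per_group: int = 5,
    n_genes: int = 2000,
    n_markers_per_group: int = 50,
    lfc: float = 2.0,
    n_batches: int = 1,
    batch_sd: float = 0.0,
    dispersion: float = 0.1,
    seed: int | None = None,
    truth: SimulationTruth | None = None,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Simulate a labeled count dataset with planted group markers.

    Base means are log-normal (log2 mean 5, SD 2, floored at 1); each
    group's markers are up-shifted by 2^lfc in that group's samples;
    samples get a log-normal batch factor (SD ``batch_sd``) shared within
    a batch, plus mild library-size variation; counts are negative
    binomial with the given dispersion.  Deterministic given ``seed``.

    Pass an existing ``truth`` to draw a replicate dataset with the same
    planted markers and base means but fresh sampling noise — the setting
    multi-dataset aggregation is meant for.
    """
    if n_markers_per_group * n_groups > n_genes:
        raise ValueError("planted markers exceed the number of genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    groups = [f"G{chr(ord('A') + k)}" for k in range(n_groups)]
    samples = [f"{g}_s{j}" for g in groups for j in range(n_per_group)]
    sample_group = np.repeat(groups, n_per_group)

    if truth is not None:
        if list(truth.base_means.index) != genes or sorted(truth.marker_genes) != groups:
            raise ValueError("supplied truth does not match the requested dimensions")
        base = truth.base_means.to_numpy(dtype=float).copy()
        marker_genes = {g: list(ms) for g, ms in truth.marker_genes.items()}
    else:
        base = 2.0 ** rng.normal(5.0, 2.0, size=n_genes)
        base = np.maximum(base, 1.0)
        marker_genes = {}
        marker_idx = rng.choice(n_genes, size=n_markers_per_group * n_groups, replace=False)
        for k, g in enumerate(groups):
            idx = marker_idx[k * n_markers_per_group:(k + 1) * n_markers_per_group]
            marker_genes[g] = [genes[i] for i in idx]

    mean = np.tile(base[:, None], (1, len(samples)))
    for g in groups:
        cols = np.where(sample_group == g)[0]
        rows = [genes.index(m) for m in marker_genes[g]]
        mean[np.ix_(rows, cols)] *= 2.0 ** lfc

    batches = np.tile(np.arange(n_batches), -(-len(samples) // n_batches))[: len(samples)]
    rng.shuffle(batches)
    if batch_sd > 0 and n_batches > 1:
        batch_factor = 2.0 ** rng.normal(0.0, batch_sd, size=n_batches)
        mean = mean * batch_factor[batches]
    depth = 2.0 ** rng.normal(0.0, 0.25, size=len(samples))
    mean = mean * depth

    counts = _nb_counts(rng, mean, dispersion)
    values = pd.DataFrame(counts, index=genes, columns=samples)
    ann = pd.DataFrame({"Group": sample_group}, index=samples)
    if n_batches > 1:
        ann["Batch"] = [f"b{b}" for b in batches]
    dataset = ExpressionDataset(values=values, scale=RAW_COUNTS, annotations=ann)
    truth = SimulationTruth(
        marker_genes=marker_genes,
        base_means=pd.Series(base, index=genes),
        lfc=lfc,
        batch_sd=batch_sd,
        dispersion=dispersion,
        seed=seed,
    )
    return dataset, truth


def generate_background(
    truth: SimulationTruth,
    target_group: str,
    overlap_fraction: float = 0.5,
    n_samples: int = 20,
    dispersion: float = 0.1,
    seed: int | None = None,
) -> tuple[ExpressionDataset, list[str]]:
    """Simulate a background (microenvironment) dataset for SNR testing.

    The first ``overlap_fraction`` share of the target group's planted
    markers are made highly expressed in the background (ubiquitous);
    the remaining markers are expressed low.  Non-marker genes keep their
    base means.  Returns the dataset and the list of planted-ubiquitous
    genes — the ones the SNR filter should remove.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if truth.base_means is None:
        raise ValueError("truth lacks base means")
    rng = np.random.default_rng(seed)
    genes = list(truth.base_means.index)
    markers = truth.marker_genes[target_group]
    n_ubiq = int(round(overlap_fraction * len(markers)))
    ubiquitous = markers[:n_ubiq]
    quiet = markers[n_ubiq:]

    mean = truth.base_means.to_numpy(dtype=float).copy()
    gidx = {g: i for i, g in enumerate(genes)}
    high = np.quantile(mean, 0.95)
    for g in ubiquitous:
        mean[gidx[g]] = max(mean[gidx[g]] * 16.0, high)
    for g in quiet:
        mean[gidx[g]] = max(mean[gidx[g]] / 16.0, 0.5)

    samples = [f"bg_s{j}" for j in range(n_samples)]
    depth = 2.0 ** rng.normal(0.0, 0.25, size=n_samples)
    M = mean[:, None] * depth[None, :]
    counts = _nb_counts(rng, M, dispersion)
    values = pd.DataFrame(counts, index=genes, columns=samples)
    ann = pd.DataFrame({"Group": ["background"] * n_samples}, index=samples)
    dataset = ExpressionDataset(values=values, scale=RAW_COUNTS, annotations=ann)
    return dataset, ubiquitous
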