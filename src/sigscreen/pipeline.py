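"""End-to-end workflow: pool -> pairwise DE -> rank-product selection ->
pool constraining -> multi-dataset aggregation -> SNR refinement."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .datatypes import ExpressionDataset, GeneSetCollection, Signature, SnrTable
from .de import run_pairwise_de
from .rankprod import compute_rp, permutation_score, rank_genes, select_genes
from .selection import aggregate_signatures, constrain_to_pool
from .snr import compute_snr, filter_by_snr, percentile_transform

log = logging.getLogger("sigscreen")


@dataclass
class RunManifest:
    """Audit record of one workflow run: config echo, version, seed, and
    per-stage gene counts."""

    config: dict
    version: str = __version__
    seed: int | None = None
    stage_counts: dict[str, int] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "seed": self.seed,
                "stage_counts": self.stage_counts,
                "started": self.started,
                "finished": self.finished,
            },
            indent=2,
        )


def screen_dataset(
    dataset: ExpressionDataset,
    config: RunConfig,
) -> tuple[pd.DataFrame, list]:
    """DE + rank-product selection on a single dataset.

    Returns the selected-gene table (score-ordered, with selection
    reasons) and the per-comparison DE results.
    """
    de_results = run_pairwise_de(dataset, config)
    ranks = rank_genes(de_results, statistic=config.rank_statistic)
    rp_result = permutation_score(
        ranks,
        n_permutations=config.n_permutations,
        seed=config.seed,
        smoothed=config.smoothed_score,
    )
    logfc = pd.DataFrame({r.comparison: r.table["logFC"] for r in de_results}).loc[ranks.index]
    selected = select_genes(rp_result, config, direction_logfc=logfc)
    return selected, de_results


def run_workflow(
    datasets: dict[str, ExpressionDataset],
    config: RunConfig,
    pool: GeneSetCollection | None = None,
    background: ExpressionDataset | None = None,
    out_dir: str | Path | None = None,
    keep_intermediates: bool = False,
) -> tuple[Signature, SnrTable | None, RunManifest]:
    """Run the full screening workflow over one or more datasets.

    Per dataset: pairwise DE against every other group, rank-product
    permutation scoring, threshold selection, constraint to the marker
    pool.  Multiple datasets are then aggregated (union / intersect /
    RRA).  With a background dataset, the signature is refined by the
    percentile SNR filter with pool genes protected.  Writes
    signature.tsv, snr.tsv (if applicable) and manifest.json to
    ``out_dir`` when given; per-comparison DE tables too when
    ``keep_intermediates``.
    """
    manifest = RunManifest(
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        seed=config.seed,
        started=datetime.now(timezone.utc).isoformat(),
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    per_dataset: dict[str, Signature] = {}
    for name, dataset in datasets.items():
        log.info("=== dataset %s: DE + rank-product selection ===", name)
        selected, de_results = screen_dataset(dataset, config)
        manifest.stage_counts[f"{name}:post_filter"] = int(len(de_results[0].table))
        manifest.stage_counts[f"{name}:post_rp"] = int(len(selected))
        log.info("dataset %s: %d genes post-filter, %d selected by rank product",
                 name, len(de_results[0].table), len(selected))
        if keep_intermediates and out is not None:
            for r in de_results:
                r.table.rename_axis("gene").to_csv(out / f"de_{name}_{r.comparison}.tsv", sep="\t")
        sig = constrain_to_pool(selected, pool)
        manifest.stage_counts[f"{name}:post_pool"] = int(len(sig))
        per_dataset[name] = sig

    if len(per_dataset) == 1:
        signature = next(iter(per_dataset.values()))
    else:
        log.info("=== aggregating %d dataset signatures (%s) ===",
                 len(per_dataset), config.aggregation)
        signature = aggregate_signatures(per_dataset, method=config.aggregation)
    manifest.stage_counts["post_aggregate"] = int(len(signature))

    snr_table: SnrTable | None = None
    if background is not None:
        log.info("=== SNR background refinement ===")
        target_samples = [
            s for s, g in datasets[next(iter(datasets))].groups.items()
            if g == config.target_group
        ]
        signal = datasets[next(iter(datasets))].subset_samples(target_samples)
        snr_table = compute_snr(percentile_transform(signal), percentile_transform(background))
        signature = filter_by_snr(signature, snr_table, threshold=config.snr_threshold, pool=pool)
    manifest.stage_counts["post_snr"] = int(len(signature))
    manifest.finished = datetime.now(timezone.utc).isoformat()

    if len(signature) == 0:
        log.warning("final signature is empty")
    if out is not None:
        from .io import write_signature, write_snr_table

        write_signature(signature, out / "signature.tsv", snr_table=snr_table)
        if snr_table is not None:
            write_snr_table(snr_table, out / "snr.tsv")
        (out / "manifest.json").write_text(manifest.to_json())
    return signature, snr_table, manifest


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
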