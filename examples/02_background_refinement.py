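"""Refine a signature against background (microenvironment) expression.

Half of the target group's planted markers are made ubiquitously high in
a simulated background dataset; the percentile SNR filter should remove
exactly those while keeping the genuinely specific markers.
"""

import sigscreen as sg
from sigscreen.snr import compute_snr, filter_by_snr, percentile_transform

dataset, truth = sg.generate_counts(seed=0)
config = sg.RunConfig(target_group="GA", seed=0)
selected, _ = sg.screen_dataset(dataset, config)

background, ubiquitous = sg.generate_background(
    truth, target_group="GA", overlap_fraction=0.5, seed=1,
)
target_samples = [s for s, g in dataset.groups.items() if g == "GA"]
snr = compute_snr(
    percentile_transform(dataset.subset_samples(target_samples)),
    percentile_transform(background),
)
refined = filter_by_snr(sg.Signature(table=selected), snr, threshold=1.0)

found = set(selected.index)
removed = found - set(refined.genes)
print(f"selected before refinement: {len(found)}")
print(f"removed by SNR < 1:         {len(removed)}")
print(f"ubiquitous markers removed: {len(removed & set(ubiquitous))} "
      f"of {len(found & set(ubiquitous))} selected")
spec = set(truth.marker_genes['GA']) - set(ubiquitous)
print(f"specific markers removed:   {len(removed & spec)} of {len(found & spec)} selected")
print("\nSNR of three example genes (positive = higher in signal than background):")
print(snr.table.loc[sorted(found)[:3]].round(3))
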