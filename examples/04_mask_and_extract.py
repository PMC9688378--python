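"""Grand-average significance mask and masked MRBD extraction.

Runs a cohort through the full EEG side of the pipeline: per-trial Morlet
power, condition averages, dB baselining, the Bonferroni-thresholded
grand-average masks, and the per-participant MRBD table, then compares
extracted values with the injected ground truth.
"""

from betadesync import NeuralSimConfig
from betadesync.pipeline import process_cohort

out = process_cohort(NeuralSimConfig(n_per_group=4, n_trials=6, seed=21))

for stage, mask in out["masks"].items():
    print(
        f"{stage:9s} mask: {mask.included_fraction:5.1f}% of beta cells "
        f"(cell threshold p < {mask.cell_threshold:.2e})"
    )

merged = out["mrbd_table"].merge(
    out["truth"],
    on=["participant", "group", "electrode", "region", "hemisphere",
        "condition", "stage"],
)
summary = (
    merged.groupby(["stage", "region"])[["depth_db", "mrbd_db"]]
    .mean()
    .round(2)
    .rename(columns={"depth_db": "injected", "mrbd_db": "extracted"})
)
print("\ninjected vs extracted MRBD (dB, cohort means):")
print(summary)
print(
    "\nThe execution mask covers the whole beta band x window (the effect\n"
    "is strong everywhere); the planning mask covers roughly the post-onset\n"
    "part. Extracted masked means track the injected depths closely."
)
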