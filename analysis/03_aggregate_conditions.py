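#!/usr/bin/env python
"""Aggregate per-image metrics: condition summaries, relative values,
compartment calls.

The untreated skin section of each (surrogate, timepoint) stratum is the
100% reference; penetrated signal deeper than the SC reaches the viable
epidermis, deeper than 110 µm counts as transdermal.
"""

from pathlib import Path

import pandas as pd

from dermaquant.aggregate import aggregate_metrics, classify_conditions, relative_to_control
from dermaquant.presets import default_manifest

out = Path("results/study")
per_image = pd.read_csv(out / "per_image_metrics.csv")
manifest = default_manifest()

summary, per_ear = aggregate_metrics(per_image.dropna(subset=["arosa_mgv_per_px"]), manifest)
summary = relative_to_control(summary, manifest)
summary.to_csv(out / "condition_summary.csv", index=False)
per_ear.to_csv(out / "per_ear_means.csv", index=False)

calls = classify_conditions(summary[summary["condition"] != manifest.blank_label])
calls.to_csv(out / "compartment_calls.csv", index=False)

cols = ["condition", "n_images", "arosa_mgv_per_px_rel_pct", "mpd_um_mean", "sct_um_mean"]
print(summary[cols].round(1).to_string(index=False))
print()
print(calls[["condition", "compartment", "mpd_um"]].round(1).to_string(index=False))
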