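#!/usr/bin/env python
"""Compare skin sections statistically within each stratum.

For every (surrogate, timepoint) stratum and metric, runs the
assumption-gated decision tree (Shapiro–Wilk → Levene → ANOVA/Welch/
Kruskal–Wallis with Tukey/Games–Howell/Dunn) on pooled images and on
per-ear means, and writes the full report with decision traces to
results/study/stats_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from dermaquant.aggregate import aggregate_metrics
from dermaquant.pipeline import PipelineConfig, _stats_report
from dermaquant.presets import default_manifest

out = Path("results/study")
per_image = pd.read_csv(out / "per_image_metrics.csv")
manifest = default_manifest()
_, per_ear = aggregate_metrics(per_image.dropna(subset=["arosa_mgv_per_px"]), manifest)

report = _stats_report(per_image, per_ear, manifest, PipelineConfig())
(out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))

for stratum in report["strata"]:
    if "skipped" in stratum:
        continue
    cmp = stratum["metrics"]["arosa_mgv_per_px"]["pooled_images"]
    stars = {f"{p['A']} vs {p['B']}": p["stars"] for p in cmp["pairwise"]}
    print(f"{stratum['surrogate']}/{stratum['timepoint']}: "
          f"{cmp['omnibus_test']} p={cmp['omnibus_p']:.3g} ({cmp['posthoc_test']}) {stars}")
print(f"full report: {out/'stats_report.json'}")
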