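#!/usr/bin/env python
"""Simulate the full study design and persist its ground truth.

Generates the default synthetic study — 3 ears x 12 conditions (3 skin
sections x 2 AI surrogates x 2 application time points) x 40 images per
biopsy, plus 20 dye-free blanks per ear — and writes the ground-truth table
to results/study/.  The TIFF images go to scratch/dataset/ (bulk data,
regenerable from the seed).
"""

from pathlib import Path

from dermaquant.presets import default_manifest
from dermaquant.synthgen import GeneratorParams, generate_study, write_dataset

SEED = 1

out = Path("results/study")
out.mkdir(parents=True, exist_ok=True)

manifest = default_manifest()
dataset = generate_study(manifest, GeneratorParams(), seed=SEED)
paths = write_dataset(dataset, "scratch/dataset", overwrite=True)
dataset.truth_table.to_csv(out / "truth.csv", index=False)

counts = dataset.truth_table.groupby("condition").size()
print(f"simulated {len(dataset.images)} images over {len(counts)} conditions (seed {SEED})")
print(counts.to_string())
print(f"images in {paths['truth'].parent}, truth table in {out/'truth.csv'}")
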