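"""Validation experiments on synthetic studies with known ground truth.

These functions define the package's benchmark conditions: each generates
synthetic data at the study's design scale, runs the measurement pipeline,
and returns the recovered quantity.  They are used both by the test suite
and by the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import imaging, stats
from .aggregate import aggregate_metrics, relative_to_control
from .presets import ConditionPreset, StudyManifest
from .synthgen import GeneratorParams, generate_section_image, generate_study

__all__ = [
    "sct_recovery",
    "surface_recovery",
    "blank_specificity",
    "arosa_monotonicity",
    "mpd_monotonicity",
    "effect_size_recovery",
    "control_mpd",
    "type_one_error",
    "power_at_shift",
]

#: treated/control penetrated-amount fractions spanning the effect range the
#: emulated study reports; used by the effect-size recovery benchmark
EFFECT_FRACTIONS = (0.80, 0.66, 0.54, 0.32)


def _seed(root: int, tag: int) -> int:
    return int(np.random.SeedSequence([root, tag]).generate_state(1)[0] % (2**31))


def sct_recovery(seed: int, n_images: int = 50) -> dict:
    """Mean absolute SCT error (µm) on low-noise dye-free renders.

    True SCT is uniform in 10–40 µm; the target is a mean absolute error
    below one pixel (2.84 µm) at the study's scale.
    """
    rng = np.random.default_rng(_seed(seed, 1))
    errors = []
    for i in range(n_images):
        params = GeneratorParams(
            sct_um=float(rng.uniform(10.0, 40.0)),
            dye_amount=0.0,
            hotspot_density=0.0,
            noise_sd=1.0,
        )
        image, truth = generate_section_image(params, _seed(seed, 100 + i))
        surface = imaging.detect_surface(image)
        profile = imaging.measure_sct(image, surface)
        errors.append(abs(profile.sct_um_mean - truth.sct_eff_um))
    return {"mae_um": float(np.mean(errors)), "n": n_images}


def surface_recovery(seed: int, n_images: int = 200) -> dict:
    """Mean absolute surface-localisation error (px) on noisy renders."""
    errors = []
    for i in range(n_images):
        params = GeneratorParams(surface_roughness_px=1.0, dye_amount=0.0)
        image, truth = generate_section_image(params, _seed(seed, 300 + i))
        detected = imaging.detect_surface(image)
        ok = detected != imaging.MISSING
        errors.append(float(np.mean(np.abs(detected[ok] - truth.surface_rows[ok]))))
    return {"mae_px": float(np.mean(errors)), "n": n_images}


def _two_condition_manifest(images_per_biopsy: int, ears: int = 3) -> StudyManifest:
    return StudyManifest(
        ears=[f"ear{i+1}" for i in range(ears)],
        conditions=[
            ConditionPreset(1, "hydrophilic", "during"),
            ConditionPreset(1, "lipophilic", "during",
                            surrogate_base={"dye_amount": 1.6, "dye_decay_um": 0.3636}),
        ],
        images_per_biopsy=images_per_biopsy,
    )


def blank_specificity(seed: int, images_per_biopsy: int = 20) -> dict:
    """Blank-condition mean AROSA as % of the dye-present control mean."""
    manifest = _two_condition_manifest(images_per_biopsy)
    dataset = generate_study(manifest, GeneratorParams(), seed=_seed(seed, 2))
    from .pipeline import PipelineConfig, measure_dataset

    per_image = measure_dataset(dataset, PipelineConfig())
    means = per_image.groupby("condition")["arosa_mgv_per_px"].mean()
    blank = float(means[manifest.blank_label])
    out = {"n": int(per_image.shape[0])}
    for preset in manifest.conditions:
        out[f"blank_pct_of_{preset.surrogate}"] = 100.0 * blank / float(means[preset.label])
    out["blank_pct_of_control"] = max(
        v for k, v in out.items() if k.startswith("blank_pct_of_")
    )
    return out


def _level_means(
    seed: int,
    tag: int,
    field_name: str,
    levels: tuple[float, ...],
    metric: str,
    n_per_level: int,
    base: GeneratorParams | None = None,
) -> dict:
    """Condition-mean metric per generator-parameter level, fixed threshold."""
    base = base or GeneratorParams()
    blank = dataclasses.replace(base, dye_amount=0.0)
    blanks = [generate_section_image(blank, _seed(seed, tag * 1000 + 900 + i))[0] for i in range(20)]
    threshold = imaging.compute_threshold(blanks, "control_stats")
    means = {}
    for li, level in enumerate(levels):
        vals = []
        for i in range(n_per_level):
            params = dataclasses.replace(base, **{field_name: getattr(base, field_name) * level})
            image, _ = generate_section_image(params, _seed(seed, tag * 1000 + li * 100 + i))
            surface = imaging.detect_surface(image)
            m = imaging.analyze_image(image, surface, threshold)
            vals.append(m.arosa_mgv_per_px if metric == "arosa" else m.mpd_um)
        means[level] = float(np.mean(vals))
    return means


def arosa_monotonicity(seed: int, n_per_level: int = 20) -> dict:
    """Condition-mean AROSA across dye-amount levels 0.25/0.5/1/2x."""
    means = _level_means(seed, 3, "dye_amount", (0.25, 0.5, 1.0, 2.0), "arosa", n_per_level)
    ordered = [means[l] for l in (0.25, 0.5, 1.0, 2.0)]
    return {
        "means": means,
        "strictly_increasing": bool(np.all(np.diff(ordered) > 0)),
        "n": n_per_level * 4,
    }


def mpd_monotonicity(seed: int, n_per_level: int = 20) -> dict:
    """Condition-mean MPD across dye-decay levels at fixed amount/threshold."""
    base = dataclasses.replace(GeneratorParams(), dye_decay_um=40.0, dye_amount=8000.0)
    levels = (0.5, 0.875, 1.25, 1.625)  # 20–65 µm e-folding depths
    means = _level_means(seed, 4, "dye_decay_um", levels, "mpd", n_per_level, base=base)
    ordered = [means[l] for l in levels]
    return {
        "means": means,
        "strictly_increasing": bool(np.all(np.diff(ordered) > 0)),
        "n": n_per_level * 4,
    }


def effect_size_recovery(seed: int, images_per_biopsy: int = 14, ears: int = 3) -> dict:
    """Recover treated/control relative AROSA for known dye fractions.

    Treated conditions scale the control dye amount by the study's reported
    effect range ({0.80, 0.66, 0.54, 0.32}); recovered relative AROSA should
    land within ±10 percentage points of 100·fraction with ≥ 40
    images/condition (3 ears × 14 biopsies).
    """
    conditions = [ConditionPreset(1, "hydrophilic", "during")]
    # sections 2/3 at the two timepoints give four non-control design slots
    slots = [(2, "during"), (3, "during"), (2, "after"), (3, "after")]
    ctrl_after = ConditionPreset(1, "hydrophilic", "after")
    conditions.append(ctrl_after)
    frac_by_label = {}
    for (section, timepoint), frac in zip(slots, EFFECT_FRACTIONS):
        p = ConditionPreset(section, "hydrophilic", timepoint, modifiers={"dye_amount": frac})
        conditions.append(p)
        frac_by_label[p.label] = frac
    manifest = StudyManifest(
        ears=[f"ear{i+1}" for i in range(ears)],
        conditions=conditions,
        images_per_biopsy=images_per_biopsy,
    )
    dataset = generate_study(manifest, GeneratorParams(), seed=_seed(seed, 5))
    from .pipeline import PipelineConfig, measure_dataset

    per_image = measure_dataset(dataset, PipelineConfig())
    summary, _ = aggregate_metrics(per_image, manifest)
    summary = relative_to_control(summary, manifest)
    rel = summary.set_index("condition")["arosa_mgv_per_px_rel_pct"]
    out: dict = {"n_per_condition": images_per_biopsy * ears, "recovered": {}, "expected": {}}
    for label, frac in frac_by_label.items():
        out["recovered"][label] = float(rel[label])
        out["expected"][label] = 100.0 * frac
    out["max_abs_error_pp"] = max(
        abs(out["recovered"][l] - out["expected"][l]) for l in frac_by_label
    )
    out["control_rel_pct"] = float(rel["s1-hydrophilic-during"])
    return out


def control_mpd(seed: int, images_per_biopsy: int = 40) -> dict:
    """Mean penetration depth of the two surrogates on untreated skin."""
    manifest = _two_condition_manifest(images_per_biopsy)
    dataset = generate_study(manifest, GeneratorParams(), seed=_seed(seed, 6))
    from .pipeline import PipelineConfig, measure_dataset

    per_image = measure_dataset(dataset, PipelineConfig())
    means = per_image.groupby("condition")["mpd_um"].mean()
    sct = per_image.groupby("condition")["sct_um"].mean()
    return {
        "mpd_hydrophilic_um": float(means["s1-hydrophilic-during"]),
        "mpd_lipophilic_um": float(means["s1-lipophilic-during"]),
        "sct_lipophilic_um": float(sct["s1-lipophilic-during"]),
        "n_per_condition": images_per_biopsy * 3,
    }


def type_one_error(seed: int, reps: int = 2000, n: int = 20, k_groups: int = 3) -> dict:
    """Rejection rate of the full decision tree under a normal null."""
    rng = np.random.default_rng(_seed(seed, 7))
    rejections = 0
    for _ in range(reps):
        groups = [(f"g{j}", rng.normal(0.0, 1.0, n)) for j in range(k_groups)]
        cmp = stats.compare_groups(stats.GroupedSample("null", groups), include_posthoc=False)
        rejections += cmp.omnibus_p < 0.05
    return {"rejection_rate": rejections / reps, "n": reps}


def power_at_shift(seed: int, reps: int = 500, n: int = 40, shift_sd: float = 1.5) -> dict:
    """Rejection rate with one of three groups shifted by ``shift_sd``·SD."""
    rng = np.random.default_rng(_seed(seed, 8))
    rejections = 0
    for _ in range(reps):
        groups = [
            ("g0", rng.normal(0.0, 1.0, n)),
            ("g1", rng.normal(0.0, 1.0, n)),
            ("g2", rng.normal(shift_sd, 1.0, n)),
        ]
        cmp = stats.compare_groups(stats.GroupedSample("shift", groups), include_posthoc=False)
        rejections += cmp.omnibus_p < 0.05
    return {"rejection_rate": rejections / reps, "n": reps}
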