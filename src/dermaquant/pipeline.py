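"""End-to-end orchestration.

One pipeline run processes one study: synthetic generation (or ingestion of
a written dataset) → per-image measurements → condition aggregation and
control normalization → compartment calls → grouped statistics, with the
effective configuration, a log and tidy CSV artifacts persisted next to the
results.  All randomness flows from a single root seed, split
deterministically per stage, so a run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import imaging, stats, synthgen
from .errors import DermaquantError, ManifestError
from .presets import StudyManifest, default_manifest

__all__ = ["PipelineConfig", "run_pipeline", "validate_manifest", "measure_dataset"]

log = logging.getLogger("dermaquant")


@dataclass
class PipelineConfig:
    """Serializable run configuration.

    Defaults reproduce the emulated study's constants: 2.84 µm/px scale,
    α = 0.05, three ears with ≥ 12 cuts and ≥ 40 images per biopsy.
    """

    input_dir: str | None = None        # read a written dataset instead of synthesising
    preset_file: str | None = None      # condition presets (package default if None)
    seed: int = 0
    scale_um_per_px: float = 2.84
    threshold_method: str = "control_stats"
    threshold_k: float = 3.0
    smoothing_window_px: int = 5
    background_quantile: float = 0.99
    background_offset: float = 20.0
    boundary_fraction: float = 0.5
    n_lines: int = 10
    epidermis_um: float = agg.DEFAULT_EPIDERMIS_UM
    alpha: float = 0.05
    out_dir: str = "results/run"
    generator: dict = field(default_factory=dict)  # overrides for GeneratorParams fields
    manifest: dict = field(default_factory=dict)   # overrides for StudyManifest fields

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _base_params(config: PipelineConfig) -> synthgen.GeneratorParams:
    params = synthgen.GeneratorParams(scale_um_per_px=config.scale_um_per_px)
    for k, v in config.generator.items():
        if not hasattr(params, k):
            raise ManifestError(f"unknown generator override {k!r}")
        setattr(params, k, v)
    return params


def measure_dataset(dataset: synthgen.StudyDataset, config: PipelineConfig) -> pd.DataFrame:
    """Per-image metrics table: SCT, AF-SC, threshold, AROSA, MPD, flags.

    Autofluorescence thresholds come from each ear's dye-free blank images
    (``control_stats``); with no blanks in the dataset the per-image Otsu
    fallback is used.  Images whose measurement fails are reported with an
    ERROR flag rather than aborting the run.
    """
    blanks: dict[str, list[synthgen.SectionImage]] = {}
    blank_label = dataset.manifest.blank_label
    for img in dataset.images:
        if img.condition == blank_label:
            blanks.setdefault(img.ear_id, []).append(img)

    thresholds: dict[str, imaging.ThresholdResult] = {}
    if config.threshold_method == "control_stats" and blanks:
        for ear, imgs in blanks.items():
            thresholds[ear] = imaging.compute_threshold(imgs, "control_stats", config.threshold_k)
            log.info("threshold[%s] = %.2f (control_stats over %d blanks)", ear, thresholds[ear].value, len(imgs))

    meta = dataset.truth_table.set_index("image_id") if not dataset.truth_table.empty else None
    rows = []
    for img in dataset.images:
        rec: dict = {
            "image_id": img.image_id,
            "ear": img.ear_id,
            "condition": img.condition,
            "cut_index": img.cut_index,
        }
        if meta is not None and img.image_id in meta.index:
            for col in ("skin_section", "surrogate", "timepoint"):
                if col in meta.columns:
                    rec[col] = meta.at[img.image_id, col]
        try:
            surface = imaging.detect_surface(
                img,
                smoothing_window_px=config.smoothing_window_px,
                background_quantile=config.background_quantile,
                background_offset=config.background_offset,
            )
            profile = imaging.measure_sct(
                img,
                surface,
                n_lines=config.n_lines,
                boundary_fraction=config.boundary_fraction,
                smoothing_window_px=config.smoothing_window_px,
            )
            if img.ear_id in thresholds:
                thr = thresholds[img.ear_id]
            else:
                thr = imaging.compute_threshold(img, "otsu")
            metrics = imaging.analyze_image(img, surface, thr)
            rec.update(
                sct_um=profile.sct_um_mean,
                sct_um_sd=profile.sct_um_sd,
                af_sc=profile.af_sc_mean,
                threshold=metrics.threshold_value,
                threshold_method=metrics.threshold_method,
                arosa_mgv_per_px=metrics.arosa_mgv_per_px,
                mpd_um=metrics.mpd_um,
                n_signal_px=metrics.n_signal_px,
                flags=";".join(sorted(metrics.flags)) if metrics.flags else "",
            )
        except DermaquantError as exc:
            log.warning("image %s failed: %s", img.image_id, exc)
            rec.update(
                sct_um=np.nan, sct_um_sd=np.nan, af_sc=np.nan, threshold=np.nan,
                threshold_method="", arosa_mgv_per_px=np.nan, mpd_um=np.nan,
                n_signal_px=0, flags=f"ERROR:{type(exc).__name__}",
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def _stats_report(per_image: pd.DataFrame, per_ear: pd.DataFrame,
                  manifest: StudyManifest, config: PipelineConfig) -> dict:
    """Compare skin sections per (surrogate, timepoint) stratum and metric.

    Pooled images are the canonical unit (matches figure annotations);
    per-ear means (n = ears) are reported alongside as the honest
    independent-unit analysis.
    """
    report: dict = {"strata": [], "alpha": config.alpha}
    flags = per_image["flags"].fillna("").astype(str)
    dye = per_image[(per_image["condition"] != manifest.blank_label)
                    & ~flags.str.startswith("ERROR")]
    for (surrogate, timepoint), sub in dye.groupby(["surrogate", "timepoint"]):
        entry: dict = {"surrogate": surrogate, "timepoint": timepoint, "metrics": {}}
        labels = sorted(sub["condition"].unique())
        if len(labels) < 2:
            entry["skipped"] = "insufficient groups (need >= 2 conditions)"
            log.info("stats skipped for stratum (%s, %s): only %d group(s)", surrogate, timepoint, len(labels))
            report["strata"].append(entry)
            continue
        for metric in agg.METRICS:
            groups = [(lab, sub.loc[sub["condition"] == lab, metric].to_numpy()) for lab in labels]
            cmp_pooled = stats.compare_groups(stats.GroupedSample(metric, groups), alpha=config.alpha)
            ear_sub = per_ear[per_ear["condition"].isin(labels)]
            ear_groups = [
                (lab, ear_sub.loc[ear_sub["condition"] == lab, metric].to_numpy()) for lab in labels
            ]
            cmp_ear = stats.compare_groups(stats.GroupedSample(metric, ear_groups), alpha=config.alpha)
            entry["metrics"][metric] = {
                "pooled_images": _comparison_dict(cmp_pooled),
                "per_ear_means": _comparison_dict(cmp_ear),
            }
            for line in cmp_pooled.trace:
                log.info("[%s/%s/%s] %s", surrogate, timepoint, metric, line)
        report["strata"].append(entry)
    return report


def _comparison_dict(c: stats.GroupComparison) -> dict:
    return {
        "omnibus_test": c.omnibus_test,
        "omnibus_statistic": c.omnibus_statistic,
        "omnibus_p": c.omnibus_p,
        "levene_p": c.levene_p,
        "posthoc_test": c.posthoc_test,
        "pairwise": c.pairwise.to_dict(orient="records"),
        "trace": c.trace,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the artifact paths and tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if config.input_dir:
            dataset = synthgen.load_dataset(config.input_dir)
            log.info("loaded %d images from %s", len(dataset.images), config.input_dir)
        else:
            manifest = default_manifest(config.preset_file, **config.manifest)
            dataset = synthgen.generate_study(manifest, _base_params(config), seed=config.seed)
            log.info("generated %d images (%d conditions, %d ears)",
                     len(dataset.images), len(manifest.conditions), len(manifest.ears))
            dataset.truth_table.to_csv(out / "truth.csv", index=False)

        per_image = measure_dataset(dataset, config)
        per_image.to_csv(out / "per_image_metrics.csv", index=False)

        summary, per_ear = agg.aggregate_metrics(per_image.dropna(subset=["arosa_mgv_per_px"]),
                                                 dataset.manifest)
        summary = agg.relative_to_control(summary, dataset.manifest)
        summary.to_csv(out / "condition_summary.csv", index=False)
        per_ear.to_csv(out / "per_ear_means.csv", index=False)

        dye_summary = summary[summary["condition"] != dataset.manifest.blank_label]
        calls = agg.classify_conditions(dye_summary, config.epidermis_um)
        calls.to_csv(out / "compartment_calls.csv", index=False)

        report = _stats_report(per_image, per_ear, dataset.manifest, config)
        (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))

        config.to_yaml(out / "effective_config.yaml")
        return {
            "out_dir": out,
            "per_image": per_image,
            "summary": summary,
            "per_ear": per_ear,
            "compartments": calls,
            "stats": report,
        }
    finally:
        log.removeHandler(handler)
        handler.close()


def validate_manifest(manifest: StudyManifest, per_image: pd.DataFrame) -> dict:
    """Report-only check of a metrics table against the study design."""
    violations: list[str] = []
    expected = set(manifest.condition_labels)
    if manifest.blanks_per_ear > 0:
        expected.add(manifest.blank_label)
    seen = set(per_image["condition"].unique()) if "condition" in per_image else set()
    for label in sorted(expected - seen):
        violations.append(f"missing condition: {label}")
    for label in sorted(seen - expected):
        violations.append(f"unmapped condition in data: {label}")
    for label in sorted(expected & seen):
        if label == manifest.blank_label:
            continue
        counts = per_image[per_image["condition"] == label].groupby("ear").size()
        for ear in manifest.ears:
            n = int(counts.get(ear, 0))
            if n == 0:
                violations.append(f"missing cell: condition {label}, ear {ear}")
            elif n < manifest.images_per_biopsy:
                violations.append(
                    f"below-minimum count: condition {label}, ear {ear}: "
                    f"{n} < {manifest.images_per_biopsy} images"
                )
    return {"n_violations": len(violations), "violations": violations}
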