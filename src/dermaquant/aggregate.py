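"""Condition-level aggregation, control normalization and compartment calls.

Per-image metrics are pooled per condition (mean ± SD, NO_SIGNAL images kept
as zeros so rarely penetrating conditions are not upward-biased), then turned
into relative values with the untreated skin section of each (surrogate,
timepoint) stratum fixed at exactly 100%.  Relative values carry the
condition's own relative standard deviation (RSD = 100·SD/mean).

The penetrated compartment is read off by comparing the mean penetration
depth with the SC thickness and the epidermis thickness (porcine ear
epidermis ≈ 100–110 µm; the conservative upper end, 110 µm, is the default
for declaring transdermal delivery): MPD ≤ SCT stays within the SC,
SCT < MPD ≤ epidermis reaches the viable epidermis, MPD > epidermis is
transdermal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ManifestError, ParameterError
from .presets import StudyManifest

__all__ = [
    "METRICS",
    "CompartmentCall",
    "aggregate_metrics",
    "relative_to_control",
    "classify_compartment",
    "classify_conditions",
]

METRICS = ("sct_um", "af_sc", "arosa_mgv_per_px", "mpd_um")

DEFAULT_EPIDERMIS_UM = 110.0


def aggregate_metrics(
    per_image: pd.DataFrame,
    manifest: StudyManifest,
    include_blanks: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-image rows per condition (and per ear for statistics).

    Returns ``(condition_summary, per_ear_means)``.  Raises for manifest
    conditions with zero images; warns (does not fail) when a biopsy is below
    the design minimum image count.
    """
    required = {"image_id", "condition", "ear", *METRICS}
    missing = required - set(per_image.columns)
    if missing:
        raise ManifestError(f"per-image table is missing columns: {sorted(missing)}")
    expected = list(manifest.condition_labels)
    if include_blanks and manifest.blanks_per_ear > 0:
        expected.append(manifest.blank_label)
    unmapped = set(per_image["condition"]) - set(expected)
    if unmapped:
        raise ManifestError(f"image rows map to no manifest cell: {sorted(unmapped)}")

    rows = []
    for label in expected:
        sub = per_image[per_image["condition"] == label]
        if sub.empty:
            raise ManifestError(f"condition {label!r} has zero images")
        if label != manifest.blank_label:
            per_ear_counts = sub.groupby("ear").size()
            low = per_ear_counts[per_ear_counts < manifest.images_per_biopsy]
            for ear, n in low.items():
                warnings.warn(
                    f"condition {label!r}, ear {ear}: {n} images is below the "
                    f"design minimum of {manifest.images_per_biopsy}",
                    stacklevel=2,
                )
        rec: dict = {"condition": label, "n_images": len(sub)}
        for m in METRICS:
            rec[f"{m}_mean"] = float(sub[m].mean())
            rec[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(rec)
    summary = pd.DataFrame(rows)

    meta_cols = [c for c in ("skin_section", "surrogate", "timepoint") if c in per_image.columns]
    if meta_cols:
        meta = per_image.groupby("condition")[meta_cols].first().reset_index()
        summary = summary.merge(meta, on="condition", how="left")

    per_ear = (
        per_image.groupby(["condition", "ear"])[list(METRICS)].mean().reset_index()
    )
    return summary, per_ear


def relative_to_control(
    summary: pd.DataFrame,
    manifest: StudyManifest,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Add ``<metric>_rel_pct`` / ``<metric>_rsd_pct`` columns per stratum.

    Relative value = 100 · condition mean / control mean, the control of each
    (surrogate, timepoint) stratum set to exactly 100%.  Blank conditions
    keep absolute values only.
    """
    out = summary.copy()
    for m in metrics:
        out[f"{m}_rel_pct"] = np.nan
        out[f"{m}_rsd_pct"] = np.nan
    if not {"surrogate", "timepoint"} <= set(out.columns):
        raise ManifestError("summary lacks surrogate/timepoint columns")

    for (surrogate, timepoint), idx in out.groupby(["surrogate", "timepoint"]).groups.items():
        if surrogate in ("none", None) or timepoint in ("none", None):
            continue
        control = manifest.control_label(str(surrogate), str(timepoint))
        ctrl_rows = out.loc[idx][out.loc[idx, "condition"] == control]
        if ctrl_rows.empty:
            raise ManifestError(f"control condition {control!r} missing from summary")
        for m in metrics:
            ctrl_mean = float(ctrl_rows[f"{m}_mean"].iloc[0])
            if ctrl_mean <= 0:
                raise ParameterError(
                    f"control mean for {m!r} in stratum ({surrogate}, {timepoint}) "
                    "is not positive; normalization undefined"
                )
            for i in idx:
                mean = float(out.at[i, f"{m}_mean"])
                sd = float(out.at[i, f"{m}_sd"])
                rel = 100.0 if out.at[i, "condition"] == control else 100.0 * mean / ctrl_mean
                out.at[i, f"{m}_rel_pct"] = rel
                out.at[i, f"{m}_rsd_pct"] = 100.0 * sd / mean if mean > 0 else np.nan
    return out


@dataclass
class CompartmentCall:
    """Which skin compartment the penetrated signal reached."""

    condition: str
    compartment: str  # within_SC | viable_epidermis | transdermal
    mpd_um: float
    sct_um: float
    epidermis_um: float


def classify_compartment(
    mpd_um: float,
    sct_um: float,
    epidermis_um: float = DEFAULT_EPIDERMIS_UM,
    condition: str = "",
) -> CompartmentCall:
    """Three-way compartment rule.

    Signal deeper than the SC reached the viable epidermis; deeper than the
    epidermis counts as transdermal.
    """
    if mpd_um < 0 or sct_um < 0 or epidermis_um < 0:
        raise ParameterError("mpd_um, sct_um and epidermis_um must be >= 0")
    if mpd_um <= sct_um:
        compartment = "within_SC"
    elif mpd_um <= epidermis_um:
        compartment = "viable_epidermis"
    else:
        compartment = "transdermal"
    return CompartmentCall(condition, compartment, mpd_um, sct_um, epidermis_um)


def classify_conditions(
    summary: pd.DataFrame, epidermis_um: float = DEFAULT_EPIDERMIS_UM
) -> pd.DataFrame:
    """Compartment call per condition from its mean MPD and mean SCT."""
    calls = [
        classify_compartment(
            float(r["mpd_um_mean"]), float(r["sct_um_mean"]), epidermis_um,
            condition=str(r["condition"]),
        )
        for _, r in summary.iterrows()
    ]
    return pd.DataFrame(
        {
            "condition": [c.condition for c in calls],
            "compartment": [c.compartment for c in calls],
            "mpd_um": [c.mpd_um for c in calls],
            "sct_um": [c.sct_um for c in calls],
            "epidermis_um": [c.epidermis_um for c in calls],
        }
    )
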