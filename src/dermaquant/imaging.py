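"""Per-image penetration measurements.

Four quantities are read off each vertical skin-section micrograph:

* **SCT** — stratum corneum thickness, measured along vertical lines from the
  detected skin surface to the SC lower boundary, converted to µm with the
  pixel scale (default 2.84 µm/px).
* **AF-SC** — SC autofluorescence, the mean grey value per pixel along each
  measured SCT line.  On dye-treated sections this is the sum of
  autofluorescence and dye that entered the SC.
* **AROSA** — the mean grey value per pixel of the whole image after an
  automated threshold removed the skin's autofluorescence; a surrogate for
  the total amount of penetrated active ingredient.
* **MPD** — mean penetration depth, the unweighted mean depth (µm below the
  local skin surface) of all suprathreshold pixels.

Conventions: rows are indexed top-down with row 0 exterior; depth is the
half-open pixel offset below the per-column surface row; every px→µm
conversion goes through the single ``scale_um_per_px`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.filters import threshold_otsu

from .errors import (
    InsufficientLinesError,
    ParameterError,
    SurfaceNotFoundError,
    ThresholdError,
)
from .synthgen import SectionImage

__all__ = [
    "SctProfile",
    "PenetrationMetrics",
    "ThresholdResult",
    "extract_channel",
    "detect_surface",
    "measure_sct",
    "compute_threshold",
    "remove_autofluorescence",
    "compute_arosa",
    "compute_mpd",
    "analyze_image",
]

MISSING = -1  # sentinel for columns without a surface crossing


def extract_channel(image: SectionImage, surrogate: str) -> SectionImage:
    """Reduce an RGB render to the surrogate's emission channel.

    The hydrophilic surrogate (fluorescein-like, green emission) maps to the
    green channel, the lipophilic one (nile-red-like) to red.  Grayscale
    images pass through unchanged; metadata is preserved.
    """
    px = image.pixels
    if px.ndim == 2:
        return image
    if px.ndim == 3 and px.shape[2] == 3:
        if surrogate == "hydrophilic":
            idx = 1
        elif surrogate == "lipophilic":
            idx = 0
        else:
            raise ParameterError(f"unknown surrogate {surrogate!r}")
        return SectionImage(
            pixels=px[..., idx],
            scale_um_per_px=image.scale_um_per_px,
            channel="green" if idx == 1 else "red",
            image_id=image.image_id,
            ear_id=image.ear_id,
            condition=image.condition,
            cut_index=image.cut_index,
        )
    raise ParameterError(f"expected 2-D gray or HxWx3 RGB image, got shape {px.shape}")


def detect_surface(
    image: SectionImage,
    smoothing_window_px: int = 5,
    background_quantile: float = 0.99,
    background_offset: float = 20.0,
    margin_rows: int = 5,
) -> np.ndarray:
    """Per-column skin surface rows (top-down first crossing).

    The background level is estimated from the top image margin at the given
    quantile plus an offset; for each column the first row where the
    column-smoothed intensity exceeds it is refined to the first raw crossing
    nearby.  Columns with no crossing get the ``MISSING`` sentinel; if every
    column is missing, :class:`SurfaceNotFoundError` is raised.
    """
    px = image.pixels.astype(float)
    h, w = px.shape
    if h < smoothing_window_px:
        raise ParameterError("image has fewer rows than the smoothing window")
    margin = px[: max(1, min(margin_rows, h - 1)), :]
    thresh = float(np.quantile(margin, background_quantile)) + background_offset

    smooth = uniform_filter1d(px, size=smoothing_window_px, axis=0, mode="nearest")
    above_s = smooth > thresh
    above_r = px > thresh
    surface = np.full(w, MISSING, dtype=int)
    half = smoothing_window_px
    for c in range(w):
        idx = np.flatnonzero(above_s[:, c])
        if idx.size == 0:
            continue
        r0 = idx[0]
        lo = max(0, r0 - half)
        raw_idx = np.flatnonzero(above_r[lo : min(h, r0 + half + 1), c])
        surface[c] = lo + raw_idx[0] if raw_idx.size else r0
    if np.all(surface == MISSING):
        raise SurfaceNotFoundError("no column crossed the background threshold")
    return surface


@dataclass
class SctProfile:
    """SC thickness and along-line intensity for sampled vertical lines."""

    line_columns: np.ndarray
    surface_row_px: np.ndarray
    sc_bottom_row_px: np.ndarray
    sct_px: np.ndarray
    af_sc_per_line: np.ndarray
    scale_um_per_px: float

    @property
    def sct_um(self) -> np.ndarray:
        return self.sct_px * self.scale_um_per_px

    @property
    def sct_um_mean(self) -> float:
        return float(np.mean(self.sct_um))

    @property
    def sct_um_sd(self) -> float:
        return float(np.std(self.sct_um, ddof=1)) if self.sct_px.size > 1 else 0.0

    @property
    def af_sc_mean(self) -> float:
        return float(np.mean(self.af_sc_per_line))


def measure_sct(
    image: SectionImage,
    surface_rows: np.ndarray,
    n_lines: int = 10,
    boundary_fraction: float = 0.5,
    smoothing_window_px: int = 5,
) -> SctProfile:
    """SC thickness and AF-SC along evenly spaced vertical lines.

    Per line the SC lower boundary is the first row below the surface where
    the column-smoothed intensity drops below ``tissue + boundary_fraction *
    (band - tissue)``, with the band level taken just under the surface and
    the tissue level from the deep quarter of the column.  With a centred odd
    smoothing window this mid-level crossing recovers a clean step edge
    exactly.  AF-SC is the mean raw grey value per pixel of the surface→
    boundary segment.
    """
    px = image.pixels.astype(float)
    h, _ = px.shape
    valid = np.flatnonzero(surface_rows != MISSING)
    # usable lines need room below the surface for band and tissue estimates
    valid = valid[surface_rows[valid] < h - smoothing_window_px]
    if valid.size < n_lines:
        raise InsufficientLinesError(int(valid.size), n_lines)
    cols = valid[np.linspace(0, valid.size - 1, n_lines).round().astype(int)]
    cols = np.unique(cols)

    half = smoothing_window_px // 2
    surface_out, bottom_out, sct_out, af_out, col_out = [], [], [], [], []
    for c in cols:
        s = int(surface_rows[c])
        col = px[:, c]
        smooth = uniform_filter1d(col, size=smoothing_window_px, mode="nearest")
        band = float(np.mean(col[s : min(h, s + 3)]))
        deep0 = s + (h - s) * 3 // 4
        tissue = float(np.median(col[deep0:])) if deep0 < h else 0.0
        level = tissue + boundary_fraction * (band - tissue)
        start = s + max(1, half)
        below = np.flatnonzero(smooth[start:] < level)
        bottom = start + below[0] if below.size else h
        sct = bottom - s
        if sct <= 0:
            continue
        col_out.append(c)
        surface_out.append(s)
        bottom_out.append(bottom)
        sct_out.append(sct)
        af_out.append(float(np.mean(col[s:bottom])))
    if not col_out:
        raise InsufficientLinesError(0, n_lines)
    return SctProfile(
        line_columns=np.asarray(col_out),
        surface_row_px=np.asarray(surface_out),
        sc_bottom_row_px=np.asarray(bottom_out),
        sct_px=np.asarray(sct_out),
        af_sc_per_line=np.asarray(af_out),
        scale_um_per_px=image.scale_um_per_px,
    )


@dataclass
class ThresholdResult:
    value: float
    method: str
    k: float | None = None
    n_pixels: int = 0
    region: str = "section"


def _section_pixels(image: SectionImage) -> tuple[np.ndarray, str]:
    """Pixels of the tissue section (at/below the detected surface).

    Falls back to the whole image when no surface can be found (e.g. an image
    without a clear skin band), recorded in the result's ``region`` tag.
    """
    px = image.pixels.astype(float)
    try:
        surface = detect_surface(image)
    except (SurfaceNotFoundError, ParameterError):
        return px.ravel(), "image"
    rows = np.arange(px.shape[0])[:, None]
    mask = (surface[None, :] != MISSING) & (rows >= surface[None, :])
    return px[mask], "section"


def compute_threshold(
    images: SectionImage | list[SectionImage],
    method: str = "control_stats",
    k: float = 3.0,
) -> ThresholdResult:
    """Automated autofluorescence-removal threshold.

    ``control_stats`` pools the section pixels of dye-free control images of
    the same ear/channel and returns their mean + k·SD (default k = 3) —
    everything the dye-free skin shows, SC band included, ends below it.
    ``otsu`` maximises the between-class variance of a single target image's
    section histogram (fallback when no controls exist).
    """
    if method == "control_stats":
        controls = images if isinstance(images, list) else [images]
        if not controls:
            raise ThresholdError("control_stats needs at least one control image")
        pooled, regions = [], []
        for img in controls:
            vals, region = _section_pixels(img)
            pooled.append(vals)
            regions.append(region)
        values = np.concatenate(pooled)
        return ThresholdResult(
            value=float(values.mean() + k * values.std()),
            method="control_stats",
            k=k,
            n_pixels=int(values.size),
            region="section" if all(r == "section" for r in regions) else "image",
        )
    if method == "otsu":
        if isinstance(images, list):
            raise ThresholdError("otsu operates on a single image")
        values, region = _section_pixels(images)
        ints = values.astype(np.int64)
        if ints.min() == ints.max():
            raise ThresholdError("otsu undefined for a constant image")
        lo, hi = int(ints.min()), int(ints.max())
        counts, _ = np.histogram(ints, bins=np.arange(lo, hi + 2))
        centers = np.arange(lo, hi + 1).astype(float)
        value = float(threshold_otsu(hist=(counts, centers)))
        return ThresholdResult(value=value, method="otsu", n_pixels=int(values.size), region=region)
    raise ParameterError(f"unknown threshold method {method!r}")


def remove_autofluorescence(image: SectionImage, threshold: float) -> np.ndarray:
    """Zero every pixel not strictly above the threshold; keep the rest."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    px = image.pixels.astype(float)
    return np.where(px > threshold, px, 0.0)


def compute_arosa(masked: np.ndarray) -> float:
    """Mean grey value per pixel of the masked image (all pixels counted).

    Zeros stay in the denominator, so both suprathreshold intensity and
    penetrated area raise the value — matching its reading as a surrogate for
    the total amount of penetrated AI.
    """
    return float(masked.sum() / masked.size)


def compute_mpd(
    masked: np.ndarray,
    surface_rows: np.ndarray,
    scale_um_per_px: float,
) -> tuple[float, int, dict]:
    """Unweighted mean depth (µm below the local surface) of retained pixels.

    Pixels above the surface are excluded; columns without a detected surface
    are skipped and counted in the returned flags.  Returns
    ``(mpd_um, n_pixels_used, flags)`` with ``mpd_um = 0`` and a NO_SIGNAL
    flag when nothing is retained.
    """
    if scale_um_per_px <= 0:
        raise ParameterError("scale must be positive")
    rows, cols = np.nonzero(masked > 0)
    flags: dict = {}
    if rows.size == 0:
        return 0.0, 0, {"NO_SIGNAL": True}
    col_surface = surface_rows[cols]
    missing = col_surface == MISSING
    if missing.any():
        flags["skipped_signal_columns"] = int(np.unique(cols[missing]).size)
    keep = ~missing & (rows >= col_surface)
    if not keep.any():
        return 0.0, 0, {"NO_SIGNAL": True, **flags}
    depths = (rows[keep] - col_surface[keep]) * scale_um_per_px
    return float(depths.mean()), int(keep.sum()), flags


@dataclass
class PenetrationMetrics:
    """Threshold, AROSA (MGV/px) and MPD (µm) for one image."""

    threshold_value: float
    threshold_method: str
    arosa_mgv_per_px: float
    mpd_um: float
    n_signal_px: int
    flags: dict = field(default_factory=dict)


def analyze_image(
    image: SectionImage,
    surface_rows: np.ndarray,
    threshold: ThresholdResult,
) -> PenetrationMetrics:
    """Threshold the image and bundle AROSA + MPD into one record."""
    masked = remove_autofluorescence(image, threshold.value)
    arosa = compute_arosa(masked)
    n_retained = int(np.count_nonzero(masked))
    mpd, _, flags = compute_mpd(masked, surface_rows, image.scale_um_per_px)
    # NO_SIGNAL tracks the retained-pixel count (not just sub-surface signal)
    if n_retained == 0:
        flags["NO_SIGNAL"] = True
    else:
        flags.pop("NO_SIGNAL", None)
    return PenetrationMetrics(
        threshold_value=threshold.value,
        threshold_method=threshold.method,
        arosa_mgv_per_px=arosa,
        mpd_um=mpd,
        n_signal_px=n_retained,
        flags=flags,
    )
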