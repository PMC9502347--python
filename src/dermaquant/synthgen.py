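"""Synthetic vertical skin-section fluorescence images with known ground truth.

Real cryosection micrographs of dye-treated skin are not publicly available,
so every downstream measurement (stratum corneum thickness, SC
autofluorescence, thresholded penetrated signal, mean penetration depth) is
exercised on renders whose generative parameters are recorded exactly.

A rendered image is organised top-down: dark background above the skin
surface, a bright stratum corneum (SC) band of known thickness, dimmer viable
tissue below it, an exponentially depth-decaying dye signal anchored at the
surface, optional bright sebum/bacteria hotspots near the surface, and
additive Gaussian camera noise, quantised to 8 or 16 bit.

Hydration couples into the render the way it is read off real sections: a
better hydrated SC is thicker and optically less dense, so the effective SC
thickness rises and the effective SC autofluorescence falls with the
hydration index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DatasetError, ParameterError
from .presets import ConditionPreset, StudyManifest

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "StudyDataset",
    "generate_section_image",
    "generate_study",
    "write_dataset",
    "load_dataset",
]

#: linear hydration -> SC-thickness coupling: sct_eff = sct_um * (0.8 + 0.4 h)
SCT_HYDRATION_SLOPE = 0.4
SCT_HYDRATION_OFFSET = 0.8
#: inverse hydration -> SC-autofluorescence coupling: af_eff = af * (1.2 - 0.4 h)
AF_HYDRATION_SLOPE = 0.4
AF_HYDRATION_OFFSET = 1.2


@dataclass
class GeneratorParams:
    """Parameters of one synthetic skin-section render.

    Grey-level magnitudes are conventions (the study reports no absolute
    grey statistics); only their orderings are meaningful.  Units: lengths in
    µm unless the field name says px, intensities in grey units of the target
    bit depth.
    """

    image_height_px: int = 128
    image_width_px: int = 160
    scale_um_per_px: float = 2.84
    surface_row_mean_px: float = 10.0
    surface_roughness_px: float = 1.0
    sct_um: float = 35.0
    hydration_index: float = 0.5
    af_sc_level: float = 180.0
    af_tissue_level: float = 40.0
    dye_amount: float = 5000.0
    dye_decay_um: float = 110.0
    hotspot_density: float = 3.0
    hotspot_level: float = 120.0
    noise_sd: float = 3.0
    background_level: float = 2.0
    bit_depth: int = 16

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ParameterError("image dimensions must be positive")
        if self.scale_um_per_px <= 0:
            raise ParameterError("scale_um_per_px must be positive")
        if self.sct_um <= 0:
            raise ParameterError("sct_um must be positive")
        if not 0.0 <= self.hydration_index <= 1.0:
            raise ParameterError("hydration_index must lie in [0, 1]")
        if self.af_tissue_level >= self.af_sc_level:
            raise ParameterError(
                "af_tissue_level must be below af_sc_level (the SC band is "
                "brighter than viable tissue)"
            )
        if self.dye_amount < 0 or self.dye_decay_um <= 0:
            raise ParameterError("dye_amount must be >= 0 and dye_decay_um > 0")
        if self.hotspot_density < 0 or self.noise_sd < 0:
            raise ParameterError("hotspot_density and noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if self.surface_row_mean_px < 0:
            raise ParameterError("surface_row_mean_px must be >= 0")
        # effective values after hydration coupling must keep the band visible
        if self.af_sc_eff <= self.af_tissue_level:
            raise ParameterError(
                "effective SC autofluorescence does not exceed tissue level"
            )
        if self.surface_row_mean_px + self.sct_px >= self.image_height_px:
            raise ParameterError("sct_um exceeds the image depth below the surface")

    # -- hydration-coupled effective values ---------------------------------
    @property
    def sct_eff_um(self) -> float:
        return self.sct_um * (SCT_HYDRATION_OFFSET + SCT_HYDRATION_SLOPE * self.hydration_index)

    @property
    def af_sc_eff(self) -> float:
        return self.af_sc_level * (AF_HYDRATION_OFFSET - AF_HYDRATION_SLOPE * self.hydration_index)

    @property
    def sct_px(self) -> int:
        return max(1, int(round(self.sct_eff_um / self.scale_um_per_px)))

    @property
    def max_grey(self) -> int:
        return (1 << self.bit_depth) - 1

    def with_modifiers(self, modifiers: dict[str, float]) -> "GeneratorParams":
        """Return a copy with multiplicative factors applied to named fields.

        ``hydration_index`` is clipped back into [0, 1] after scaling.
        """
        out = dataclasses.replace(self)
        for name, factor in modifiers.items():
            if not hasattr(out, name):
                raise ParameterError(f"unknown generator parameter {name!r}")
            setattr(out, name, getattr(out, name) * factor)
        out.hydration_index = float(np.clip(out.hydration_index, 0.0, 1.0))
        return out


@dataclass
class GroundTruth:
    """Effective generative values actually used for a render."""

    seed: int
    scale_um_per_px: float
    surface_rows: np.ndarray  # per-column integer surface row
    sct_px: int
    sct_eff_um: float
    af_sc_eff: float
    af_tissue_level: float
    dye_amount: float
    dye_decay_um: float
    hydration_index: float
    hotspot_density: float
    noise_sd: float
    bit_depth: int

    def as_record(self) -> dict:
        rec = dataclasses.asdict(self)
        rec["surface_rows"] = ";".join(str(int(r)) for r in self.surface_rows)
        rec["surface_row_mean"] = float(np.mean(self.surface_rows))
        return rec


@dataclass
class SectionImage:
    """One micrograph plus its pixel scale and study coordinates.

    Rows are indexed top-down: row 0 is exterior (above the skin surface) and
    depth increases with the row index.
    """

    pixels: np.ndarray
    scale_um_per_px: float = 2.84
    channel: str = "gray"
    image_id: str = ""
    ear_id: str = ""
    condition: str = ""
    cut_index: int = 0

    def __post_init__(self) -> None:
        if self.scale_um_per_px <= 0:
            raise ParameterError("scale_um_per_px must be positive")


def _render(params: GeneratorParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Float render + per-column surface rows, before quantisation."""
    h, w = params.image_height_px, params.image_width_px
    jitter = rng.normal(0.0, params.surface_roughness_px, size=w)
    surface = np.clip(np.round(params.surface_row_mean_px + jitter), 0, h - 1).astype(int)

    rows = np.arange(h)[:, None]
    depth_px = rows - surface[None, :]
    skin = depth_px >= 0
    sc_band = skin & (depth_px < params.sct_px)

    img = np.full((h, w), params.background_level, dtype=float)
    img[skin] = params.af_tissue_level
    img[sc_band] = params.af_sc_eff

    if params.dye_amount > 0:
        depth_um = depth_px * params.scale_um_per_px
        dye = np.where(skin, params.dye_amount * np.exp(-np.maximum(depth_um, 0.0) / params.dye_decay_um), 0.0)
        img += dye

    n_spots = rng.poisson(params.hotspot_density) if params.hotspot_density > 0 else 0
    for _ in range(n_spots):
        col = int(rng.integers(0, w))
        row = int(np.clip(surface[col] + rng.integers(-1, 2), 0, h - 1))
        r0, r1 = max(0, row - 1), min(h, row + 2)
        c0, c1 = max(0, col - 1), min(w, col + 2)
        img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], params.hotspot_level)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return img, surface


def generate_section_image(
    params: GeneratorParams,
    seed: int,
    *,
    rgb_channel: str | None = None,
) -> tuple[SectionImage, GroundTruth]:
    """Render one synthetic section image.

    Parameters
    ----------
    params
        Generator parameters; validated before use.
    seed
        Any integer; identical parameters and seed give pixel-identical
        output.
    rgb_channel
        ``None`` renders single-channel grayscale (canonical).  ``"green"``
        or ``"red"`` embeds the same grayscale render into that channel of an
        RGB image (green for the hydrophilic, red for the lipophilic
        surrogate) to exercise channel extraction.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    img, surface = _render(params, rng)

    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    quantised = np.clip(np.round(img), 0, params.max_grey).astype(dtype)

    if rgb_channel is not None:
        if rgb_channel not in ("green", "red"):
            raise ParameterError("rgb_channel must be 'green' or 'red'")
        rgb = np.zeros(quantised.shape + (3,), dtype=dtype)
        rgb[..., 1 if rgb_channel == "green" else 0] = quantised
        pixels: np.ndarray = rgb
        channel = rgb_channel
    else:
        pixels = quantised
        channel = "gray"

    image = SectionImage(pixels=pixels, scale_um_per_px=params.scale_um_per_px, channel=channel)
    truth = GroundTruth(
        seed=int(seed),
        scale_um_per_px=params.scale_um_per_px,
        surface_rows=surface,
        sct_px=params.sct_px,
        sct_eff_um=params.sct_eff_um,
        af_sc_eff=params.af_sc_eff,
        af_tissue_level=params.af_tissue_level,
        dye_amount=params.dye_amount,
        dye_decay_um=params.dye_decay_um,
        hydration_index=params.hydration_index,
        hotspot_density=params.hotspot_density,
        noise_sd=params.noise_sd,
        bit_depth=params.bit_depth,
    )
    return image, truth


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

#: per-ear multiplicative log-normal random effect (SD of log, ~10%)
EAR_EFFECT_SD = 0.10
#: generator fields the ear effect multiplies
EAR_EFFECT_FIELDS = ("af_sc_level", "af_tissue_level", "sct_um")


@dataclass
class StudyDataset:
    """In-memory study: images plus a ground-truth table keyed by image id."""

    manifest: StudyManifest
    images: list[SectionImage] = field(default_factory=list)
    truth_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _ear_factors(root_seed: int, ear_idx: int) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([root_seed, 7919, ear_idx]))
    return {f: float(np.exp(rng.normal(0.0, EAR_EFFECT_SD))) for f in EAR_EFFECT_FIELDS}


def _image_seed(root_seed: int, ear_idx: int, cond_idx: int, img_idx: int) -> int:
    ss = np.random.SeedSequence([root_seed, ear_idx, cond_idx, img_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(
    manifest: StudyManifest,
    base: GeneratorParams,
    presets: Sequence[ConditionPreset] | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Render every (ear x condition) cell of the study design.

    Each ear carries a multiplicative log-normal random effect on its
    autofluorescence levels and SC thickness, shared by all of that ear's
    images, emulating independent animals.  Dye-free blank images (used for
    autofluorescence thresholding) are rendered per ear when the manifest
    requests them.
    """
    presets = list(presets) if presets is not None else list(manifest.conditions)
    if not presets:
        raise DatasetError("empty preset list")
    labels = [p.label for p in presets]
    if len(set(labels)) != len(labels):
        raise DatasetError("duplicate condition labels in preset list")

    images: list[SectionImage] = []
    records: list[dict] = []
    n_cuts = max(1, manifest.cuts_per_biopsy)
    n_imgs = max(1, manifest.images_per_biopsy)

    def _emit(ear_idx: int, ear: str, cond_idx: int, label: str, preset: ConditionPreset | None,
              params: GeneratorParams, count: int) -> None:
        for i in range(count):
            s = _image_seed(seed, ear_idx, cond_idx, i)
            image, truth = generate_section_image(params, s)
            cut = (i * n_cuts) // count + 1
            image.image_id = f"{ear}_{label}_{i:03d}"
            image.ear_id = ear
            image.condition = label
            image.cut_index = cut
            rec = truth.as_record()
            rec.update(
                image_id=image.image_id,
                ear=ear,
                condition=label,
                cut_index=cut,
                skin_section=preset.skin_section if preset else 1,
                surrogate=preset.surrogate if preset else "none",
                timepoint=preset.timepoint if preset else "none",
            )
            records.append(rec)
            images.append(image)

    for ear_idx, ear in enumerate(manifest.ears):
        factors = _ear_factors(seed, ear_idx)
        ear_base = base.with_modifiers(factors)
        for cond_idx, preset in enumerate(presets):
            params = ear_base.with_modifiers(preset.modifiers)
            if preset.surrogate_base is not None:
                params = params.with_modifiers(preset.surrogate_base)
            _emit(ear_idx, ear, cond_idx, preset.label, preset, params, n_imgs)
        if manifest.blanks_per_ear > 0:
            blank = dataclasses.replace(ear_base, dye_amount=0.0)
            _emit(ear_idx, ear, len(presets), manifest.blank_label, None, blank,
                  manifest.blanks_per_ear)

    table = pd.DataFrame.from_records(records)
    front = ["image_id", "ear", "condition", "skin_section", "surrogate", "timepoint", "cut_index"]
    table = table[front + [c for c in table.columns if c not in front]]
    return StudyDataset(manifest=manifest, images=images, truth_table=table)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(dataset: StudyDataset, directory: str | Path, overwrite: bool = False) -> dict:
    """Write TIFF images plus truth CSV and manifest JSON; returns the paths."""
    directory = Path(directory)
    img_dir = directory / "images"
    truth_path = directory / "truth.csv"
    manifest_path = directory / "manifest.json"
    if truth_path.exists() and not overwrite:
        raise DatasetError(f"dataset already exists at {directory} (pass overwrite=True)")
    img_dir.mkdir(parents=True, exist_ok=True)

    image_paths = []
    for image in dataset.images:
        p = img_dir / f"{image.image_id}.tif"
        tifffile.imwrite(p, image.pixels)
        image_paths.append(p)
    dataset.truth_table.to_csv(truth_path, index=False)
    manifest_path.write_text(json.dumps(dataset.manifest.to_dict(), indent=2))
    return {"images": image_paths, "truth": truth_path, "manifest": manifest_path}


def load_dataset(directory: str | Path) -> StudyDataset:
    """Re-load a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    truth_path = directory / "truth.csv"
    manifest_path = directory / "manifest.json"
    if not truth_path.exists() or not manifest_path.exists():
        raise DatasetError(f"no dataset found at {directory}")
    manifest = StudyManifest.from_dict(json.loads(manifest_path.read_text()))
    table = pd.read_csv(truth_path)
    images = []
    for rec in table.itertuples():
        p = directory / "images" / f"{rec.image_id}.tif"
        pixels = tifffile.imread(p)
        images.append(
            SectionImage(
                pixels=pixels,
                scale_um_per_px=float(rec.scale_um_per_px),
                image_id=str(rec.image_id),
                ear_id=str(rec.ear),
                condition=str(rec.condition),
                cut_index=int(rec.cut_index),
            )
        )
    return StudyDataset(manifest=manifest, images=images, truth_table=table)
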