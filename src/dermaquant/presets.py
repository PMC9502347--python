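"""Study design: condition presets and the study manifest.

The emulated study applies two fluorescent active-ingredient (AI) surrogates
(hydrophilic sodium-fluorescein-like, in water; lipophilic nile-red-like, in
oil) to three skin sections per porcine ear — section 1 untreated control,
section 2 professionally treated without massage, section 3 treated with
massage — at two application time points (during the treatment, i.e. under
the mask, and after the treatment).  Section 1 receives only the two AI
applications; it is the 100% reference of each (surrogate, timepoint)
stratum.

Presets modify a shared base parameter set multiplicatively.  The factors are
qualitative study-condition definitions (mask uptake and massage remove AI
applied during the treatment; massage removes the water front that blocks the
lipophilic AI applied afterwards; cleansing removes sebum/bacteria hotspots)
and live in ``data/presets.yaml`` so they are versioned, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ManifestError, ParameterError

SKIN_SECTIONS = {1: "no treatment", 2: "treatment without massage", 3: "treatment with massage"}
SURROGATES = ("hydrophilic", "lipophilic")
TIMEPOINTS = ("during", "after")


@dataclass
class ConditionPreset:
    """One study condition: skin section x AI surrogate x application time."""

    skin_section: int
    surrogate: str
    timepoint: str
    modifiers: dict[str, float] = field(default_factory=dict)
    #: surrogate-specific base overrides (dye amount/decay differ between the
    #: hydrophilic and lipophilic formulations); identical for every section
    #: of a stratum, hence not part of the treatment-effect modifiers.
    surrogate_base: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.skin_section not in SKIN_SECTIONS:
            raise ParameterError(f"skin_section must be one of {sorted(SKIN_SECTIONS)}")
        if self.surrogate not in SURROGATES:
            raise ParameterError(f"surrogate must be one of {SURROGATES}")
        if self.timepoint not in TIMEPOINTS:
            raise ParameterError(f"timepoint must be one of {TIMEPOINTS}")
        if self.skin_section == 1 and any(v != 1 for v in self.modifiers.values()):
            raise ParameterError("control preset (section 1) must have all modifiers = 1")

    @property
    def label(self) -> str:
        return f"s{self.skin_section}-{self.surrogate}-{self.timepoint}"

    @property
    def is_control(self) -> bool:
        return self.skin_section == 1

    def to_dict(self) -> dict:
        return {
            "skin_section": self.skin_section,
            "surrogate": self.surrogate,
            "timepoint": self.timepoint,
            "modifiers": dict(self.modifiers),
            "surrogate_base": dict(self.surrogate_base) if self.surrogate_base else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionPreset":
        return cls(
            skin_section=int(d["skin_section"]),
            surrogate=str(d["surrogate"]),
            timepoint=str(d["timepoint"]),
            modifiers={k: float(v) for k, v in (d.get("modifiers") or {}).items()},
            surrogate_base=(
                {k: float(v) for k, v in d["surrogate_base"].items()}
                if d.get("surrogate_base")
                else None
            ),
        )


@dataclass
class StudyManifest:
    """Design of one study run.

    Defaults mirror the emulated protocol: three independent ears, at least
    12 cuts and 40 images per biopsy (>= 120 images per condition), plus
    dye-free blank images per ear for autofluorescence thresholding.
    """

    ears: list[str] = field(default_factory=lambda: ["ear1", "ear2", "ear3"])
    conditions: list[ConditionPreset] = field(default_factory=list)
    cuts_per_biopsy: int = 12
    images_per_biopsy: int = 40
    blanks_per_ear: int = 20
    blank_label: str = "blank"

    def __post_init__(self) -> None:
        if not self.ears:
            raise ManifestError("manifest needs at least one ear")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ManifestError("duplicate condition labels in manifest")
        for surrogate, timepoint in {(c.surrogate, c.timepoint) for c in self.conditions}:
            n_ctrl = sum(
                1
                for c in self.conditions
                if c.is_control and (c.surrogate, c.timepoint) == (surrogate, timepoint)
            )
            if n_ctrl != 1:
                raise ManifestError(
                    f"stratum ({surrogate}, {timepoint}) needs exactly one "
                    f"control condition (skin section 1), found {n_ctrl}"
                )

    @property
    def condition_labels(self) -> list[str]:
        return [c.label for c in self.conditions]

    def control_label(self, surrogate: str, timepoint: str) -> str:
        for c in self.conditions:
            if c.is_control and (c.surrogate, c.timepoint) == (surrogate, timepoint):
                return c.label
        raise ManifestError(f"no control condition for stratum ({surrogate}, {timepoint})")

    def to_dict(self) -> dict:
        return {
            "ears": list(self.ears),
            "conditions": [c.to_dict() for c in self.conditions],
            "cuts_per_biopsy": self.cuts_per_biopsy,
            "images_per_biopsy": self.images_per_biopsy,
            "blanks_per_ear": self.blanks_per_ear,
            "blank_label": self.blank_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyManifest":
        return cls(
            ears=[str(e) for e in d["ears"]],
            conditions=[ConditionPreset.from_dict(c) for c in d["conditions"]],
            cuts_per_biopsy=int(d.get("cuts_per_biopsy", 12)),
            images_per_biopsy=int(d.get("images_per_biopsy", 40)),
            blanks_per_ear=int(d.get("blanks_per_ear", 20)),
            blank_label=str(d.get("blank_label", "blank")),
        )


def _default_preset_path() -> Path:
    return Path(str(resources.files("dermaquant").joinpath("data/presets.yaml")))


def load_presets(path: str | Path | None = None) -> list[ConditionPreset]:
    """Load condition presets from a YAML file (package default if None)."""
    path = Path(path) if path is not None else _default_preset_path()
    doc = yaml.safe_load(path.read_text())
    surrogate_base = {k: dict(v) for k, v in (doc.get("surrogate_base") or {}).items()}
    presets = []
    for entry in doc["conditions"]:
        p = ConditionPreset.from_dict(entry)
        p.surrogate_base = surrogate_base.get(p.surrogate)
        presets.append(p)
    return presets


def default_manifest(preset_path: str | Path | None = None, **kwargs) -> StudyManifest:
    """Full default study design: 3 ears x 12 conditions (+ blanks)."""
    return StudyManifest(conditions=load_presets(preset_path), **kwargs)
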