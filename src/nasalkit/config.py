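"""YAML run configuration: one file bundling every pinned constant.

All method constants (window/hop/frame timing, coefficient counts, the
vowel-nasalization thresholds, the analysis band, the clinical cuts, the
training hyperparameters) live in the nested dataclass configs with the
method's values as defaults; a run configuration file overrides selected
keys and is schema-validated — unknown keys are reported, not ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .labeling import LabelingConfig
from .model import TrainConfig
from .nasalance import ENasalanceConfig
from .perceptual import PerceptualScale

__all__ = ["RunConfig", "load_run_config"]

_SECTIONS = {
    "features": FeatureConfig,
    "labeling": LabelingConfig,
    "train": TrainConfig,
    "enasalance": ENasalanceConfig,
    "perceptual": PerceptualScale,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of all stage configurations plus the run seed."""

    seed: int = 0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    enasalance: ENasalanceConfig = field(default_factory=ENasalanceConfig)
    perceptual: PerceptualScale = field(default_factory=PerceptualScale)


def _build_section(cls, payload: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(
            f"config section {section!r} has unknown keys: {sorted(unknown)}"
        )
    coerced = {
        k: frozenset(v) if isinstance(getattr(cls(), k, None), frozenset) else
        tuple(v) if isinstance(v, list) else v
        for k, v in payload.items()
    }
    return cls(**coerced)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Top-level keys: ``seed`` plus any of the sections ``features``,
    ``labeling``, ``train``, ``enasalance``, ``perceptual``.  Section
    values fall back to the method defaults; violations of a section's
    invariants raise with the offending keys named.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(payload) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    sections = {
        name: _build_section(cls, payload.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(seed=int(payload.get("seed", 0)), **sections)
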