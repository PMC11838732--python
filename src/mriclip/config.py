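"""YAML run configuration with schema validation (unknown keys rejected)."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .pipeline import DeskSettings

_ALLOWED = {"preset", "seed", "n_studies", "prevalences", "vq_patches",
            "vq_epochs", "lm_epochs", "name_epochs", "clip_epochs",
            "clip_batch", "clip_lr", "head_epochs"}


def load_run_config(path) -> dict:
    """Parse a YAML run config into {'seed', 'preset', 'settings'}.

    Unknown keys are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    unknown = set(raw) - _ALLOWED
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    preset = raw.pop("preset", "desk")
    if preset not in ("desk", "paper"):
        raise ValueError(f"unknown preset {preset!r}")
    seed = int(raw.pop("seed", 0))
    valid = {f.name for f in fields(DeskSettings)}
    settings = DeskSettings(**{k: (tuple(v) if k == "prevalences" else v)
                               for k, v in raw.items() if k in valid})
    return {"seed": seed, "preset": preset, "settings": settings}
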