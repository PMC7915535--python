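"""Pipeline configuration: sectioned defaults, YAML overrides, run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import yaml

from .epoching import OnsetParams
from .preprocess import PreprocessConfig
from .synthetic import SynthConfig
from .training import TrainConfig

__all__ = ["PipelineConfig", "load_config", "run_manifest", "split_seed"]

_SECTIONS = {
    "preprocess": PreprocessConfig,
    "epoching": OnsetParams,
    "synth": SynthConfig,
    "train": TrainConfig,
}

_EVAL_DEFAULTS = {"window_start_s": -3.0, "window_stop_s": 3.0, "reset_offset_s": None}
_PANEL_DEFAULTS = {"n_sims": 10_000, "prior": "uniform"}


@dataclasses.dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    epoching: OnsetParams = dataclasses.field(default_factory=OnsetParams)
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    eval: dict = dataclasses.field(default_factory=lambda: dict(_EVAL_DEFAULTS))
    panel: dict = dataclasses.field(default_factory=lambda: dict(_PANEL_DEFAULTS))

    def to_dict(self) -> dict:
        out = {}
        for name in _SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        out["eval"] = dict(self.eval)
        out["panel"] = dict(self.panel)
        return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build the config from defaults + optional YAML file + overrides.

    Unknown sections or keys are rejected rather than silently ignored.
    """
    doc: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in (overrides or {}).items():
        doc.setdefault(section, {}).update(values)
    cfg = PipelineConfig()
    for section, values in doc.items():
        if section in _SECTIONS:
            cls = _SECTIONS[section]
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(values) - known
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            values = {
                k: (math.inf if v == "inf" else tuple(v) if isinstance(v, list) else v)
                for k, v in values.items()
            }
            setattr(cfg, section, dataclasses.replace(getattr(cfg, section), **values))
        elif section in ("eval", "panel"):
            target = getattr(cfg, section)
            unknown = set(values) - set(target)
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            target.update(values)
        else:
            raise ValueError(f"unknown config section {section!r}")
    return cfg


def split_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_manifest(config: PipelineConfig, seed: int, outputs: list[str]) -> dict:
    """Reproducibility record written next to every CLI output."""
    import numpy
    import scipy

    from . import __version__

    doc = config.to_dict()
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return {
        "config": doc,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "outputs": outputs,
        "versions": {
            "emid": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
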