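"""YAML configuration for thresholds, per-feature scores and extraction options.

The defaults reproduce the published behaviour; every knob the algorithm
uses is exposed so alternative scoring tables can be tried without code
changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .extract import ExtractionOptions
from .modcount import ScoringScheme, ThresholdPolicy


@dataclass(frozen=True)
class Config:
    policy: ThresholdPolicy
    scheme: ScoringScheme
    options: ExtractionOptions


def default_config() -> Config:
    return Config(ThresholdPolicy(), ScoringScheme(), ExtractionOptions())


def config_to_dict(cfg: Config) -> dict:
    return {
        "threshold": asdict(cfg.policy),
        "scores": asdict(cfg.scheme),
        "extraction": {
            **{
                k: (sorted(v) if isinstance(v, frozenset) else v)
                for k, v in asdict(cfg.options).items()
            }
        },
    }


def config_from_dict(data: dict) -> Config:
    data = data or {}
    policy = ThresholdPolicy(**(data.get("threshold") or {}))
    scheme = ScoringScheme(**(data.get("scores") or {}))
    ext = dict(data.get("extraction") or {})
    if "organic_elements" in ext:
        ext["organic_elements"] = frozenset(ext["organic_elements"])
    options = ExtractionOptions(**ext)
    return Config(policy, scheme, options)


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return default_config()
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
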