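"""Structured pipeline configuration with YAML round-tripping.

One config file drives every subcommand; a single global seed fans out
deterministically to per-module seeds so one number reproduces a full
experiment.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .features import OPERATING_SET

__all__ = ["PipelineConfig", "load_config", "save_config"]


def _check_keys(section: str, data: dict, allowed) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}; "
            f"allowed: {', '.join(sorted(allowed))}"
        )


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with documented defaults."""

    # preprocessing
    highpass_hz: float = 10.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    causal: bool = False
    # windowing
    window_ms: float = 300.0
    step_ms: float = 10.0
    # features
    features: tuple[str, ...] = OPERATING_SET
    # GMM
    em_tol: float = 1e-6
    em_max_iter: int = 500
    memory_length: int = 1000
    # detector
    detector: str = "type2-info"
    muscles: tuple[str, ...] = ()
    subset_size: int = 3
    debounce: int = 1
    # evaluation
    t_pre: float = 0.5
    t_post: float = 1.0
    # information analysis
    n_bins: int = 4
    screen_alpha: float = 0.001
    # synthetic data
    n_trials: int = 24
    n_sessions: int = 7
    drift: float = 0.0
    # global
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        _check_keys("pipeline", data, allowed)
        kwargs = dict(data)
        for key in ("features", "muscles"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = list(d["features"])
        d["muscles"] = list(d["muscles"])
        return d

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        h = 0
        for ch in module:
            h = (h * 131 + ord(ch)) % 1_000_003
        return (self.seed * 1_000_003 + h) % (2**31 - 1)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
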