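"""Run configuration and logging setup."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .similarity import ESTIMATORS


@dataclass
class RunConfig:
    """Top-level knobs shared by the CLI subcommands.

    All stochastic operations draw from ``seed`` (handed down as numpy
    Generators), so a run is reproducible end to end.
    """

    seed: int = 0
    estimator: str = "centered"
    alpha: float = 0.05
    log_level: str = "INFO"
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}, got {self.estimator!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in ("seed", "estimator", "alpha", "log_level", "paths") if k in raw}
        return cls(**known)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
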