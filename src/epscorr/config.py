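"""Pipeline configuration: detection windows, jitter null, thresholding, QC."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

#: number of lag bins in every cross-correlation profile (fixed by construction)
N_LAG_BINS = 21
#: threshold multiplier over the pooled mean (fixed: mean + 2 SD)
THRESHOLD_SD_MULTIPLIER = 2.0
#: AUROC histogram grid: correlations 0..0.5 in steps of 0.001
ROC_HIST_RANGE = (0.0, 0.5)
ROC_HIST_BIN_WIDTH = 0.001


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Parameters of the paired event-train correlation pipeline.

    Attributes
    ----------
    window_half_width : float
        Detection-window half-width W in seconds. The lag grid spans ±W in
        21 bins of width ``W / 10`` (defaults: 0.1 s, i.e. the ±100 ms window
        with 10 ms bins; 0.05 s gives the ±50 ms window with 5 ms bins).
    jitter_bound : float
        Bound J of the uniform circular-offset null, in seconds (±J).
    jitter_iterations : int
        Number of jitter resamples K per session.
    seed : int
        Base RNG seed for every stochastic stage.
    qc_min_events, qc_min_duration : numbers
        Session inclusion minima applied before correlation analysis.
    """

    window_half_width: float = 0.1
    jitter_bound: float = 0.5
    jitter_iterations: int = 100
    seed: int = 0
    qc_min_events: int = 100
    qc_min_duration: float = 120.0
    qc_min_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.window_half_width <= 0:
            raise ConfigError("window_half_width must be > 0")
        if self.jitter_bound <= 0:
            raise ConfigError("jitter_bound must be > 0")
        if self.jitter_iterations < 1:
            raise ConfigError("jitter_iterations must be >= 1")
        if self.qc_min_events < 0 or self.qc_min_duration < 0 or self.qc_min_rate < 0:
            raise ConfigError("QC minima must be >= 0")

    @property
    def bin_width(self) -> float:
        """Lag-bin width Δ = W/10 in seconds, so that kΔ, k = −10..10 spans ±W."""
        return self.window_half_width / 10.0

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Load a config from a ``key: value`` YAML file; absent keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of key: value pairs")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
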