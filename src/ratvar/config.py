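"""Pipeline configuration.

Defaults reproduce the analysis constants for conscious-rat recordings:
rat spectral bands 0-0.2 / 0.2-0.75 / 0.75-3.0 Hz, ~300-beat stationary
fragments, 2 kHz waveform sampling, AR order searched over 8-20 by AIC and
alpha = 0.05 for the factorial statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .spectral import (DEFAULT_FRAGMENT_LEN, DEFAULT_ORDER_RANGE, K_MEAN,
                       K_VAR, RAT_BANDS)
from .stats import ALPHA


@dataclass(frozen=True)
class PipelineConfig:
    bands: tuple = RAT_BANDS  # Hz: (VLF, LF, HF)
    fragment_len: int = DEFAULT_FRAGMENT_LEN  # beats
    k_mean: float = K_MEAN  # stationarity: mean-span threshold (x SD)
    k_var: float = K_VAR  # stationarity: variance-span threshold (x var)
    order_min: int = DEFAULT_ORDER_RANGE[0]
    order_max: int = DEFAULT_ORDER_RANGE[1]
    sampling_rate: float = 2000.0  # Hz, waveform rate
    alpha: float = ALPHA
    dispersion: str = "sd"  # label for group dispersion: 'sd' or 'sem'
    albumin_interval: str = "iqr"  # 'iqr' or 'minmax'
    seed: int = 0
    design_path: str | None = None  # cohort design YAML; None = shipped default

    def __post_init__(self) -> None:
        edges = [e for band in self.bands for e in band]
        if any(b > a for a, b in zip(edges[1:], edges[:-1])):
            raise ValueError("band edges must be non-decreasing")
        if self.fragment_len < 10:
            raise ValueError("fragment_len is implausibly small")
        if not (1 <= self.order_min <= self.order_max):
            raise ValueError("need 1 <= order_min <= order_max")
        if self.order_max >= self.fragment_len / 2:
            raise ValueError("order_max must be below fragment_len / 2")
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be at least 100 Hz")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.dispersion not in ("sd", "sem"):
            raise ValueError("dispersion must be 'sd' or 'sem'")
        if self.albumin_interval not in ("iqr", "minmax"):
            raise ValueError("albumin_interval must be 'iqr' or 'minmax'")

    @property
    def order_range(self) -> tuple[int, int]:
        return (self.order_min, self.order_max)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a config from YAML (missing keys fall back to defaults)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if "bands" in data:
        data["bands"] = tuple(tuple(float(e) for e in band)
                              for band in data["bands"])
    data.update(overrides)
    return PipelineConfig(**data)
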