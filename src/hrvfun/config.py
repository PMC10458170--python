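"""Pipeline configuration with study defaults.

Defaults follow the analysis protocol the package implements: 4 Hz IBI
resampling, 2-minute analysis windows, LF = [0.04, 0.15) Hz and
HF = [0.15, 0.40] Hz band edges, LHSD routing threshold 1.47.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .curve_features import DEFAULT_SD_THRESHOLD
from .errors import ConfigurationError
from .ibi_spectral import (
    DEFAULT_MIN_BEATS_PER_SEGMENT,
    DEFAULT_RESAMPLE_RATE_HZ,
    DEFAULT_WINDOW_S,
    HF_BAND,
    LF_BAND,
    PeakDetectionConfig,
)

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the end-to-end pipeline in one place."""

    resample_rate_hz: float = DEFAULT_RESAMPLE_RATE_HZ
    window_s: float = DEFAULT_WINDOW_S
    lf_band: tuple[float, float] = LF_BAND
    hf_band: tuple[float, float] = HF_BAND
    min_beats_per_segment: int = DEFAULT_MIN_BEATS_PER_SEGMENT
    interpolation: str = "linear"
    fft_window: str = "rectangular"
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    clamp_predictions: bool = False
    peak_detection: PeakDetectionConfig = field(default_factory=PeakDetectionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "peak_detection" in d and isinstance(d["peak_detection"], dict):
            d["peak_detection"] = PeakDetectionConfig(**d["peak_detection"])
        for key in ("lf_band", "hf_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
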