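"""Pipeline configuration: nested dataclasses, YAML loading, dotted-key
overrides, and range validation that names the offending key."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from . import extract as _extract
from . import fascia as _fascia
from . import preprocess as _pre
from .fuzzyart import FuzzyARTParams


@dataclass
class StretchConfig:
    low_frac: float = _pre.DEFAULT_TAIL_FRAC
    high_frac: float = _pre.DEFAULT_TAIL_FRAC


@dataclass
class NoiseFilterConfig:
    min_area: int = _pre.DEFAULT_MIN_AREA


@dataclass
class LabelingConfig:
    connectivity: int = _pre.DEFAULT_CONNECTIVITY


@dataclass
class FasciaConfig:
    width_frac: float = _fascia.DEFAULT_WIDTH_FRAC
    bottom_tol_frac: float = _fascia.DEFAULT_BOTTOM_TOL_FRAC
    knot_stride: int = _fascia.DEFAULT_KNOT_STRIDE


@dataclass
class RoiConfig:
    margin_px: int = _fascia.DEFAULT_ROI_MARGIN


@dataclass
class FuzzyArtConfig:
    rho: float = 0.85
    alpha: float = 0.5
    beta_max: float = 1.0
    max_clusters: int = 16

    def to_params(self) -> FuzzyARTParams:
        return FuzzyARTParams(
            rho=self.rho,
            alpha=self.alpha,
            beta_max=self.beta_max,
            max_clusters=self.max_clusters,
        )


@dataclass
class ExtractConfig:
    dark_quantile: float = _extract.DEFAULT_DARK_QUANTILE
    erode_radius: int = _extract.DEFAULT_ERODE_RADIUS
    erode_iterations: int = _extract.DEFAULT_ERODE_ITERATIONS
    min_area: int = _extract.DEFAULT_MIN_CANDIDATE_AREA


_RANGES = {
    "stretch.low_frac": lambda v: 0 <= v < 0.5,
    "stretch.high_frac": lambda v: 0 <= v < 0.5,
    "noise_filter.min_area": lambda v: v >= 0,
    "labeling.connectivity": lambda v: v in (4, 8),
    "fascia.width_frac": lambda v: 0 < v <= 1,
    "fascia.bottom_tol_frac": lambda v: 0 <= v <= 1,
    "fascia.knot_stride": lambda v: v >= 1,
    "roi.margin_px": lambda v: v >= 0,
    "fuzzyart.rho": lambda v: 0 < v <= 1,
    "fuzzyart.alpha": lambda v: 0 <= v <= 1,
    "fuzzyart.beta_max": lambda v: v > 0,
    "fuzzyart.max_clusters": lambda v: v >= 1,
    "extract.dark_quantile": lambda v: 0 < v <= 1,
    "extract.erode_radius": lambda v: v >= 1,
    "extract.erode_iterations": lambda v: v >= 0,
    "extract.min_area": lambda v: v >= 0,
}


@dataclass
class PipelineConfig:
    """All tunable parameters of the extraction pipeline, with defaults."""

    stretch: StretchConfig = field(default_factory=StretchConfig)
    noise_filter: NoiseFilterConfig = field(default_factory=NoiseFilterConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    fascia: FasciaConfig = field(default_factory=FasciaConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    fuzzyart: FuzzyArtConfig = field(default_factory=FuzzyArtConfig)
    extract: ExtractConfig = field(default_factory=ExtractConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key, ok in _RANGES.items():
            section, name = key.split(".")
            value = getattr(getattr(self, section), name)
            if not ok(value):
                raise ConfigError(f"config key '{key}' = {value!r} is out of range")
        if self.stretch.low_frac + self.stretch.high_frac >= 1:
            raise ConfigError("stretch.low_frac + stretch.high_frac must be < 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def set_key(self, dotted: str, value) -> None:
        """Apply one ``section.key=value`` override (numbers parsed)."""
        if dotted not in _RANGES:
            raise ConfigError(f"unknown config key '{dotted}'")
        section, name = dotted.split(".")
        current = getattr(getattr(self, section), name)
        if isinstance(value, str):
            try:
                value = type(current)(float(value)) if isinstance(current, (int, float)) else value
            except ValueError as exc:
                raise ConfigError(f"cannot parse value for '{dotted}': {value!r}") from exc
        setattr(getattr(self, section), name, value)
        self.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for section, entries in (data or {}).items():
            if not hasattr(cfg, section) or not isinstance(entries, dict):
                raise ConfigError(f"unknown config section '{section}'")
            for name, value in entries.items():
                cfg.set_key(f"{section}.{name}", value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
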