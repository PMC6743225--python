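"""Pipeline configuration.

All numeric parameters of every stage live in one :class:`PipelineConfig`
object with the published defaults, so a whole run is reproducible from a
single YAML document.  Validation is strict: non-positive lengths, inverted
bands and unknown keys are rejected rather than silently accepted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: 10-20 montage used throughout: Fpz is recorded solely for ocular-artifact
#: handling and never enters the feature matrix.
MONTAGE: tuple[str, ...] = (
    "Fpz", "AF3", "AF4", "AF7", "AF8", "Fz", "F3", "F4", "F7", "F8",
    "CP3", "CP4", "Pz", "P3", "P4",
)

FRONTAL: tuple[str, ...] = ("AF3", "AF4", "AF7", "AF8", "Fz", "F3", "F4", "F7", "F8")
CENTRO_PARIETAL: tuple[str, ...] = ("CP3", "CP4", "Pz", "P3", "P4")
PARIETAL: tuple[str, ...] = ("Pz", "P3", "P4")

BLINK_CHANNEL = "Fpz"


@dataclass
class FilterConfig:
    low_hz: float = 1.0
    high_hz: float = 30.0
    order: int = 5
    #: online operation demands a causal filter; zero-phase is offline-only
    zero_phase: bool = False


@dataclass
class EpochConfig:
    length_s: float = 2.0
    step_s: float = 0.125


@dataclass
class ArtifactConfig:
    amp_uv: float = 100.0
    trend_r2: float = 0.3
    trend_slope_uv_s: float = 10.0
    jump_uv: float = 25.0


@dataclass
class BlinkConfig:
    channel: str = BLINK_CHANNEL
    mad_mult: float = 4.0
    min_dur_s: float = 0.05
    pad_s: float = 0.05


@dataclass
class BandConfig:
    theta_offsets: tuple[float, float] = (-6.0, -2.0)
    alpha_offsets: tuple[float, float] = (-2.0, 2.0)
    beta_offsets: tuple[float, float] = (2.0, 16.0)
    iaf_search_hz: tuple[float, float] = (7.0, 13.0)
    #: required ratio of the alpha peak over the fitted 1/f trend
    iaf_peak_ratio: float = 2.0
    frontal: tuple[str, ...] = FRONTAL
    centro_parietal: tuple[str, ...] = CENTRO_PARIETAL
    parietal: tuple[str, ...] = PARIETAL


@dataclass
class FeatureConfig:
    log: bool = True
    #: keep per-bin features (the default); band_mean averages bins per band
    band_mean: bool = False


@dataclass
class ClassifierConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    max_features: int = 30
    threshold_mode: str = "midpoint"  # or "fixed0.5"


@dataclass
class SmoothConfig:
    window_s: float = 30.0


@dataclass
class ControllerConfig:
    period_s: float = 300.0


@dataclass
class FixationConfig:
    area_frac: float = 0.002
    min_dur_s: float = 0.020
    assign_radius: float = 0.05


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    blink: BlinkConfig = field(default_factory=BlinkConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    asswlda: ClassifierConfig = field(default_factory=ClassifierConfig)
    smooth: SmoothConfig = field(default_factory=SmoothConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    fixation: FixationConfig = field(default_factory=FixationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        f = self.filter
        if not (0 < f.low_hz < f.high_hz):
            raise ConfigError("filter band must satisfy 0 < low < high")
        if f.order < 1:
            raise ConfigError("filter order must be >= 1")
        e = self.epoch
        if e.length_s <= 0 or e.step_s <= 0:
            raise ConfigError("epoch length and step must be positive")
        a = self.artifact
        if min(a.amp_uv, a.jump_uv, a.trend_slope_uv_s) <= 0 or not (0 < a.trend_r2 < 1):
            raise ConfigError("artifact thresholds out of range")
        b = self.bands
        for name, (lo, hi) in (
            ("theta", b.theta_offsets), ("alpha", b.alpha_offsets), ("beta", b.beta_offsets),
        ):
            if lo >= hi:
                raise ConfigError(f"{name} band offsets are inverted")
        if b.iaf_search_hz[0] >= b.iaf_search_hz[1]:
            raise ConfigError("IAF search range is inverted")
        c = self.asswlda
        if not (0 < c.p_enter <= 1) or not (0 < c.p_remove <= 1):
            raise ConfigError("stepwise p thresholds must be in (0, 1]")
        if c.max_features < 1:
            raise ConfigError("max_features must be >= 1")
        if c.threshold_mode not in ("midpoint", "fixed0.5"):
            raise ConfigError(f"unknown threshold mode {c.threshold_mode!r}")
        if self.smooth.window_s <= e.step_s:
            raise ConfigError("smoothing window must exceed the epoch step")
        if self.controller.period_s <= 0:
            raise ConfigError("controller period must be positive")
        fx = self.fixation
        if fx.area_frac <= 0 or fx.min_dur_s <= 0 or fx.assign_radius <= 0:
            raise ConfigError("fixation parameters must be positive")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        section_types = {f.name: f.type for f in dataclasses.fields(cls)}
        factories = {
            "filter": FilterConfig, "epoch": EpochConfig, "artifact": ArtifactConfig,
            "blink": BlinkConfig, "bands": BandConfig, "features": FeatureConfig,
            "asswlda": ClassifierConfig, "smooth": SmoothConfig,
            "controller": ControllerConfig, "fixation": FixationConfig,
        }
        for key, val in d.items():
            if key == "seed":
                kwargs["seed"] = int(val)
                continue
            if key not in factories:
                raise ConfigError(f"unknown config section {key!r}")
            fac = factories[key]
            known = {f.name for f in dataclasses.fields(fac)}
            bad = set(val) - known
            if bad:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(bad)}")
            sec = {k: tuple(v) if isinstance(v, list) else v for k, v in val.items()}
            kwargs[key] = fac(**sec)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d or {})
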