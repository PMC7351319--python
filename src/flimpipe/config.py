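"""Run configuration: a single validated, YAML-round-trippable object that
holds every fixed constant of the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _check_fields(section: str, data: dict, cls):
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config field {section}.{key}")


@dataclass
class CohortConfig:
    n_patients: int = 3
    n_points: int = 120
    contrast: float = 1.0
    complementary: bool = False
    snr_mean: float = 42.0
    snr_sd: float = 5.0
    contexts: list = field(default_factory=lambda: ["in_vivo_pre", "ex_vivo", "tumor_bed"])
    spot_radius: float = 10.0


@dataclass
class InstrumentConfig:
    sampling_interval: float = 0.08
    samples_per_channel: int = 512
    baseline_samples: int = 64
    irf_fwhm: float = 0.6
    irf_center: float = 3.0
    background_level: float = 0.02
    frame_size: list = field(default_factory=lambda: [1280, 720])


@dataclass
class LaguerreConfig:
    order: int = 12
    envelopes: list = field(default_factory=lambda: [1.0, 2.0, 4.0, 8.0, 16.0])


@dataclass
class ThresholdConfig:
    snr_db: float = 30.0
    mad_k: float = 2.5
    radius_px: float = 10.0


@dataclass
class InterpolationConfig:
    power: float = 2.0
    radius: float = 30.0
    snr_weighting: str = "amplitude"


@dataclass
class LocalizationConfig:
    hue_min: float = 200.0
    hue_max: float = 280.0
    saturation_min: float = 0.4
    min_area: int = 20


@dataclass
class VisualizationConfig:
    enabled: bool = True
    max_scans: int = 2
    alpha: float = 0.6
    colormap: str = "jet"


_SECTIONS = {
    "cohort": CohortConfig,
    "instrument": InstrumentConfig,
    "laguerre": LaguerreConfig,
    "thresholds": ThresholdConfig,
    "interpolation": InterpolationConfig,
    "localization": LocalizationConfig,
    "visualization": VisualizationConfig,
}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "flim_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    laguerre: LaguerreConfig = field(default_factory=LaguerreConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    interpolation: InterpolationConfig = field(default_factory=InterpolationConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    visualization: VisualizationConfig = field(default_factory=VisualizationConfig)

    def validate(self):
        if self.cohort.n_patients < 1:
            raise ConfigError("cohort.n_patients must be >= 1")
        if self.thresholds.radius_px <= 0:
            raise ConfigError("thresholds.radius_px must be positive")
        if self.instrument.sampling_interval <= 0:
            raise ConfigError("instrument.sampling_interval must be positive")
        if self.interpolation.snr_weighting not in ("amplitude", "db", "none"):
            raise ConfigError("interpolation.snr_weighting must be amplitude|db|none")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        top_known = {"seed", "output_dir", *_SECTIONS}
        for key in data:
            if key not in top_known:
                raise ConfigError(f"unknown config field {key}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = data.pop(name, {}) or {}
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name} must be a mapping")
            _check_fields(name, section, section_cls)
            kwargs[name] = section_cls(**section)
        kwargs["seed"] = int(data.get("seed", 0))
        kwargs["output_dir"] = str(data.get("output_dir", "flim_run"))
        return cls(**kwargs).validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
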