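"""Configuration objects for every pipeline stage.

All tunables are plain dataclasses so a whole run is describable by one
nested mapping (YAML on disk).  ``load_config`` fills defaults and rejects
unknown keys with the offending key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


#: Intraoperative channels the pipeline understands, with their units.
CHANNEL_UNITS: dict[str, str] = {
    "MAP": "mmHg",
    "HR": "beats/min",
    "SPO2": "%",
    "BT": "degC",
    "ETCO2": "mmHg",
    "RR": "breaths/min",
    "TV": "mL",
    "MV": "L/min",
    "PEEP": "cmH2O",
    "PIP": "cmH2O",
    "PPLAT": "cmH2O",
    "MAWP": "cmH2O",
    "FIO2": "fraction",
    "CO": "L/min",
}

CHANNELS: tuple[str, ...] = tuple(CHANNEL_UNITS)

#: Physiologic plausibility bounds (min, max) per channel.  Values outside
#: these are removed before any statistic is computed.  These are documented
#: clinical-range defaults, configurable per run.
DEFAULT_PLAUSIBILITY: dict[str, tuple[float, float]] = {
    "MAP": (20.0, 200.0),
    "HR": (20.0, 220.0),
    "SPO2": (50.0, 100.0),
    "BT": (30.0, 42.0),
    "ETCO2": (5.0, 90.0),
    "RR": (4.0, 60.0),
    "TV": (50.0, 1500.0),
    "MV": (0.5, 30.0),
    "PEEP": (0.0, 25.0),
    "PIP": (1.0, 60.0),
    "PPLAT": (1.0, 50.0),
    "MAWP": (1.0, 40.0),
    "FIO2": (0.21, 1.0),
    "CO": (1.0, 15.0),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic surgical-cohort generator.

    The defaults encode the study conditions the analysis assumes: entry
    delays with median 34 s and IQR 22-54 s, roughly 11.4% of blood draws
    without a detectable MAP surge, and an arterial-to-end-tidal CO2
    gradient averaging about 7.6 mmHg that rises with age and falls with
    body temperature, SpO2/FiO2 ratio and respiratory-system compliance.
    """

    n_cases: int = 300
    seed: int = 42
    case_duration_s: tuple[float, float] = (3000.0, 7200.0)
    sample_interval_s: float = 1.0
    abga_per_case: tuple[int, int] = (2, 6)
    surge_amplitude: tuple[float, float] = (20.0, 40.0)   # mmHg
    surge_duration_s: tuple[float, float] = (15.0, 40.0)
    no_surge_fraction: float = 0.114
    # recorded-entry delay: log-normal, calibrated to median 34 s, IQR 22-54 s
    entry_delay_mu: float = 3.5264                        # ln(34)
    entry_delay_sigma: float = 0.6656
    entry_delay_max_s: float = 600.0
    # PaCO2 - ETCO2 gradient model (linear in engineered covariates)
    gamma0: float = 6.65
    gamma_age: float = 0.6       # mmHg per decade above 50 y
    gamma_bt: float = 1.5        # mmHg per degC below 36.5
    gamma_sf: float = 0.5        # mmHg per 100-unit SpO2/FiO2 deficit from 400
    gamma_crs: float = 1.0       # mmHg per 10 mL/cmH2O compliance deficit from 50
    sigma_g: float = 1.5         # mmHg, Gaussian gradient noise
    # overall SD of the bounded quasi-periodic MAP baseline variability
    map_noise_sd: float = 4.0
    # off-draw distractor bumps (per hour), exercising nearest-period selection
    distractor_rate_per_h: float = 0.2
    # fraction of events with one ventilator channel masked (missing-data drills)
    missing_channel_fraction: float = 0.0
    min_gap_s: float = 300.0
    first_draw_s: float = 1300.0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        for name in ("case_duration_s", "abga_per_case", "surge_amplitude",
                     "surge_duration_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")
        if not 0.0 <= self.no_surge_fraction < 1.0:
            raise ConfigError("no_surge_fraction must be in [0, 1)")
        if self.sigma_g < 0:
            raise ConfigError("sigma_g must be >= 0")
        if self.sample_interval_s <= 0:
            raise ConfigError("sample_interval_s must be > 0")
        if self.abga_per_case[0] < 1:
            raise ConfigError("abga_per_case minimum must be >= 1")
        if not 0.0 <= self.missing_channel_fraction < 1.0:
            raise ConfigError("missing_channel_fraction must be in [0, 1)")


@dataclass
class AlignmentConfig:
    """Event-timestamp refinement parameters.

    A blood draw through the arterial line transiently occludes it, raising
    the measured MAP; the detector looks back ``lookback_s`` (20 min) from
    the recorded ABGA timestamp for samples whose z score within that window
    exceeds ``z_threshold``, and takes the abnormal period nearest the
    recorded time as the estimated draw.  The feature trigger sits
    ``pre_trigger_s`` before the estimated draw, and the observation window
    of ``window_s`` ends ``blackout_s`` before the trigger.
    """

    z_threshold: float = 3.0
    lookback_s: float = 1200.0
    pre_trigger_s: float = 60.0
    blackout_s: float = 0.0
    window_s: float = 60.0
    min_window_samples: int = 10

    def validate(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be > 0")
        for name in ("lookback_s", "pre_trigger_s", "window_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.blackout_s < 0:
            raise ConfigError("blackout_s must be >= 0")
        if self.min_window_samples < 2:
            raise ConfigError("min_window_samples must be >= 2")


@dataclass
class FeatureConfig:
    """Feature-extraction options: outlier filtering and plausibility bounds."""

    iqr_k: float = 3.0
    plausibility: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLAUSIBILITY))
    include_co: bool = True

    def validate(self) -> None:
        if self.iqr_k <= 0:
            raise ConfigError("iqr_k must be > 0")
        for ch, (lo, hi) in self.plausibility.items():
            if lo >= hi:
                raise ConfigError(f"plausibility[{ch}]: min {lo} >= max {hi}")


@dataclass
class SearchSpec:
    """Hyperparameter search contract for the gradient-boosted regressor.

    Seeded random search over the documented space; the inner objective is
    the mean MAE across inner validation folds.
    """

    n_trials: int = 20
    seed: int = 0
    depth: tuple[int, int] = (3, 10)
    learning_rate: tuple[float, float] = (0.01, 0.3)   # log-uniform
    iterations: tuple[int, int] = (100, 1000)
    l2_leaf_reg: tuple[float, float] = (1.0, 10.0)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        for name in ("depth", "learning_rate", "iterations", "l2_leaf_reg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")


@dataclass
class FoldConfig:
    """Case-grouped nested cross-validation layout."""

    k_outer: int = 7
    k_inner: int = 6

    def validate(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ConfigError("k_outer and k_inner must be >= 2")


@dataclass
class EvalConfig:
    """Agreement-evaluation options."""

    ci_level: float = 0.95
    icc_form: str = "ICC2"   # two-way random effects, absolute agreement, single rater

    def validate(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must be in (0, 1)")
        if self.icc_form != "ICC2":
            raise ConfigError(f"unsupported icc_form: {self.icc_form}")


@dataclass
class PipelineConfig:
    """One object describing a full simulate-to-report run."""

    seed: int = 42
    out_dir: str = "results"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    folds: FoldConfig = field(default_factory=FoldConfig)
    search: SearchSpec = field(default_factory=SearchSpec)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def validate(self) -> None:
        self.generator.validate()
        self.alignment.validate()
        self.features.validate()
        self.folds.validate()
        self.search.validate()
        self.evaluation.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _coerce(cls: type, data: dict[str, Any], path: str) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        f = fields[key]
        default = (f.default_factory() if f.default_factory is not dataclasses.MISSING
                   else f.default)
        if dataclasses.is_dataclass(default):
            if not isinstance(value, dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            kwargs[key] = _coerce(type(default), value, f"{path}{key}.")
        elif key == "plausibility":
            kwargs[key] = {ch: tuple(b) for ch, b in value.items()}
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a nested mapping."""
    cfg = _coerce(PipelineConfig, data or {}, "")
    cfg.validate()
    return cfg


def load_config(path: str) -> PipelineConfig:
    """Load a YAML pipeline configuration; empty file means all defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
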