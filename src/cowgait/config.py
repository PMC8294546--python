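"""Run configuration: documented defaults, strict key validation, YAML loading.

Every tunable of the analysis lives here so a run is fully described by one
config file plus a seed.  Unknown keys are rejected rather than ignored, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("cowgait")

GRAVITY = 9.80665  # m/s^2

LIMBS = ("LF", "RF", "LH", "RH")
UPPER_BODY = ("sacrum", "withers", "back", "LTC", "RTC", "head", "collar")
LOCATIONS = LIMBS + UPPER_BODY


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


@dataclass
class EventConfig:
    """Claw-on / claw-off detector settings.

    Detection runs on the signed mediolateral gyro channel: protraction
    (swing) is positive, retraction (stance) negative.  Swing is flagged where
    the low-passed rate exceeds ``swing_frac`` of the positive peak; claw-off
    is refined to the nearest negative-to-positive zero crossing and claw-on
    is snapped to the accelerometer jerk peak (hoof-impact landmark).
    """

    lowpass_hz: float = 15.0          # gyro anti-noise low-pass cutoff
    swing_frac: float = 0.10          # swing threshold as fraction of protraction peak
    min_stance_s: float = 0.10        # shortest admissible stance
    min_swing_s: float = 0.10         # shortest admissible swing
    snap_window_s: float = 0.05       # half-window for landmark refinement
    peak_quantile: float = 0.99       # robust positive-rate peak estimate
    min_peak_dps: float = 30.0        # below this protraction peak: no gait
    jerk_snr_min: float = 5.0         # jerk peak must exceed this x local MAD to snap


@dataclass
class AngleConfig:
    """Quaternion complementary-filter settings for sagittal limb angle."""

    gyro_weight: float = 0.99         # per-sample weight on gyro propagation
    accel_gate_ms2: float = 1.0       # skip accel correction if | |a|-g | exceeds this
    mediolateral_axis: int = 1        # gyro axis indexing the sagittal rotation (y)
    sign: float = 1.0                 # +1: protraction positive with right-hand y rate


@dataclass
class VdispConfig:
    """Cyclic double integration and stride-normalization settings."""

    min_stride_s: float = 0.3         # strides outside this span are skipped
    max_stride_s: float = 3.0
    pad_fraction: float = 0.10        # display padding either side of the stride
    n_samples: int = 100              # points of the stride-normalized curve


@dataclass
class ScreenConfig:
    """Stride-by-stride regularity screen."""

    rel_tol: float = 0.25             # max relative deviation of stance from running median
    running_window: int = 9           # strides in the running-median window
    support_tol_s: float = 0.05       # tolerated duration of 0- or 4-limb support
    max_intervals: int = 4            # included contiguous runs kept per measurement


@dataclass
class InferenceConfig:
    """Bootstrap and mixed-model settings."""

    bootstrap_reps: int = 2000
    ci_level: float = 0.95
    cluster_by_cow: bool = False      # cow-level cluster bootstrap for group estimates
    curve_metric: str = "rms"         # 'rms' or 'mean_abs' for the most-typical curve


@dataclass
class Config:
    """Full analysis configuration with documented defaults."""

    rate_hz: float = 200.0
    seed: int = 0
    output_units_mm: bool = True      # report displacement curves in millimetres
    events: EventConfig = field(default_factory=EventConfig)
    angle: AngleConfig = field(default_factory=AngleConfig)
    vdisp: VdispConfig = field(default_factory=VdispConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    def log_startup(self) -> None:
        log.info("configuration: %s", self)


_SECTIONS = {
    "events": EventConfig,
    "angle": AngleConfig,
    "vdisp": VdispConfig,
    "screen": ScreenConfig,
    "inference": InferenceConfig,
}


def _build(cls, data: dict, where: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown key {key!r} in {where}")
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config file; absent keys take their documented defaults.

    An empty or missing-section file yields the full default configuration.
    Any unknown key raises :class:`ConfigError` naming the key.
    """
    if path is None:
        cfg = Config()
        cfg.log_startup()
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    top_fields = {f.name for f in dataclasses.fields(Config)}
    kwargs = {}
    for key, value in raw.items():
        if key not in top_fields:
            raise ConfigError(f"unknown key {key!r} in config root")
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value, f"section {key!r}")
        else:
            kwargs[key] = value
    cfg = Config(**kwargs)
    cfg.log_startup()
    return cfg
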