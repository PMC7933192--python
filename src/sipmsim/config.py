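"""Structured run configuration: YAML in, validated dataclasses out.

All physical quantities carry explicit unit suffixes in their key names
(``_hz``, ``_s``, ``_w``, ``_a``, ``_v``, ``_ohm``, ``_f``, ``_j``) so a
config file cannot silently mix units.  Unknown keys are rejected and
validation errors name the offending section and field.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chain import BiasSupplyParams, ImpulseResponseParams
from .fluorophore import FluorophoreParams
from .imaging import ScanGeometry
from .montecarlo import SiPMDeviceParams

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Config parsing or validation failure, with the field path."""


def _log_grid(lo: float, hi: float, n: int) -> list[float]:
    return [float(x) for x in np.geomspace(lo, hi, n)]


@dataclass
class ChainConfig:
    """Analog chain settings: impulse response, PZC, lowpass, bias supply."""

    impulse: ImpulseResponseParams = field(default_factory=ImpulseResponseParams)
    pzc_time_constant_s: float | None = None  # None -> match the slow time constant
    pzc_attenuation: float = 0.1
    lowpass_cutoff_hz: float = 25e6
    lowpass_order: int = 4
    lowpass_family: str = "butterworth"
    bias: BiasSupplyParams | None = None


@dataclass
class PTCConfig:
    """Monte Carlo PTC sweep settings."""

    flux_grid_hz: list = field(default_factory=lambda: _log_grid(1e8, 1e10, 5))
    equivalent_bandwidth: float = 1.0
    min_samples: int = 2_000_000
    target_detected_events: int = 2_000_000
    settle_constants: float = 50.0


@dataclass
class SweepConfig:
    """Fluorophore repetition-rate sweep settings."""

    lifetimes_s: list = field(default_factory=lambda: [0.5e-9, 3e-9, 10e-9])
    rates_hz: list = field(default_factory=lambda: _log_grid(10e6, 800e6, 25))
    reference_rate_hz: float = 78e6


@dataclass
class FramesConfig:
    """Synthetic frame-stack settings (uniform object)."""

    size: int = 64
    brightness: float = 1.0
    photons_at_unit_brightness: float = 100.0
    n_frames: int = 16
    detector: str = "ideal"
    dwell_s: float = 1e-7
    excess_noise_factor: float | None = None  # required for the pmt detector


@dataclass
class SnrConfig:
    """SNR-plan settings."""

    saturation_flux_hz: float = 2e9
    pixel_rate_hz: float | None = None  # None -> derive from scan geometry


@dataclass
class RunConfig:
    seed: int = 0
    device: SiPMDeviceParams = field(default_factory=SiPMDeviceParams)
    chain: ChainConfig = field(default_factory=ChainConfig)
    scan: ScanGeometry = field(default_factory=ScanGeometry)
    fluorophore: FluorophoreParams = field(default_factory=FluorophoreParams)
    ptc: PTCConfig = field(default_factory=PTCConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    frames: FramesConfig = field(default_factory=FramesConfig)
    snr: SnrConfig = field(default_factory=SnrConfig)


# Which fields are nested section dataclasses (for recursive building).
_NESTED: dict[tuple[type, str], type] = {
    (RunConfig, "device"): SiPMDeviceParams,
    (RunConfig, "chain"): ChainConfig,
    (RunConfig, "scan"): ScanGeometry,
    (RunConfig, "fluorophore"): FluorophoreParams,
    (RunConfig, "ptc"): PTCConfig,
    (RunConfig, "sweep"): SweepConfig,
    (RunConfig, "frames"): FramesConfig,
    (RunConfig, "snr"): SnrConfig,
    (ChainConfig, "impulse"): ImpulseResponseParams,
    (ChainConfig, "bias"): BiasSupplyParams,
}


def _build(cls: type, data, path: str = ""):
    label = path or "config"
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{label}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigError(f"{label}: unknown keys {unknown}")
    kwargs = {}
    for name, value in data.items():
        sub = _NESTED.get((cls, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}" if path else name)
        else:
            # YAML null on a section key means "section absent/off"
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{label}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    return _build(RunConfig, data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def to_dict(config: RunConfig) -> dict:
    return _plain(dataclasses.asdict(config))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical serialized config (manifest provenance)."""
    canonical = yaml.safe_dump(to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
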