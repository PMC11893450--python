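"""Structured run configuration: schema-validated, YAML round-trippable.

Every random operation in a run receives an explicit seed derived from the
single ``seed`` field, so a config fully determines the outputs.  Unknown
keys are rejected by name.  All distances are mm, times microseconds,
frequencies MHz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .acoustic import (MEDIUM_PRESETS, ArrayGeometry, MediumProperties,
                       PulseShape, TransducerResponse, matrix_array)
from .beam_dose import BeamSpec
from .denoise import WaveletFilterSpec
from .volume import GridSpec

# Single-frame peak SNR of the default noisy-acquisition scene.  Calibrated
# once so that 50-frame averaging localizes the Bragg peak to within 2 mm in
# the default 87 MeV scene, then held fixed (see docs/methods.md).
DEFAULT_SNR_SINGLE_FRAME = 2.0


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


@dataclass(frozen=True)
class ArraySpec:
    rows: int = 16
    cols: int = 16
    element_size_mm: float = 3.0
    kerf_mm: float = 0.2
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kerf_mm < 0:
            raise ValueError("kerf must be >= 0 (pitch = element size + kerf)")
        object.__setattr__(self, "center_mm", tuple(float(x) for x in self.center_mm))
        object.__setattr__(self, "normal", tuple(float(x) for x in self.normal))

    def build(self) -> ArrayGeometry:
        return matrix_array(self.rows, self.cols, self.element_size_mm,
                            self.kerf_mm, self.center_mm, self.normal)


@dataclass(frozen=True)
class GridConfig:
    shape: tuple[int, int, int]
    spacing_mm: float = 0.4
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(x) for x in self.origin_mm))

    def build(self) -> GridSpec:
        return GridSpec.isotropic(self.shape, self.spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class BeamConfig:
    energy_mev: float = 87.0
    entry_point_mm: tuple[float, float, float] = (0.0, 0.0, 75.0)
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    lateral_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry_point_mm",
                           tuple(float(x) for x in self.entry_point_mm))
        object.__setattr__(self, "direction", tuple(float(x) for x in self.direction))

    def build(self, pulse_duration_us: float) -> BeamSpec:
        return BeamSpec(self.energy_mev, self.entry_point_mm, self.direction,
                        self.lateral_sigma_mm, pulse_duration_us)


@dataclass(frozen=True)
class PulseConfig:
    duration_us: float = 4.0
    kind: str = "trapezoid"
    rise_fraction: float = 0.1

    def build(self) -> PulseShape:
        return PulseShape(self.duration_us, self.kind, self.rise_fraction)


@dataclass(frozen=True)
class TransducerConfig:
    center_frequency_mhz: float = 1.0
    fractional_bandwidth_pct: float = 60.0

    def build(self) -> TransducerResponse:
        return TransducerResponse(self.center_frequency_mhz,
                                  self.fractional_bandwidth_pct)


@dataclass(frozen=True)
class AcquisitionConfig:
    sampling_mhz: float = 20.0
    record_length_us: float = 75.0
    snr_single_frame: float = DEFAULT_SNR_SINGLE_FRAME
    n_averages: int = 50
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.sampling_mhz <= 0 or self.record_length_us <= 0:
            raise ValueError("sampling rate and record length must be positive")
        if self.snr_single_frame <= 0:
            raise ValueError("single-frame SNR must be positive")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")


@dataclass(frozen=True)
class DenoiseConfig:
    enabled: bool = False
    wavelet: str = "sym8"
    levels: int = 5
    threshold_scale: float = 1.0
    cutoff_mhz: float | None = 0.12

    def build(self) -> WaveletFilterSpec:
        return WaveletFilterSpec(self.wavelet, self.levels,
                                 threshold_scale=self.threshold_scale,
                                 cutoff_mhz=self.cutoff_mhz)


@dataclass(frozen=True)
class ReconConfig:
    variant: str = "das"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("das", "ubp"):
            raise ValueError(f"variant must be 'das' or 'ubp', got {self.variant!r}")


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of one simulate->reconstruct->evaluate run."""

    medium: str | dict = "water"
    array: ArraySpec = field(default_factory=ArraySpec)
    transducer: TransducerConfig = field(default_factory=TransducerConfig)
    pulse: PulseConfig = field(default_factory=PulseConfig)
    beam: BeamConfig = field(default_factory=BeamConfig)
    dose_grid: GridConfig = field(default_factory=lambda: GridConfig(
        (61, 61, 180), 0.4, (-12.0, -12.0, 4.0)))
    recon_grid: GridConfig = field(default_factory=lambda: GridConfig(
        (51, 51, 66), 0.4, (-10.0, -10.0, 6.0)))
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.medium, str) and self.medium not in MEDIUM_PRESETS:
            raise ConfigError(
                f"unknown medium preset {self.medium!r}; "
                f"choose from {sorted(MEDIUM_PRESETS)} or give explicit properties"
            )
        # Build the derived objects once to run their invariant checks.
        self.build_medium()
        self.array.build()
        self.transducer.build()
        self.pulse.build()

    def build_medium(self) -> MediumProperties:
        if isinstance(self.medium, str):
            return MEDIUM_PRESETS[self.medium]()
        return _from_mapping(MediumProperties, dict(self.medium), "medium")

    def stage_seed(self, stage: str) -> int:
        """Independent per-stage stream seeded from the global seed."""
        h = 2166136261
        for b in stage.encode():
            h = ((h ^ b) * 16777619) % 2**32
        return ((self.seed * 2654435761) % 2**32 ^ h) % (2**31 - 1)


_SECTIONS = {
    "array": ArraySpec, "transducer": TransducerConfig, "pulse": PulseConfig,
    "beam": BeamConfig, "dose_grid": GridConfig, "recon_grid": GridConfig,
    "acquisition": AcquisitionConfig, "denoise": DenoiseConfig, "recon": ReconConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    unknown = set(data) - (set(_SECTIONS) | {"medium", "seed"})
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _from_mapping(cls, data.pop(name) or {}, name)
    kwargs.update(data)
    return _from_mapping(RunConfig, kwargs, "run")


def config_to_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def load_config(path: str) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(cfg), f, sort_keys=False)
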