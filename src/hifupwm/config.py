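"""Run configuration: defaults, YAML loading, strict key validation.

Every default equals the study's stated operating point where one exists
(1.1 MHz centre frequency, 64 mm / 63 mm bowl, 112 um grid, 20 s exposure
+ 10 s cooling from 37 C, CEM43 >= 240 min, 380 mV / 50 ms / 250 us / 256
segments PCD capture, 500 kHz - 10 MHz power band, 26 W calibrated surface
acoustic power).  The schema is a flat two-level mapping (group -> key);
unknown groups or keys are errors so that a typo cannot silently
mis-parameterize a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .field import Layer, MediumStack, TransducerModel
from .bioheat import ThermalProperties

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class ExcitationConfig:
    centre_frequency: float = 1.1e6
    modulation_index: float = 0.70
    duty_cycle: float = 0.5
    samples_per_cycle: int = 256
    n_cycles: int = 8
    rail_step: float = 30.0


@dataclass
class TransducerConfig:
    aperture_diameter: float = 0.064
    focal_length: float = 0.063
    centre_frequency: float = 1.1e6
    fir_order: int = 50


@dataclass
class LayerConfig:
    name: str = "layer"
    sound_speed: float = 1482.0
    density: float = 1000.0
    absorption_coeff: float = 0.0
    absorption_exponent: float = 2.0
    thickness: float = 0.043


@dataclass
class MediaConfig:
    layers: list = field(default_factory=lambda: [
        LayerConfig("water", 1482.0, 1000.0, 0.0, 2.0, 0.043),
        LayerConfig("tissue", 1547.0, 1060.0, 0.52, 1.1, 0.045),
    ])


@dataclass
class ThermalConfig:
    density: float = 1060.0
    sound_speed: float = 1547.0
    specific_heat: float = 3421.0
    conductivity: float = 0.49
    perfusion_rate: float = 0.0
    blood_temperature: float = 37.0


@dataclass
class ExposureConfig:
    acoustic_power_w: float = 26.0
    t_on: float = 20.0
    t_cool: float = 10.0
    start_temperature: float = 37.0
    cem43_threshold_min: float = 240.0


@dataclass
class GridConfig:
    spacing: float = 112e-6
    r_max: float = 0.032
    z_max: float = 0.078
    scaled_spacing: float = 0.5e-3


@dataclass
class SolverConfig:
    dt: float | None = None
    store_every: int = 1
    n_harmonics: int = 6


@dataclass
class PCDConfig:
    trigger_threshold: float = 0.380
    holdoff: float = 0.050
    segment_length: float = 250e-6
    max_segments: int = 256
    highpass_hz: float = 5e6


@dataclass
class PowerBandConfig:
    f_lo: float = 500e3
    f_hi: float = 10e6


@dataclass
class RunConfig:
    """Aggregated parameter groups for a full comparison run."""

    excitation: ExcitationConfig = field(default_factory=ExcitationConfig)
    transducer: TransducerConfig = field(default_factory=TransducerConfig)
    media: MediaConfig = field(default_factory=MediaConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    pcd: PCDConfig = field(default_factory=PCDConfig)
    power_band: PowerBandConfig = field(default_factory=PowerBandConfig)
    seed: int = 0

    def transducer_model(self) -> TransducerModel:
        t = self.transducer
        return TransducerModel(t.aperture_diameter, t.focal_length,
                               t.centre_frequency, t.fir_order)

    def medium_stack(self) -> MediumStack:
        return MediumStack(tuple(
            Layer(l.name, l.sound_speed, l.density, l.absorption_coeff,
                  l.absorption_exponent, l.thickness)
            for l in self.media.layers
        ))

    def thermal_properties(self) -> ThermalProperties:
        t = self.thermal
        return ThermalProperties(
            density=t.density, sound_speed=t.sound_speed,
            specific_heat=t.specific_heat, conductivity=t.conductivity,
            perfusion_rate=t.perfusion_rate,
            blood_temperature=t.blood_temperature,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _apply(obj, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, val in data.items():
        if key not in names:
            raise KeyError(f"unknown configuration key {path}{key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, dict):
            _apply(current, val, f"{path}{key}.")
        elif key == "layers":
            if not isinstance(val, list):
                raise TypeError("media.layers must be a list of mappings")
            layers = []
            for entry in val:
                lc = LayerConfig()
                _apply(lc, entry, f"{path}layers[].")
                layers.append(lc)
            obj.layers = layers
        else:
            setattr(obj, key, val)


def load_config(path_or_mapping) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a mapping.

    Unknown keys anywhere in the document are errors.
    """
    if isinstance(path_or_mapping, dict):
        data = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise TypeError("configuration document must be a mapping")
    cfg = RunConfig()
    _apply(cfg, data, "")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full parameter set, embedded in artifacts."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
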