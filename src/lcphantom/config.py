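"""Structured study configuration: beams, phantoms, detector, protocol.

A study config is a single YAML document; every field has a default that
reproduces the reference validation conditions (three Cu-hardened beams,
central LC module vs the 8-mm reference column, 73/78/66 uGy/min).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .geometry import (
    PhantomModel,
    build_cdrad_column,
    build_plate_a,
    build_plate_b,
    build_plate_c,
)
from .roi import CnrProtocol
from .simulate import (
    DEFAULT_KERMA_RATES,
    DEFAULT_QUANTA_PER_KERMA_PIXEL,
    AcquisitionConfig,
    DetectorModel,
)
from .spectrum import DEFAULT_BEAMS, BeamQuality

__all__ = ["StudyConfig", "PHANTOM_BUILDERS"]

PHANTOM_BUILDERS = {
    "plate_a": build_plate_a,
    "plate_b": build_plate_b,
    "plate_c": build_plate_c,
    "cdrad_column": build_cdrad_column,
}


@dataclass
class StudyConfig:
    master_seed: int = 1
    output_dir: str = "lcphantom_out"
    replicates: int = 1
    beams: list = field(default_factory=lambda: ["Q1", "Q2", "Q3"])
    phantoms: list = field(default_factory=lambda: ["plate_a", "cdrad_column"])
    lc_phantom: str = "plate_a"
    reference_phantom: str = "cdrad_column"
    detector: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    observer: dict = field(
        default_factory=lambda: {
            "criterion_cnr": 1.2,
            "n_observers": 5,
            "jitter_sd_mm": 0.15,
        }
    )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    # -- resolved objects -------------------------------------------------
    def beam(self, name: str) -> BeamQuality:
        if name not in DEFAULT_BEAMS:
            raise KeyError(f"unknown beam {name!r}; known: {sorted(DEFAULT_BEAMS)}")
        return DEFAULT_BEAMS[name]

    def phantom(self, name: str) -> PhantomModel:
        if name not in PHANTOM_BUILDERS:
            raise KeyError(
                f"unknown phantom {name!r}; known: {sorted(PHANTOM_BUILDERS)}"
            )
        return PHANTOM_BUILDERS[name]()

    def detector_model(self) -> DetectorModel:
        return DetectorModel(**self.detector)

    def cnr_protocol(self) -> CnrProtocol:
        return CnrProtocol(**self.protocol)

    def acquisition_for(self, beam_name: str, seed: int) -> AcquisitionConfig:
        acq = dict(self.acquisition)
        rates = acq.pop("kerma_rates", DEFAULT_KERMA_RATES)
        return AcquisitionConfig(
            beam=self.beam(beam_name),
            air_kerma_rate=float(rates.get(beam_name, 73.0)),
            exposure_time=float(acq.pop("exposure_time_s", 1.0)),
            quanta_per_kerma_pixel=float(
                acq.pop("quanta_per_kerma_pixel", DEFAULT_QUANTA_PER_KERMA_PIXEL)
            ),
            seed=seed,
        )

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
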