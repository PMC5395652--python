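"""Run configuration: a YAML/JSON-serializable bundle of every tunable.

Every command writes its *resolved* configuration (defaults merged with
overrides) next to its results, together with the package version, seeds
and input hashes, so any reported number can be traced to its settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inference import NoiseModel
from .pk_model import PKParameters
from .postprocess import EXENATIDE_MOLAR_MASS_G_PER_MOL
from .sampler import SamplerConfig
from .synthetic_data import TestInputParams

__all__ = ["RunConfig", "load_config", "sha256_of"]


@dataclass
class RunConfig:
    pk: dict = field(default_factory=dict)          # PKParameters overrides
    input_params: dict = field(default_factory=dict)  # TestInputParams overrides
    basis: dict = field(default_factory=lambda: {"n_grid": 200, "n_basis": 20})
    noise: dict = field(default_factory=lambda: {
        "family": "student_t", "sigma": 0.10, "df": 4.0})
    sampler: dict = field(default_factory=dict)     # SamplerConfig overrides
    molar_mass_g_per_mol: float = EXENATIDE_MOLAR_MASS_G_PER_MOL
    bodyweight_kg: float = 90.0

    def pk_params(self) -> PKParameters:
        return PKParameters(**self.pk)

    def test_input_params(self) -> TestInputParams:
        return TestInputParams(**self.input_params)

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def sampler_config(self, **overrides) -> SamplerConfig:
        merged = {**self.sampler, **overrides}
        return SamplerConfig(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()
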