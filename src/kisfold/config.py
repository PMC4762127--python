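"""Run configuration: every tunable model parameter with its default,
loadable from YAML, with unknown keys rejected and the fully resolved
configuration logged on each run."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants

logger = logging.getLogger("kisfold")


@dataclass
class LatticeConfig:
    bond_length: float = constants.VIRTUAL_BOND_LENGTH
    enumeration_cap_nt: int = constants.LOOP_ENUMERATION_CAP_NT


@dataclass
class HelixConfig:
    rise: float = constants.HELIX_RISE
    radius: float = constants.HELIX_RADIUS
    bp_per_turn: int = constants.HELIX_BP_PER_TURN  # fixed by the z(s) phase


@dataclass
class GeometryConfig:
    virtual_bond_length: float = constants.VIRTUAL_BOND_LENGTH
    clash_distance: float = constants.CLASH_DISTANCE
    helix: HelixConfig = field(default_factory=HelixConfig)


@dataclass
class EnergeticsConfig:
    temperature: float = constants.T_DEFAULT
    pseudoknot_beta1: float = 9.6
    pseudoknot_beta2: float = 0.1
    pseudoknot_beta3: float = 0.6
    fjc_a: float = 6.2
    fjc_b: float = 15.0
    fjc_c0: float = 0.0


@dataclass
class EnsembleConfig:
    c_total: float = 1e-6
    dg_init: float = constants.DG_INIT
    min_helix: int = 2
    min_hairpin: int = 3
    length_cap: int = constants.DIMER_LENGTH_CAP_NT
    include_unpaired_associated: bool = True


@dataclass
class RunConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    energetics: EnergeticsConfig = field(default_factory=EnergeticsConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    seed: int = 0  # used only by fixture generation

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_resolved(self) -> None:
        logger.info("resolved configuration: %s", self.to_dict())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, "config")


def _build(dc_type, data: dict, where: str):
    if not isinstance(data, dict):
        raise ValueError(f"{where}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = {
            "LatticeConfig": LatticeConfig,
            "GeometryConfig": GeometryConfig,
            "HelixConfig": HelixConfig,
            "EnergeticsConfig": EnergeticsConfig,
            "EnsembleConfig": EnsembleConfig,
        }.get(str(ftype).split(".")[-1])
        kwargs[name] = _build(nested, value, f"{where}.{name}") if nested else value
    return dc_type(**kwargs)
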