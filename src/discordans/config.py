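"""Run configuration: schema-validated YAML in, fully-resolved config out.

A config file is a nested mapping with optional sections ``ion``, ``ca``,
``geometry``, ``solver`` and ``protocol`` plus top-level keys ``model``,
``preset``, ``scale``, ``seed`` and ``out``.  Unknown keys are rejected with
the offending name.  An empty file yields the all-defaults configuration
(dx = 0.015 cm, D_v = 1e-3 cm²/ms, M = 75 sarcomeres, C_m = 1 µF/cm²).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from ._params import CaCyclingParams, IonicParams, NoiseSource
from .protocols import PacingProtocol

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class GeometryConfig:
    n_x: int = 100
    n_y: int = 1
    m: int = 75
    dx: float = 0.015
    d_v: float = 1e-3

    def validate(self):
        if self.n_x < 1 or self.n_y < 1 or self.m < 1:
            raise ConfigError("geometry.n_x/n_y/m must be >= 1")
        if self.dx <= 0:
            raise ConfigError("geometry.dx must be > 0")
        if self.d_v < 0:
            raise ConfigError("geometry.d_v must be >= 0")


@dataclass
class SolverConfig:
    dt_min: float = 0.01
    dt_max: float = 0.1
    dvdt_switch: float = 5.0

    def validate(self):
        if not 0 < self.dt_min <= self.dt_max:
            raise ConfigError("solver: need 0 < dt_min <= dt_max")


@dataclass
class RunConfig:
    model: str = "cell"
    preset: str | None = None
    scale: str = "small"
    seed: int = 0
    out: str | None = None
    ion: IonicParams = field(default_factory=IonicParams)
    ca: CaCyclingParams = field(default_factory=CaCyclingParams)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    protocol: PacingProtocol | None = None

    def validate(self):
        if self.scale not in ("small", "paper"):
            raise ConfigError(f"scale must be small|paper, got {self.scale!r}")
        self.ion.validate()
        self.ca.validate()
        self.geometry.validate()
        self.solver.validate()
        if self.protocol is not None:
            try:
                self.protocol.validate()
            except ValueError as e:
                raise ConfigError(f"protocol: {e}") from e
        return self


_SECTIONS = {"ion": IonicParams, "ca": CaCyclingParams,
             "geometry": GeometryConfig, "solver": SolverConfig}
_TOP_KEYS = {"model", "preset", "scale", "seed", "out", "protocol",
             *_SECTIONS.keys()}


def _build_section(cls, data, name):
    valid = {f.name for f in fields(cls)}
    kw = {}
    for k, v in (data or {}).items():
        if k not in valid:
            raise ConfigError(f"unknown key {name}.{k}")
        kw[k] = v
    try:
        return cls(**kw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {name} section: {e}") from e


def _build_protocol(data):
    if data is None:
        return None
    valid = {"stages", "stim_sites", "stim_amp", "stim_dur_ms", "s2"}
    for k in data:
        if k not in valid:
            raise ConfigError(f"unknown key protocol.{k}")
    stages = [tuple(s) for s in data.get("stages", [])]
    stim_sites = data.get("stim_sites", "all")
    if isinstance(stim_sites, list) and stim_sites and stim_sites[0] == "left_edge":
        stim_sites = ("left_edge", int(stim_sites[1]))
    return PacingProtocol(stages=stages, stim_sites=stim_sites,
                          stim_amp=data.get("stim_amp", 40.0),
                          stim_dur_ms=data.get("stim_dur_ms", 1.0),
                          s2=tuple(data["s2"]) if data.get("s2") else None)


def load_config(path) -> RunConfig:
    """Load, validate and default-fill a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    for k in data:
        if k not in _TOP_KEYS:
            raise ConfigError(f"unknown key {k}")
    cfg = RunConfig(
        model=data.get("model", "cell"),
        preset=data.get("preset"),
        scale=data.get("scale", "small"),
        seed=int(data.get("seed", 0)),
        out=data.get("out"),
        ion=_build_section(IonicParams, data.get("ion"), "ion"),
        ca=_build_section(CaCyclingParams, data.get("ca"), "ca"),
        geometry=_build_section(GeometryConfig, data.get("geometry"),
                                "geometry"),
        solver=_build_section(SolverConfig, data.get("solver"), "solver"),
        protocol=_build_protocol(data.get("protocol")),
    )
    return cfg.validate()


def dump_config(cfg: RunConfig) -> dict:
    """Canonical plain-dict form (defaults resolved); YAML/JSON-safe, and
    ``config_from_dict(dump_config(cfg))`` round-trips."""
    out = {
        "model": cfg.model, "preset": cfg.preset, "scale": cfg.scale,
        "seed": cfg.seed, "out": cfg.out,
        "ion": asdict(cfg.ion),
        "ca": {k: (v.value if isinstance(v, NoiseSource) else v)
               for k, v in asdict(cfg.ca).items()},
        "geometry": asdict(cfg.geometry),
        "solver": asdict(cfg.solver),
    }
    if cfg.protocol is not None:
        out["protocol"] = {
            "stages": [list(s) for s in cfg.protocol.stages],
            "stim_sites": (list(cfg.protocol.stim_sites)
                           if isinstance(cfg.protocol.stim_sites, tuple)
                           else cfg.protocol.stim_sites),
            "stim_amp": cfg.protocol.stim_amp,
            "stim_dur_ms": cfg.protocol.stim_dur_ms,
            "s2": list(cfg.protocol.s2) if cfg.protocol.s2 else None,
        }
    return out
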