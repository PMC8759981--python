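"""Run configuration: strict YAML parsing, defaults, validation, provenance.

All tunable numbers live in the shipped ``data/defaults.yaml``; a user
config overrides any subset of them.  Parsing is strict — unknown keys are
fatal — so a misspelled tissue parameter cannot silently fall back to its
default.  A fully resolved configuration can be written back out as a
provenance file and re-run bit-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path

import yaml

from . import tissue_db
from .bioheat_solver import SkinModel
from .geometry import AnatomyParams, LabelGrid, build_anatomy
from .protocol_runner import Protocol
from .tissue_db import BloodModel

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


def _defaults_dict() -> dict:
    text = resources.files("cordcool.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


_FIDELITY_PRESETS = {
    # paper-fidelity: the source protocol's 0.02 s step on a half-millimetre
    # grid; desk: the default working resolution
    "desk": {"spacing": 1.0e-3, "dt": 0.5},
    "paper": {"spacing": 0.5e-3, "dt": 0.02},
}


@dataclass
class RunConfig:
    """Fully resolved, validated configuration of one simulation."""

    anatomy: dict
    tissues: dict
    blood: dict
    solver: dict
    calibration: dict
    protocol: dict
    output: dict
    provenance: dict = field(default_factory=dict)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        defaults = _defaults_dict()
        data = dict(data or {})
        # tissue overrides are keyed by tissue name with free fields; merge
        # them separately from the strict tree
        tissue_over = data.pop("tissues", {}) or {}
        prov = data.pop("provenance", {}) or {}
        merged = _merge({k: v for k, v in defaults.items() if k != "tissues"},
                        data)
        merged["tissues"] = tissue_over
        merged["provenance"] = prov
        cfg = cls(**merged)
        cfg._apply_fidelity()
        cfg.validate()
        return cfg

    @classmethod
    def default(cls) -> "RunConfig":
        return cls.from_dict({})

    def _apply_fidelity(self) -> None:
        preset = self.solver.get("fidelity", "desk")
        if preset not in _FIDELITY_PRESETS:
            raise ConfigError(f"unknown fidelity preset {preset!r}; "
                              f"choose from {sorted(_FIDELITY_PRESETS)}")
        for key, value in _FIDELITY_PRESETS[preset].items():
            if self.solver.get(key) is None:
                self.solver[key] = value

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        registry = self.build_registry()
        blood = self.build_blood()
        report = tissue_db.validate_registry(registry, blood)
        if report:
            raise ConfigError("invalid tissue registry:\n  "
                              + "\n  ".join(report))
        self.build_anatomy_params().validate()
        self.build_protocol().validate()
        if self.solver["spacing"] <= 0 or self.solver["dt"] <= 0:
            raise ConfigError("solver.spacing and solver.dt must be > 0")
        if self.calibration["skin_convection_coefficient"] < 0:
            raise ConfigError("skin_convection_coefficient must be >= 0")
        if self.calibration["csf_conductivity_factor"] <= 0:
            raise ConfigError("csf_conductivity_factor must be > 0")

    # -- builders ----------------------------------------------------------
    def build_registry(self):
        registry = tissue_db.default_registry()
        return tissue_db.apply_overrides(registry, self.tissues)

    def build_blood(self) -> BloodModel:
        base = tissue_db.default_blood()
        allowed = {"specific_heat", "density", "arterial_temperature"}
        bad = set(self.blood) - allowed
        if bad:
            raise ConfigError(f"unknown blood key(s) {sorted(bad)}")
        merged = {**asdict(base), **self.blood}
        return BloodModel(**merged)

    def build_anatomy_params(self) -> AnatomyParams:
        valid = {f.name for f in dc_fields(AnatomyParams)}
        bad = set(self.anatomy) - valid
        if bad:
            raise ConfigError(f"unknown anatomy key(s) {sorted(bad)}")
        kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in self.anatomy.items()}
        return AnatomyParams(**kwargs)

    def build_grid(self) -> LabelGrid:
        return build_anatomy(self.build_anatomy_params(),
                             spacing=self.solver["spacing"])

    def build_skin(self) -> SkinModel:
        cal = self.calibration
        return SkinModel(kind=cal["skin_model"],
                         coefficient=cal["skin_convection_coefficient"],
                         exponent=cal["skin_convection_exponent"],
                         ambient=cal["ambient_temperature"])

    def build_protocol(self) -> Protocol:
        p = self.protocol
        return Protocol(
            coolant_setpoint=p["coolant_setpoint"],
            cooling_duration=p["cooling_duration"],
            stoppage_duration=p["stoppage_duration"],
            dt=self.solver["dt"],
            report_interval=p["report_interval"],
            snapshot_times=tuple(p["snapshot_times"]),
        )

    def solver_options(self) -> dict:
        return dict(
            csf_conductivity_factor=self.calibration["csf_conductivity_factor"],
            extra_density_factor=self.calibration["extra_density_factor"],
        )

    # -- provenance --------------------------------------------------------
    def resolved_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("anatomy", "tissues", "blood", "solver", "calibration",
              "protocol", "output")}
        return yaml.safe_load(yaml.safe_dump(d))  # plain types only

    def registry_hash(self) -> str:
        reg = self.build_registry()
        canon = yaml.safe_dump(
            {name: asdict(t) for name, t in sorted(reg.items())},
            sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def write_provenance(self, path) -> Path:
        from . import __version__
        doc = self.resolved_dict()
        doc["provenance"] = {
            "package": "cordcool",
            "version": __version__,
            "registry_sha256": self.registry_hash(),
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the full defaults.  Unknown keys raise
    :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return RunConfig.default()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(data)
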