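"""Registry of tissue thermophysical properties and the blood model.

The simulator treats the axial cross-section as ten material classes
(spinal cord, cerebrospinal fluid, dura, epidural fat, yellow ligament,
vertebral bone, paraspinal muscle, splanchnic tissue, subcutaneous tissue,
and the catheter polymer).  Each class carries density ``rho`` (kg/m^3),
thermal conductivity ``k`` (W/(m K)), specific heat ``c`` (J/(kg K)), a
volumetric metabolic source ``q_m`` (W/m^3) and a blood mass-perfusion rate
``w_b`` (kg/(s m^3)).  The perfusion heat source used by the solver is

    q_p = w_b * c_b * (Ta - T)   [W/m^3]

with blood specific heat ``c_b`` and arterial temperature ``Ta`` shared by
all perfused tissues.  The catheter and the cerebrospinal fluid are inert
(``q_m = w_b = 0``).

Default values ship in ``data/tissues.yaml`` and any field can be
overridden per tissue through the run configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "TISSUE_NAMES",
    "TissueProperties",
    "BloodModel",
    "TissueLookupError",
    "default_registry",
    "default_blood",
    "get_tissue",
    "validate_registry",
    "load_registry_file",
]

#: Canonical tissue identifiers, in the order used for raster label codes.
TISSUE_NAMES = (
    "cerebrospinal_fluid",
    "spinal_cord",
    "dura",
    "epidural_space",
    "yellow_ligament",
    "spine",
    "muscle",
    "splanchnic_tissue",
    "subcutaneous_tissue",
    "catheter",
)

#: Tissues that must carry neither metabolism nor perfusion.
INERT_TISSUES = ("catheter", "cerebrospinal_fluid")


class TissueLookupError(KeyError):
    """Raised when a tissue identifier is not in the registry."""


@dataclass(frozen=True)
class TissueProperties:
    """Thermophysical constants for one tissue class (SI units)."""

    name: str
    density: float                  # kg/m^3
    thermal_conductivity: float     # W/(m K)
    specific_heat: float            # J/(kg K)
    metabolic_heat: float = 0.0     # W/m^3
    perfusion_mass_rate: float = 0.0  # kg/(s m^3)
    viscosity: float | None = None  # Pa s, informational only

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c in J/(m^3 K)."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class BloodModel:
    """Arterial blood shared by every perfused tissue.

    ``arterial_temperature`` doubles as the model's thermoregulatory
    baseline: with the registry's perfusion rates the deep tissues
    equilibrate at ``Ta + q_m/(w_b c_b)``, about a quarter degree above
    ``Ta``, essentially independent of skin losses.
    """

    specific_heat: float = 3617.0        # J/(kg K)
    density: float = 1050.0              # kg/m^3
    arterial_temperature: float = 36.15  # degC

    def perfusion_coefficient(self, tissue: TissueProperties) -> float:
        """w_b * c_b in W/(m^3 K) for the given tissue."""
        return tissue.perfusion_mass_rate * self.specific_heat


def _registry_from_mapping(data: Mapping) -> dict[str, TissueProperties]:
    registry = {}
    for name, fields in data.items():
        registry[name] = TissueProperties(name=name, **fields)
    return registry


def _load_default_data() -> dict:
    text = resources.files("cordcool.data").joinpath("tissues.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS_CACHE: dict | None = None


def _defaults() -> dict:
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        _DEFAULTS_CACHE = _load_default_data()
    return copy.deepcopy(_DEFAULTS_CACHE)


def default_registry() -> dict[str, TissueProperties]:
    """The shipped registry with every tissue of the cross-section."""
    return _registry_from_mapping(_defaults()["tissues"])


def default_blood() -> BloodModel:
    blood = _defaults()["blood"]
    return BloodModel(
        specific_heat=blood["specific_heat"],
        density=blood["density"],
        arterial_temperature=blood["arterial_temperature"],
    )


def load_registry_file(path) -> tuple[dict[str, TissueProperties], BloodModel]:
    """Load a full registry + blood model from a YAML file (same schema as
    the shipped ``tissues.yaml``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    registry = _registry_from_mapping(data["tissues"])
    blood = BloodModel(**data.get("blood", {}))
    return registry, blood


def get_tissue(name: str, registry: Mapping[str, TissueProperties] | None = None
               ) -> TissueProperties:
    """Look up one tissue by identifier.

    Raises
    ------
    TissueLookupError
        If ``name`` is not registered; the message lists valid identifiers.
    """
    reg = default_registry() if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        valid = ", ".join(sorted(reg))
        raise TissueLookupError(
            f"unknown tissue {name!r}; valid identifiers: {valid}"
        ) from None


def apply_overrides(registry: dict[str, TissueProperties],
                    overrides: Mapping[str, Mapping[str, float]]
                    ) -> dict[str, TissueProperties]:
    """Return a copy of ``registry`` with per-tissue field overrides applied."""
    out = dict(registry)
    for name, fields in overrides.items():
        base = get_tissue(name, out)
        bad = set(fields) - {
            "density", "thermal_conductivity", "specific_heat",
            "metabolic_heat", "perfusion_mass_rate", "viscosity",
        }
        if bad:
            raise ValueError(f"unknown tissue property field(s) {sorted(bad)} "
                             f"for tissue {name!r}")
        out[name] = replace(base, **fields)
    return out


def validate_registry(registry: Mapping[str, TissueProperties],
                      blood: BloodModel) -> list[str]:
    """Check every registry invariant; return a list of violation messages.

    An empty list means the registry is physically admissible.  Checks are
    report-based (no exception) so a config loader can surface all problems
    at once.
    """
    report: list[str] = []
    for name in TISSUE_NAMES:
        if name not in registry:
            report.append(f"missing tissue {name!r}")
    for name, t in registry.items():
        if t.density <= 0:
            report.append(f"{name}: density must be > 0 (got {t.density})")
        if t.thermal_conductivity <= 0:
            report.append(f"{name}: thermal_conductivity must be > 0 "
                          f"(got {t.thermal_conductivity})")
        if t.specific_heat <= 0:
            report.append(f"{name}: specific_heat must be > 0 "
                          f"(got {t.specific_heat})")
        if t.metabolic_heat < 0:
            report.append(f"{name}: metabolic_heat must be >= 0 "
                          f"(got {t.metabolic_heat})")
        if t.perfusion_mass_rate < 0:
            report.append(f"{name}: perfusion_mass_rate must be >= 0 "
                          f"(got {t.perfusion_mass_rate})")
    for name in INERT_TISSUES:
        t = registry.get(name)
        if t is None:
            continue
        if t.metabolic_heat != 0 or t.perfusion_mass_rate != 0:
            report.append(
                f"{name}: must be inert (metabolic_heat = "
                f"{t.metabolic_heat}, perfusion_mass_rate = "
                f"{t.perfusion_mass_rate})")
    if blood.specific_heat <= 0:
        report.append(f"blood: specific_heat must be > 0 "
                      f"(got {blood.specific_heat})")
    if blood.density <= 0:
        report.append(f"blood: density must be > 0 (got {blood.density})")
    if not 30.0 <= blood.arterial_temperature <= 42.0:
        report.append(f"blood: arterial_temperature must be in [30, 42] degC "
                      f"(got {blood.arterial_temperature})")
    return report
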