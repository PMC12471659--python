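"""Parameter containers and packaged presets.

All quantities use the canonical unit system of the model: forces in N,
stresses/strengths in MPa, elastic moduli in GPa, lengths in mm, time in s,
frequency in Hz, angles in degrees at every public interface.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Any

__all__ = [
    "LogBase",
    "Band",
    "CeramicMaterial",
    "FoundationStack",
    "VeneerGeometry",
    "LoadCase",
    "ModelConstants",
    "FatigueProtocol",
    "load_presets",
    "preset_material",
    "preset_foundation",
    "preset_load",
    "preset_geometry",
    "preset_constants",
    "preset_protocol",
]


class LogBase(str, Enum):
    """Logarithm convention used in the critical-load and foundation-exponent
    formulas. The empirical calibration of the dimensionless constants is
    base-10; natural log is retained as an option for sensitivity checks."""

    base10 = "base10"
    natural = "natural"


class Band(str, Enum):
    """Prediction band: mean material parameters, or the conservative lower
    band (reduced strength and/or lower SCG exponent)."""

    mean = "mean"
    lower = "lower"


def _require_positive(obj: Any, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class CeramicMaterial:
    """One veneer ceramic: elastic modulus, fast-fracture flexural strength
    scatter (mean ± SD, MPa) and the slow-crack-growth velocity exponent N
    with its lower confidence bound.

    Larger N means slower moisture-assisted strength degradation under
    cyclic load; zirconia (N≈25) degrades more slowly than lithium
    disilicate (N≈20) but starts from lower strength relative to its
    stiffness.
    """

    name: str
    elastic_modulus_E: float  # GPa
    strength_mean: float  # MPa, intrinsic fast-fracture flexural strength
    strength_sd: float  # MPa
    scg_exponent_mean: float
    scg_exponent_lower: float

    def __post_init__(self) -> None:
        _require_positive(
            self,
            "elastic_modulus_E",
            "strength_mean",
            "strength_sd",
            "scg_exponent_mean",
            "scg_exponent_lower",
        )
        if self.scg_exponent_lower > self.scg_exponent_mean:
            raise ValueError(
                "scg_exponent_lower must not exceed scg_exponent_mean "
                f"({self.scg_exponent_lower} > {self.scg_exponent_mean})"
            )
        if self.strength_sd >= self.strength_mean:
            raise ValueError(
                "strength_sd must be smaller than strength_mean "
                f"({self.strength_sd} >= {self.strength_mean})"
            )

    def with_overrides(self, **kwargs: Any) -> "CeramicMaterial":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FoundationStack:
    """Adhesive cement layer on a dentin-analog substrate.

    Note the subscript convention: ``Es`` is the *cement* modulus and ``Ec``
    the *substrate* modulus — counter-intuitive but fixed by the effective
    modulus formula E* = E_c (E_s/E_c)^L.
    """

    cement_modulus_Es: float  # GPa
    substrate_modulus_Ec: float  # GPa
    cement_thickness_h: float  # mm

    def __post_init__(self) -> None:
        _require_positive(
            self, "cement_modulus_Es", "substrate_modulus_Ec", "cement_thickness_h"
        )
        if self.cement_modulus_Es > self.substrate_modulus_Ec:
            warnings.warn(
                "cement modulus exceeds substrate modulus; the foundation model "
                "is calibrated for a compliant cement on a stiffer substrate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class VeneerGeometry:
    """Veneer thickness and cusp incline at the loading point (degrees)."""

    thickness_d: float  # mm
    cusp_incline_theta: float = 0.0  # degrees

    def __post_init__(self) -> None:
        _require_positive(self, "thickness_d")
        if not 0.0 <= self.cusp_incline_theta < 90.0:
            raise ValueError(
                f"cusp_incline_theta must lie in [0, 90) degrees, got "
                f"{self.cusp_incline_theta!r}"
            )


@dataclass(frozen=True)
class LoadCase:
    """Applied occlusal load, chewing frequency and the reference time of the
    short-term strength test entering the SCG power law.

    Predicted lifetimes scale linearly in ``reference_time_t0``, so
    order-of-magnitude conclusions are insensitive to it over [0.1, 10] s.
    """

    applied_load_F: float  # N
    frequency_f: float  # Hz
    reference_time_t0: float = 1.0  # s

    def __post_init__(self) -> None:
        _require_positive(self, "applied_load_F", "frequency_f", "reference_time_t0")


@dataclass(frozen=True)
class ModelConstants:
    """Dimensionless calibration constants of the plate-on-foundation model.

    ``B`` and ``C`` scale the critical-load formula; ``alpha``, ``beta``,
    ``gamma`` parameterise the empirical foundation-interaction exponent
    L = exp(−[α + β·log(h/d)]^γ).
    """

    B: float = 1.35
    C: float = 1.0
    alpha: float = 1.18
    beta: float = 0.33
    gamma: float = 3.13
    log_base: LogBase = LogBase.base10

    def __post_init__(self) -> None:
        _require_positive(self, "B", "C", "alpha", "gamma")
        # accept plain strings for convenience when built from config files
        if not isinstance(self.log_base, LogBase):
            object.__setattr__(self, "log_base", LogBase(self.log_base))


@dataclass(frozen=True)
class FatigueProtocol:
    """Chewing-simulation protocol: cyclic load with thermocycling, stopped
    (right-censored) at ``total_cycles``."""

    applied_load: float = 49.0  # N
    frequency: float = 1.6  # Hz
    total_cycles: int = 1_200_000
    years_equivalent: float = 5.0
    thermocycle_low_C: float = 5.0
    thermocycle_high_C: float = 55.0
    dwell_time_s: float = 120.0

    def __post_init__(self) -> None:
        _require_positive(self, "total_cycles", "years_equivalent")

    @property
    def cycles_per_year(self) -> float:
        return self.total_cycles / self.years_equivalent


# ---------------------------------------------------------------------------
# Packaged presets


def load_presets() -> dict[str, Any]:
    """Raw preset dictionary from the packaged configuration file."""
    text = resources.files("ovfatigue.data").joinpath("presets.toml").read_text()
    return tomllib.loads(text)


def preset_material(name: str, presets: dict[str, Any] | None = None) -> CeramicMaterial:
    """Packaged ceramic by key (``lithium_disilicate`` or ``zirconia_5y``).

    The gradient multilayered zirconia veneer sits at the boundary of the
    5Y-PSZ layer, so it carries 5Y-PSZ strength and modulus — a conservative
    worst-case assignment for the 4Y/5Y transition zone, whose gradient
    strength cannot be measured directly.
    """
    presets = presets or load_presets()
    try:
        entry = presets["materials"][name]
    except KeyError:
        known = ", ".join(sorted(presets["materials"]))
        raise KeyError(f"unknown material preset {name!r}; packaged: {known}") from None
    return CeramicMaterial(**entry)


def preset_foundation(presets: dict[str, Any] | None = None) -> FoundationStack:
    presets = presets or load_presets()
    return FoundationStack(**presets["foundation"])


def preset_load(presets: dict[str, Any] | None = None) -> LoadCase:
    presets = presets or load_presets()
    return LoadCase(**presets["load"])


def preset_geometry(thickness_d: float, presets: dict[str, Any] | None = None) -> VeneerGeometry:
    presets = presets or load_presets()
    return VeneerGeometry(thickness_d=thickness_d, **presets["geometry"])


def preset_constants(presets: dict[str, Any] | None = None) -> ModelConstants:
    presets = presets or load_presets()
    return ModelConstants(**presets["constants"])


def preset_protocol(presets: dict[str, Any] | None = None) -> FatigueProtocol:
    presets = presets or load_presets()
    return FatigueProtocol(**presets["protocol"])
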