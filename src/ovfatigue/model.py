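"""Closed-form radial-fracture fatigue model for bonded ceramic veneers.

A stiff ceramic plate of thickness d bonded to a compliant cement/substrate
foundation fails by flexural radial cracking from its cementation (intaglio)
surface once the normal load component reaches the critical load

    F_nR = B σ d² / log(C E / E*),

where σ is the ceramic's flexural strength, E its modulus and E* the
effective foundation modulus, E* = E_c (E_s/E_c)^L with the empirical
interaction exponent L = exp(−[α + β log(h/d)]^γ) set by the cement
thickness h. Under cyclic loading in a moist environment, slow crack growth
degrades strength as σ_F/σ_0 = (t_0/t_F)^{1/N}, which converts the
single-cycle critical load into a lifetime: the veneer survives n = f·t_F
cycles where t_F = t_0 (F_nR/F_n)^N.

With σ in MPa and d in mm, σ·d² carries units of N, so all loads are in
newtons without conversion factors. Lifetimes are computed and stored in
log₁₀ space: mean-band values exceed 10¹⁶ cycles for thicker veneers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .params import (
    Band,
    CeramicMaterial,
    FoundationStack,
    LoadCase,
    LogBase,
    ModelConstants,
    VeneerGeometry,
)

__all__ = [
    "DomainError",
    "FatiguePrediction",
    "normal_load",
    "foundation_interaction_exponent",
    "effective_modulus",
    "critical_radial_load",
    "cycles_to_failure",
    "critical_load_at_cycles",
    "band_parameters",
    "predict_lifetime",
    "crossover_thickness",
    "failure_probability_before",
    "required_strength",
]


class DomainError(ValueError):
    """Raised when inputs fall outside the model's empirical validity domain."""


def _log(x: float, base: LogBase) -> float:
    return math.log10(x) if base is LogBase.base10 else math.log(x)


@dataclass(frozen=True)
class FatiguePrediction:
    """Full result of one lifetime prediction; every field equals the output
    of the corresponding standalone operation."""

    material: str
    band: Band
    thickness_d: float  # mm
    normal_load_Fn: float  # N
    interaction_exponent_L: float
    effective_modulus_Estar: float  # GPa
    critical_load_FnR: float  # N
    log10_cycles_to_failure: float
    time_to_fracture_tF: float  # s (inf if cycles overflow float range)
    degraded_strength_sigmaF: float  # MPa, strength at which F_nR = F_n
    scg_exponent_N: float
    strength_sigma0: float  # MPa, band strength used

    @property
    def fails_at_first_loading(self) -> bool:
        """True when the applied normal load already exceeds the critical
        load, i.e. predicted survival is below one loading period."""
        return self.critical_load_FnR <= self.normal_load_Fn


def normal_load(load: LoadCase, geometry: VeneerGeometry) -> float:
    """Normal component F_n = F cos θ of the occlusal load on the cusp
    incline; only this component drives flexural radial fracture."""
    return load.applied_load_F * math.cos(math.radians(geometry.cusp_incline_theta))


def foundation_interaction_exponent(
    foundation: FoundationStack,
    geometry: VeneerGeometry,
    constants: ModelConstants = ModelConstants(),
) -> float:
    """Empirical exponent L = exp(−[α + β log(h/d)]^γ) interpolating the
    foundation between substrate (L→0) and cement (L→1) behaviour.

    The bracket must be positive: γ is non-integer, so a non-positive base
    has no real power. The calibration domain corresponds to thin cement
    layers (h ≪ d).
    """
    ratio = foundation.cement_thickness_h / geometry.thickness_d
    bracket = constants.alpha + constants.beta * _log(ratio, constants.log_base)
    if bracket <= 0.0:
        raise DomainError(
            f"foundation interaction exponent undefined: alpha + beta*log(h/d) = "
            f"{bracket:.4g} <= 0 for h/d = {ratio:.4g} (outside calibration domain)"
        )
    return math.exp(-(bracket**constants.gamma))


def effective_modulus(foundation: FoundationStack, L: float) -> float:
    """Effective foundation modulus E* = E_c (E_s/E_c)^L, a geometric
    interpolation between substrate (L=0) and cement (L=1) moduli."""
    if not 0.0 <= L <= 1.0:
        raise DomainError(f"interaction exponent L must lie in [0, 1], got {L!r}")
    Es, Ec = foundation.cement_modulus_Es, foundation.substrate_modulus_Ec
    return Ec * (Es / Ec) ** L


def critical_radial_load(
    material: CeramicMaterial,
    geometry: VeneerGeometry,
    Estar: float,
    constants: ModelConstants = ModelConstants(),
    strength_override: float | None = None,
) -> float:
    """Critical load F_nR = B σ d² / log(C E/E*) initiating a radial crack
    at the intaglio surface.

    ``strength_override`` substitutes a specimen- or band-specific strength
    for the material's mean (MPa). Requires C·E > E*: the plate must be
    stiffer than its foundation for the flexure formula to hold.
    """
    sigma = material.strength_mean if strength_override is None else strength_override
    if sigma <= 0:
        raise DomainError(f"strength must be positive, got {sigma!r}")
    stiffness_ratio = constants.C * material.elastic_modulus_E / Estar
    if stiffness_ratio <= 1.0:
        raise DomainError(
            f"C*E/E* = {stiffness_ratio:.4g} <= 1: plate not stiffer than "
            "foundation, outside model validity"
        )
    d = geometry.thickness_d
    return constants.B * sigma * d * d / _log(stiffness_ratio, constants.log_base)


def cycles_to_failure(
    Fn_applied: float,
    FnR: float,
    scg_exponent_N: float,
    load: LoadCase,
) -> float:
    """log₁₀ of the number of cycles until slow crack growth degrades the
    critical load down to the applied load.

    Inverts the SCG power law at F(t_F) = F_n: t_F = t₀ (F_nR/F_n)^N and
    n = f·t_F. Values below log₁₀(f·t₀) signal failure at first loading and
    are returned as-is (no clamping).
    """
    if Fn_applied <= 0 or FnR <= 0:
        raise DomainError("loads must be positive")
    return (
        math.log10(load.frequency_f * load.reference_time_t0)
        + scg_exponent_N * math.log10(FnR / Fn_applied)
    )


def critical_load_at_cycles(
    FnR0: float,
    n_cycles: float,
    scg_exponent_N: float,
    load: LoadCase,
) -> float:
    """Fatigue-degraded critical load F(n) = F_nR0 (f·t₀/n)^{1/N} after n
    cycles; the strength-degradation design curve."""
    if n_cycles <= 0:
        raise DomainError(f"n_cycles must be positive, got {n_cycles!r}")
    ratio = load.frequency_f * load.reference_time_t0 / n_cycles
    return FnR0 * ratio ** (1.0 / scg_exponent_N)


def band_parameters(
    material: CeramicMaterial,
    band: Band | str,
    lower_strength_policy: str = "mean_minus_sd",
) -> tuple[float, float]:
    """(strength σ₀, SCG exponent N) for a prediction band.

    The mean band uses (σ̄, N_mean). The lower band uses N_lower combined
    with σ̄ − 1·SD by default (``mean_minus_sd``) or with σ̄ alone
    (``n_only``) — the latter varies N only, as design-curve captions
    sometimes do.
    """
    band = Band(band)
    if band is Band.mean:
        return material.strength_mean, material.scg_exponent_mean
    if lower_strength_policy == "mean_minus_sd":
        sigma = material.strength_mean - material.strength_sd
    elif lower_strength_policy == "n_only":
        sigma = material.strength_mean
    else:
        raise ValueError(
            f"unknown lower_strength_policy {lower_strength_policy!r}; "
            "expected 'mean_minus_sd' or 'n_only'"
        )
    return sigma, material.scg_exponent_lower


def predict_lifetime(
    material: CeramicMaterial,
    geometry: VeneerGeometry,
    foundation: FoundationStack,
    load: LoadCase,
    constants: ModelConstants = ModelConstants(),
    band: Band | str = Band.mean,
    lower_strength_policy: str = "mean_minus_sd",
) -> FatiguePrediction:
    """Chain the full model: load decomposition → foundation exponent →
    effective modulus → critical load → SCG lifetime."""
    band = Band(band)
    sigma0, N = band_parameters(material, band, lower_strength_policy)
    try:
        Fn = normal_load(load, geometry)
        L = foundation_interaction_exponent(foundation, geometry, constants)
        Estar = effective_modulus(foundation, L)
        FnR = critical_radial_load(material, geometry, Estar, constants, sigma0)
        log10_n = cycles_to_failure(Fn, FnR, N, load)
    except DomainError as err:
        raise DomainError(f"{material.name} d={geometry.thickness_d} mm: {err}") from err
    # t_F = n/f computed in log space; beyond float range report inf
    log10_tF = log10_n - math.log10(load.frequency_f)
    tF = 10.0**log10_tF if log10_tF < 308 else math.inf
    stiffness_log = _log(
        constants.C * material.elastic_modulus_E / Estar, constants.log_base
    )
    sigmaF = Fn * stiffness_log / (constants.B * geometry.thickness_d**2)
    return FatiguePrediction(
        material=material.name,
        band=band,
        thickness_d=geometry.thickness_d,
        normal_load_Fn=Fn,
        interaction_exponent_L=L,
        effective_modulus_Estar=Estar,
        critical_load_FnR=FnR,
        log10_cycles_to_failure=log10_n,
        time_to_fracture_tF=tF,
        degraded_strength_sigmaF=sigmaF,
        scg_exponent_N=N,
        strength_sigma0=sigma0,
    )


def crossover_thickness(
    matA: CeramicMaterial,
    matB: CeramicMaterial,
    foundation: FoundationStack,
    load: LoadCase,
    constants: ModelConstants = ModelConstants(),
    band: Band | str = Band.mean,
    d_range: tuple[float, float] = (0.3, 1.5),
    lower_strength_policy: str = "mean_minus_sd",
    cusp_incline_theta: float = 0.0,
    xtol: float = 1e-6,
) -> float:
    """Thickness at which the two materials' predicted lifetimes cross.

    Root of Δ(d) = log₁₀ n_A(d) − log₁₀ n_B(d) located by Brent's method to
    well below 10⁻³ mm; requires a sign change over ``d_range``. The cusp
    incline shifts the crossover slightly because the two materials carry
    different SCG exponents.
    """

    def delta(d: float) -> float:
        geo = VeneerGeometry(thickness_d=d, cusp_incline_theta=cusp_incline_theta)
        kwargs = dict(
            foundation=foundation,
            load=load,
            constants=constants,
            band=band,
            lower_strength_policy=lower_strength_policy,
        )
        a = predict_lifetime(matA, geo, **kwargs).log10_cycles_to_failure
        b = predict_lifetime(matB, geo, **kwargs).log10_cycles_to_failure
        return a - b

    lo, hi = d_range
    f_lo, f_hi = delta(lo), delta(hi)
    if f_lo == 0.0 and f_hi == 0.0:
        raise DomainError(
            "lifetime difference is identically zero over the range "
            "(identical materials?); no isolated crossover"
        )
    if f_lo * f_hi > 0:
        raise DomainError(
            "no lifetime crossover in "
            f"[{lo}, {hi}] mm: log10-lifetime difference is {f_lo:.3g} at "
            f"{lo} mm and {f_hi:.3g} at {hi} mm (same sign)"
        )
    return float(brentq(delta, lo, hi, xtol=xtol))


def required_strength(
    n_c: float,
    material: CeramicMaterial,
    geometry: VeneerGeometry,
    foundation: FoundationStack,
    load: LoadCase,
    constants: ModelConstants = ModelConstants(),
    scg_exponent_N: float | None = None,
) -> float:
    """Threshold intrinsic strength σ_req (MPa) below which a specimen fails
    before n_c cycles.

    Algebraic inversion of the critical-load and SCG relations:
    σ_req = F_n (n_c/(f t₀))^{1/N} · log(C E/E*) / (B d²).
    """
    if n_c <= 0:
        raise DomainError(f"n_c must be positive, got {n_c!r}")
    N = material.scg_exponent_mean if scg_exponent_N is None else scg_exponent_N
    Fn = normal_load(load, geometry)
    L = foundation_interaction_exponent(foundation, geometry, constants)
    Estar = effective_modulus(foundation, L)
    stiffness_ratio = constants.C * material.elastic_modulus_E / Estar
    if stiffness_ratio <= 1.0:
        raise DomainError(
            f"C*E/E* = {stiffness_ratio:.4g} <= 1: outside model validity"
        )
    time_factor = (n_c / (load.frequency_f * load.reference_time_t0)) ** (1.0 / N)
    return (
        Fn
        * time_factor
        * _log(stiffness_ratio, constants.log_base)
        / (constants.B * geometry.thickness_d**2)
    )


def failure_probability_before(
    n_c: float,
    material: CeramicMaterial,
    geometry: VeneerGeometry,
    foundation: FoundationStack,
    load: LoadCase,
    constants: ModelConstants = ModelConstants(),
    scg_exponent_N: float | None = None,
) -> float:
    """Closed-form probability that a specimen with normally distributed
    intrinsic strength fails (radial crack) before n_c cycles.

    The lifetime is a strictly increasing function of the drawn strength, so
    P(fail before n_c) = Φ((σ_req − σ̄)/SD) with σ_req from
    :func:`required_strength`.
    """
    sigma_req = required_strength(
        n_c, material, geometry, foundation, load, constants, scg_exponent_N
    )
    z = (sigma_req - material.strength_mean) / material.strength_sd
    return float(norm.cdf(z))
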