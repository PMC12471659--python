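"""Monte-Carlo chewing-simulation cohorts and censored strength recovery.

The generator is the stochastic twin of the closed-form model: each
specimen draws an intrinsic flexural strength from the material's normal
scatter (truncated at zero by rejection — negligible mass for the packaged
parameters), its lifetime follows deterministically from the
plate-on-foundation + slow-crack-growth equations, and the protocol
right-censors every lifetime at the simulation length. Because lifetime is
strictly increasing in strength, the empirical failure fraction converges
on the closed-form normal-tail probability — the headline consistency
property between this module and the model.

The inverse direction is also exact: a failed specimen's cycle count maps
back to the strength that produced it, so a censored-normal maximum
likelihood fit on inverted strengths recovers the generating (mean, SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from . import model
from .experiment import CSV_COLUMNS, OUTCOME_FAILED, OUTCOME_INTACT
from .params import (
    CeramicMaterial,
    FoundationStack,
    LoadCase,
    ModelConstants,
    VeneerGeometry,
)

__all__ = [
    "CohortSpec",
    "ImpliedStrength",
    "StrengthFit",
    "simulate_cohort",
    "invert_strength",
    "fit_strength_distribution",
]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate (and invert) one simulated cohort.

    ``scg_exponent`` is the cohort's slow-crack-growth exponent N — a
    material property, fixed across specimens. Setting ``scg_exponent_sd``
    > 0 instead draws N once per cohort (not per specimen), for band
    studies of the N confidence interval.
    """

    material: CeramicMaterial
    geometry: VeneerGeometry
    foundation: FoundationStack
    load: LoadCase
    constants: ModelConstants = field(default_factory=ModelConstants)
    scg_exponent: float | None = None  # default: material's mean N
    n_specimens: int = 12
    censor_cycles: int = 1_200_000
    seed: int = 0
    scg_exponent_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.censor_cycles < 1:
            raise ValueError("censor_cycles must be >= 1")

    @property
    def N(self) -> float:
        return (
            self.material.scg_exponent_mean
            if self.scg_exponent is None
            else self.scg_exponent
        )

    def group_id(self) -> str:
        return f"{self.material.name}-{self.geometry.thickness_d:g}"


class ImpliedStrength(NamedTuple):
    """Strength implied by one specimen record: a point value for a failure,
    a lower bound (the survival threshold at the censoring cycle count) for
    an intact specimen."""

    value: float  # MPa
    is_lower_bound: bool


@dataclass(frozen=True)
class StrengthFit:
    """Censored-normal MLE of the intrinsic strength distribution."""

    strength_mean_hat: float  # MPa
    strength_sd_hat: float  # MPa
    log_likelihood: float
    n_failed: int
    n_censored: int


def _lifetime_constants(spec: CohortSpec) -> tuple[float, float]:
    """(normal load F_n, log-stiffness term log(CE/E*)) shared by every
    specimen of a cohort."""
    Fn = model.normal_load(spec.load, spec.geometry)
    L = model.foundation_interaction_exponent(
        spec.foundation, spec.geometry, spec.constants
    )
    Estar = model.effective_modulus(spec.foundation, L)
    ratio = spec.constants.C * spec.material.elastic_modulus_E / Estar
    if ratio <= 1.0:
        raise model.DomainError(
            f"C*E/E* = {ratio:.4g} <= 1: outside model validity"
        )
    logfun = math.log10 if spec.constants.log_base.value == "base10" else math.log
    return Fn, logfun(ratio)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort as a specimen table in the canonical CSV schema.

    Failed specimens are recorded at ⌈n⌉ cycles (crack detected at the end
    of the cycle in which the lifetime elapses); survivors are censored at
    ``censor_cycles``. Identical seeds give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.N
    if spec.scg_exponent_sd > 0.0:
        N = float(rng.normal(N, spec.scg_exponent_sd))
    Fn, log_stiffness = _lifetime_constants(spec)

    mean, sd = spec.material.strength_mean, spec.material.strength_sd
    strengths = rng.normal(mean, sd, spec.n_specimens)
    bad = strengths <= 0.0
    while bad.any():  # rejection at sigma <= 0
        strengths[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = strengths <= 0.0

    d = spec.geometry.thickness_d
    FnR = spec.constants.B * strengths * d * d / log_stiffness
    log10_n = (
        math.log10(spec.load.frequency_f * spec.load.reference_time_t0)
        + N * np.log10(FnR / Fn)
    )
    fails = log10_n < math.log10(spec.censor_cycles)
    cycles = np.full(spec.n_specimens, spec.censor_cycles, dtype="int64")
    cycles[fails] = np.maximum(1, np.ceil(10.0 ** log10_n[fails])).astype("int64")

    gid = spec.group_id()
    return pd.DataFrame(
        {
            "specimen_id": [f"{gid}-{i + 1:03d}" for i in range(spec.n_specimens)],
            "group_id": gid,
            "material": spec.material.name,
            "thickness_mm": d,
            "outcome": np.where(fails, OUTCOME_FAILED, OUTCOME_INTACT),
            "cycles": cycles,
        },
        columns=CSV_COLUMNS,
    )


def invert_strength(record, spec: CohortSpec) -> ImpliedStrength:
    """Intrinsic strength implied by one specimen record.

    For a failure, the algebraic inversion σ₀ = F_n (n/(f t₀))^{1/N}
    log(CE/E*)/(B d²) recovers the drawn strength exactly (up to cycle
    rounding). For an intact specimen the same expression evaluated at the
    censoring count is only a lower bound on the specimen's strength.
    """
    cycles = int(record["cycles"]) if not isinstance(record, tuple) else int(record[5])
    outcome = record["outcome"]
    sigma = model.required_strength(
        cycles,
        spec.material,
        spec.geometry,
        spec.foundation,
        spec.load,
        spec.constants,
        scg_exponent_N=spec.N,
    )
    return ImpliedStrength(value=sigma, is_lower_bound=(outcome == OUTCOME_INTACT))


def _censored_normal_nll(params, failed_sigma, n_censored, censor_sigma):
    mu, log_s = params
    s = math.exp(log_s)
    nll = -np.sum(norm.logpdf(failed_sigma, loc=mu, scale=s))
    if n_censored:
        nll -= n_censored * norm.logsf(censor_sigma, loc=mu, scale=s)
    return nll


def fit_strength_distribution(table: pd.DataFrame, spec: CohortSpec) -> StrengthFit:
    """Censored-normal maximum likelihood estimate of (strength mean, SD).

    Failures contribute density terms at their inverted strengths; censored
    specimens contribute the upper-tail survival probability above the
    censoring threshold strength. Optimised over (μ, log s) by L-BFGS-B
    from a fixed three-point start grid (deterministic; guards against
    local optima under heavy censoring).
    """
    failed = table[table["outcome"] == OUTCOME_FAILED]
    n_failed, n_censored = len(failed), int((table["outcome"] == OUTCOME_INTACT).sum())
    if n_failed < 3:
        raise ValueError(
            f"need at least 3 failed specimens to fit a strength distribution, "
            f"got {n_failed}"
        )
    # vectorised inversion: sigma_i = K * n_i^(1/N) with a shared prefactor
    Fn, log_stiffness = _lifetime_constants(spec)
    N = spec.N
    prefactor = (
        Fn
        * (spec.load.frequency_f * spec.load.reference_time_t0) ** (-1.0 / N)
        * log_stiffness
        / (spec.constants.B * spec.geometry.thickness_d**2)
    )
    failed_sigma = prefactor * failed["cycles"].to_numpy(dtype=float) ** (1.0 / N)
    if np.std(failed_sigma) < 1e-9 * max(1.0, abs(np.mean(failed_sigma))):
        raise ValueError(
            "degenerate data: all failure strengths identical; the scale "
            "parameter is unidentifiable"
        )
    censor_sigma = model.required_strength(
        spec.censor_cycles,
        spec.material,
        spec.geometry,
        spec.foundation,
        spec.load,
        spec.constants,
        scg_exponent_N=spec.N,
    )

    m0, s0 = float(np.mean(failed_sigma)), float(np.std(failed_sigma, ddof=1))
    starts = [
        (m0, s0),
        (m0 + s0, 2.0 * s0),  # censoring pulls the naive moments down
        (censor_sigma, max(s0, 0.25 * censor_sigma)),
    ]
    best = None
    for mu0, sd0 in starts:
        res = minimize(
            _censored_normal_nll,
            x0=np.array([mu0, math.log(max(sd0, 1e-3))]),
            args=(failed_sigma, n_censored, censor_sigma),
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, log_s_hat = best.x
    return StrengthFit(
        strength_mean_hat=float(mu_hat),
        strength_sd_hat=float(math.exp(log_s_hat)),
        log_likelihood=float(-best.fun),
        n_failed=n_failed,
        n_censored=n_censored,
    )
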