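# Methods

## Physical model and assumptions

A bonded occlusal veneer is idealized as a homogeneous, isotropic elastic
plate (modulus E, thickness d) resting on a compliant foundation composed
of a thin resin-cement layer (modulus E_s, thickness h) over a dentin-like
substrate (modulus E_c). Radial fracture initiates at the intaglio surface
when the normal load component F_n = F cos θ reaches

    F_nR = B σ d² / log(C E / E*),        E* = E_c (E_s/E_c)^L,
    L = exp(−[α + β log(h/d)]^γ).

The model assumes the adhesive interfaces stay intact up to ceramic
fracture, a single effective contact load, and plate flexure as the only
stress field — no contact (partial-cone) cracking, no thermal stresses, no
finite-element resolution of the stress distribution. Fatigue enters solely
through moisture-assisted slow crack growth: strength decays as
σ_F/σ_0 = (t_0/t_F)^{1/N}, so the cycles-to-failure follow
n = f t_0 (F_nR/F_n)^N. Lifetimes are computed and stored in log₁₀ space;
`time_to_fracture_tF` saturates to `inf` beyond the float range, and a
predicted log₁₀ n below log₁₀(f t_0) is returned unclamped and flagged as
failure at first loading.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| F, θ, f | 49, 15, 1.6 | N, °, Hz | chewing-simulation load case |
| E (zirconia / LD) | 210 / 95 | GPa | ceramic moduli |
| σ (zirconia / LD) | 411 ± 107 / 462 ± 34 | MPa | flexural strength mean ± SD (n = 10 lab specimens each) |
| N mean / lower (zirconia) | 25 / 23 | – | SCG velocity exponent band |
| N mean / lower (LD) | 20 / 17 | – | idem |
| E_s, E_c, h | 7.9, 18.6, 0.04 | GPa, GPa, mm | cement, substrate, cement thickness |
| B, C, α, β, γ | 1.35, 1, 1.18, 0.33, 3.13 | – | empirical plate-on-foundation constants |
| t_0 | 1 | s | reference time of the short-term strength test |
| censor | 1.2 × 10⁶ | cycles | protocol length (≙ 5 years at 240,000 cycles/yr) |

The packaged gradient multilayered zirconia is assigned 5Y-PSZ properties:
the veneers sit at the boundary of the 5Y layer and fracture initiates in
the weaker constituent, so this is the conservative choice for a transition
zone whose gradient strength cannot be measured directly.

Subscript warning: in the effective-modulus formula, E_s is the *cement*
and E_c the *substrate* modulus.

## Numerical and design choices

- **Log base.** The critical-load and foundation-exponent formulas are
  evaluated with base-10 logarithms by default (`ModelConstants.log_base`);
  base-10 is the convention under which the packaged constants reproduce
  the order-of-magnitude lifetime claims (10¹⁰ cycles for 0.5 mm lithium
  disilicate; < 10⁴ for 0.4 mm zirconia lower band). Natural log is
  retained as an option for sensitivity analysis.
- **Reference time t_0.** Not separately identifiable from the packaged
  data; fixed at 1 s. Lifetimes scale linearly in t_0, so conclusions are
  insensitive to t_0 ∈ [0.1, 10] s (±1 decade on a scale spanning > 15).
- **Lower band.** By default the lower band combines σ − 1 SD with
  N_lower. An N-only variant (`lower_strength_policy="n_only"`) varies N
  alone, as design-chart captions sometimes describe; only the joint
  perturbation places the lower bound inside the observed Z-0.5 failure
  range, which is why it is the default. Both are documented API options.
- **Domain guards.** The foundation-exponent bracket α + β log(h/d) must be
  positive before raising to the non-integer power γ; the plate must be
  stiffer than its foundation (C E > E*). Violations raise `DomainError`
  naming the offending quantity; the curve builder skips such rows with a
  warning instead of aborting.
- **Units.** Degrees at all interfaces (radians internally);
  N/MPa/GPa/mm/s/Hz as the canonical system. σ[MPa]·d[mm]² is a force in N,
  so no conversion constants appear; the test suite checks closure against
  a Pa/m re-derivation to 10 significant digits.
- **Crossover.** The zirconia/lithium-disilicate crossover thickness is the
  Brent root of the log₁₀-lifetime difference (well below the 10⁻³ mm
  tolerance), cross-checked against a 0.01 mm grid scan. The cusp incline
  shifts it slightly (0.78 mm at 15° vs 0.79 mm at 0°) because the two
  materials carry different N.

## Packaged experiment record

72 specimens: two ceramics × three thicknesses (0.5/1.0/1.5 mm) × 12,
fatigued at 49 N / 1.6 Hz for 1.2 × 10⁶ cycles with 5–55 °C thermocycling.
Six of twelve Z-0.5 specimens developed radial cracks (at 95,107; 95,296;
381,053; 630,042; 656,903; 840,513 cycles); every other specimen is
right-censored at the protocol length. Radial cracking is the event; wear
facets are not, and no specimen fractured completely or debonded. Cycle
counts are attached to sequential specimen IDs in ascending order — only
the multiset of counts is authoritative. Group labels: Z-0.5/1.0/1.5 and
(named here for symmetry) LD-0.5/1.0/1.5.

## Synthetic cohorts: what they emulate and what they do not

`simulate_cohort` draws each specimen's intrinsic strength from the
material's normal scatter (truncated at zero by rejection; negligible mass
for the packaged parameters), maps it deterministically through the model
to a lifetime, and right-censors at the protocol length. Failures are
recorded at ⌈n⌉ cycles. N is a material property — fixed within a cohort,
optionally drawn once per cohort (`scg_exponent_sd`) for band studies.

The generator reproduces exactly the statistical structure the analysis
assumes: strength scatter as the only randomness, deterministic
strength→lifetime mapping, ideal censoring. Passing tests therefore
demonstrate internal consistency (generator ↔ closed-form probability,
inversion ↔ generation, MLE recovery), not realism of actual chewing
simulation: real cohorts add cyclic contact damage, hydraulic pumping,
specimen geometry variation, cement-thickness scatter and detection lag
between crack initiation and periodic inspection, none of which are
modelled. The normal strength form itself is an assumption read from
mean ± SD reporting (n = 10); no Weibull alternative is fitted.

`fit_strength_distribution` inverts failures to exact strengths
(σ₀ ∝ n^{1/N}) and maximises the censored-normal log-likelihood (density
terms for failures, upper-tail survival terms for censored records) over
(μ, log s) with L-BFGS-B from a fixed three-point start grid —
deterministic, and robust to the flat likelihood region under heavy
censoring. Degenerate inputs (fewer than 3 failures, identical failure
strengths) are rejected. The likelihood ignores the zero-truncation of the
generator (mass < 10⁻⁴ at the packaged parameters).

## Problem sizes

Monte-Carlo agreement checks use 10⁵ specimens per configuration (binomial
3σ ≈ 0.35% at p ≈ 0.16); likelihood-recovery studies use 10⁴ specimens
(mean recovered within 1% uncensored, 10% when ~84% of records are
censored); curve tables use a 0.3–1.5 mm grid at 0.01 mm. These sizes make
the statistical tolerances tight while the full suite runs in seconds.

## Known limitations

- Validity is bounded by the empirical calibration: thin cement relative to
  the veneer (bracket > 0) and a plate stiffer than its foundation.
- Material constants are treated as homogeneous and isotropic; the gradient
  zirconia's transition zone is represented by 5Y-PSZ values.
- The years-in-service conversion (240,000 cycles/year) is a protocol
  convention, not a clinical measurement; design charts that mark
  "approximately five years" differ from the exact conversion used here.
- No inferential statistics across groups are computed — the validation is
  descriptive agreement between observed cycle counts and prediction bands.
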