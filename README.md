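# ovfatigue

Fatigue-lifetime prediction for thin ceramic **occlusal veneers** (OVs)
bonded to a compliant cement/dentin-analog foundation, for dental
biomaterials researchers deciding how thin a lithium disilicate or
translucent (5Y-PSZ-like) zirconia veneer may safely be.

The dominant catastrophic failure mode of a thin bonded veneer is the
**flexural radial crack**: a flexure-driven crack that pops in at the inner
(intaglio) cementation surface beneath the occlusal contact. `ovfatigue`
implements the closed-form mechanics of that failure mode and its fatigue
extension, validates the predictions against a packaged 72-specimen
chewing-simulation record, and provides a Monte-Carlo cohort generator with
a censored-likelihood strength fitter.

## The model

Only the normal component of the occlusal load F applied on a cusp incline
θ drives veneer flexure:

    F_n = F cos θ

Treating the veneer as a stiff plate of thickness *d* (mm) on a compliant
foundation, the critical load initiating a radial crack is

    F_nR = B σ d² / log(C E / E*)

with flexural strength σ (MPa), ceramic modulus E, dimensionless constants
B = 1.35, C ≈ 1, and the effective foundation modulus interpolating between
the cement (E_s = 7.9 GPa) and substrate (E_c = 18.6 GPa) moduli via an
empirical exponent set by the cement thickness h:

    E* = E_c (E_s / E_c)^L,   L = exp(−[α + β log(h/d)]^γ),
    α = 1.18, β = 0.33, γ = 3.13

In the moist oral environment, slow crack growth (SCG) degrades strength as
a power law in loading time, σ_F/σ_0 = (t_0/t_F)^{1/N}, with velocity
exponent N (≈25 for yttria-stabilized zirconia, ≈20 for lithium
disilicate). Setting the degraded critical load equal to the applied load
gives the number of chewing cycles to radial fracture at frequency f:

    n = f t_0 (F_nR / F_n)^N

Predictions are carried in log₁₀(n) (mean-band lifetimes exceed 10¹⁶ cycles
for thick veneers). The *lower band* combines σ − 1 SD with the lower
confidence bound on N; the *mean band* uses the mean σ and N. Because the
lifetime is a strictly increasing function of a specimen's drawn strength,
normal strength scatter yields a closed-form failure probability at any
cycle horizon — the quantity the Monte-Carlo generator reproduces.

## Worked example

```python
from ovfatigue import Band, predict_lifetime, preset_material, \
    load_packaged_experiment, validate_against_experiment
from ovfatigue.pipeline import ModelConfig

config = ModelConfig.packaged_defaults()
zirconia = preset_material("zirconia_5y")

pred = predict_lifetime(
    zirconia, config.geometry(0.5), config.foundation,
    config.load, config.constants, band=Band.lower,
)
print(f"F_n    = {pred.normal_load_Fn:.1f} N")
print(f"L      = {pred.interaction_exponent_L:.4f}")
print(f"E*     = {pred.effective_modulus_Estar:.2f} GPa")
print(f"F_nR   = {pred.critical_load_FnR:.1f} N")
print(f"log10 n = {pred.log10_cycles_to_failure:.2f}"
      f"  (~{10**pred.log10_cycles_to_failure:.2e} cycles)")

table = load_packaged_experiment(config.protocol)
report = validate_against_experiment(table, "Z-0.5", config=config)
print(f"observed failures: {report.n_failed}/{report.n_specimens}")
print(f"observed geomean / lower-band prediction = "
      f"{report.geomean_observed_over_lower:.2f}")
```

prints

```
F_n    = 47.3 N
L      = 0.5867
E*     = 11.25 GPa
F_nR   = 80.7 N
log10 n = 5.54  (~3.45e+05 cycles)
observed failures: 6/12
observed geomean / lower-band prediction = 0.94
```

Reading: a 49 N bite on the 15° cusp incline presses 47.3 N normally onto a
0.5 mm zirconia veneer. The 40 µm cement layer gives an effective
foundation modulus of 11.25 GPa, so the conservative (lower-band) critical
load is 80.7 N — above the applied load, but slow crack growth erodes that
margin within ~3.4 × 10⁵ chewing cycles, well inside the 1.2 × 10⁶-cycle
(five-year) protocol. The packaged experiment indeed saw 6 of 12 such
veneers crack, and the geometric mean of their failure cycle counts lands
within 6% of the lower-band prediction. The same CLI is available as
`ovfatigue curves|validate|simulate|fit|crossover|run` (see
`ovfatigue --help`).

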