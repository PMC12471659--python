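# Packaged parameter presets for the occlusal-veneer fatigue model.
# Units: moduli GPa, strengths MPa, lengths mm, load N, frequency Hz, time s,
# angles degrees. schema_version guards future layout changes.
schema_version = 1

[materials.lithium_disilicate]
name = "lithium_disilicate"
elastic_modulus_E = 95.0
strength_mean = 462.0
strength_sd = 34.0
scg_exponent_mean = 20.0
scg_exponent_lower = 17.0

# Gradient multilayered zirconia milled in the 4Y/5Y transition zone,
# assigned 5Y-PSZ properties (worst case for the gradient zone).
[materials.zirconia_5y]
name = "zirconia_5y"
elastic_modulus_E = 210.0
strength_mean = 411.0
strength_sd = 107.0
scg_exponent_mean = 25.0
scg_exponent_lower = 23.0

# Variolink Esthetic DC resin cement (~40 um) on Filtek Z100 dentin analog.
[foundation]
cement_modulus_Es = 7.9
substrate_modulus_Ec = 18.6
cement_thickness_h = 0.04

[load]
applied_load_F = 49.0
frequency_f = 1.6
reference_time_t0 = 1.0

[geometry]
cusp_incline_theta = 15.0

[constants]
B = 1.35
C = 1.0
alpha = 1.18
beta = 0.33
gamma = 3.13
log_base = "base10"

[protocol]
applied_load = 49.0
frequency = 1.6
total_cycles = 1200000
years_equivalent = 5.0
thermocycle_low_C = 5.0
thermocycle_high_C = 55.0
dwell_time_s = 120.0
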