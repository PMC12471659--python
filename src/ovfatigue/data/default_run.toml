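# Default batch run: full design-curve table, validation of every packaged
# experimental group, and one simulated Z-0.5-like cohort with a strength fit.
[run]
output_dir = "ovfatigue-out"
seed = 0

[curves]
materials = ["lithium_disilicate", "zirconia_5y"]
bands = ["lower", "mean"]
d_min = 0.3
d_max = 1.5
d_step = 0.01

[validate]
groups = ["LD-0.5", "LD-1.0", "LD-1.5", "Z-0.5", "Z-1.0", "Z-1.5"]

[simulate]
material = "zirconia_5y"
thickness_mm = 0.5
n_specimens = 12
censor_cycles = 1200000
fit = false
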