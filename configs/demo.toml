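# Demo pipeline configuration (overrides of the built-in defaults).
# Run with: retinotract run-all --config configs/demo.toml

seed = 1
outdir = "results/pipeline"

[synthetic]
mode = "OT"            # OT | LGN
n_units = 60
jitter_sigma = 0.13    # fraction of the 135-deg represented field
duration_s = 300.0     # checkerboard presentation time

[rf_mapping]
p_threshold = 1e-5
size_threshold_deg = 15.0

[mc]
reps = 1000

[jitter]
sigma_max = 0.5
sigma_step = 0.05
trials_per_sigma = 39000
measured_median_deg = 21.3   # measured OT nearby-pair median RF distance
geometry = "disk2d"          # disk2d | ball3d
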