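# Demo run: a 24x24 grid over an April-May hot spell, 24 wards, 36 stations.
# Five 3-day simulation segments; the first 24 h of each are spin-up; the
# 0700 UTC instants of the remaining days feed the hazard index.
seed: 0
out_dir: results/demo
nx: 24
ny: 24
cell_size: 333.0
start: "2024-04-23"
n_days: 15
freq_hours: 1
n_wards: 24
n_stations: 36
obs_noise_sd: 0.5
indicator_noise_sd: 0.3
spinup_hours: 24
segment_days: 3
analysis_hour_utc: 7
albedo: 0.3
emissivity: 0.97
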