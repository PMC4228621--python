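# WEST 2: noisy-data-set filter; strictest of the four presets.
name: WEST2
smoothness_max_pct: 10
high_start: true
max_change_khz: [2, 4]
reject_gap_ms: 2
body_over_us: 2000
fc_khz: [15, 60]
sc_oct_s: [-100, 1000]
sweep_khz: [0.1, 60]
s1_oct_s: [30, 9999]
duration_ms: [2, 30]
min_calls: 5
time_for_calls_s: 5
min_time_between_calls_ms: 50
pmc_pct: [8, 9999]
synthetic_lines:
  - {x_var: dur_ms, y_var: sweep_khz, p1: [6, 0], p2: [0, 3.5], min: 0, max: 60}
  - {x_var: dur_ms, y_var: sweep_khz, p1: [3.25, 0], p2: [1.75, 8], min: 0, max: 1000}
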