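# BCID filter settings (selection rules only; the proprietary classifier is
# out of scope).
name: BCID
smoothness_max_pct: 12
high_start: false
ignore_fragments_us: 2200
join_fragments_us: 2000
body_over_us: 2400
fmax_khz: [17, 120]
fmin_khz: [16, 60]
sweep_khz: [3, 70]
duration_ms: [1, 20]
min_calls: 5
time_for_calls_s: 15
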