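# BM filter: permissive frequency-modulated sequence selection with no
# characteristic-frequency bounds, in the style of early DOS-era rule sets.
name: BM
smoothness_max_pct: 15
high_start: false
body_over_us: 240
sweep_khz: [6, 300]
duration_ms: [1, 30]
min_calls: 5
time_for_calls_s: 5
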