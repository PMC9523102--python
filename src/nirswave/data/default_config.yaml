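# Default pipeline configuration; values mirror the study conditions.
band_hz: [0.01, 0.08]
filter_low_hz: 0.0095
filter_high_hz: 2.0
filter_order: 6
chromophores: [o2hb, hhb]
do_bandpass: true
do_ica: true
do_despike: true
ica_threshold: 0.5
despike_window_s: 3.0
despike_k: 5.0
n_voices: 16
omega0: 6.0
use_coi: true
n_surrogates: 50
wpco_significance: true
min_cycles: 5
duration_f_min_hz: 0.01
enforce_duration: true
alpha: 0.05
n_comparison_families: 3
paired: false
seed: 0
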