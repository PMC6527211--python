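# Reduced-scale profile for quick end-to-end runs: smaller populations and
# samples, fewer replicates, shorter boosting paths. Rates computed at this
# scale are noisy and the rarest exposures are often absent entirely; use
# the study profile for quantitative comparisons.
n_replicates: 20
methods: [ml, firth, ridge, lasso, boosting]
n_pop: 20000
n_cases: 1000
n_controls: 1000
p_count: 50
p_max: 0.03
p_min: 0.00005
snr: 3.0
alpha: 0.157
n_folds: 10
n_bootstrap: 100
m_max: 200
boost_penalty: 200.0
master_seed: 0
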