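# Study-scale defaults: 100 replicates of 100,000-subject populations,
# 5,000 cases + 5,000 controls, all five methods.
n_replicates: 100
methods: [ml, firth, ridge, lasso, boosting]
n_pop: 100000
n_cases: 5000
n_controls: 5000
p_count: 50
p_max: 0.03
p_min: 0.00005
snr: 3.0
alpha: 0.157
n_folds: 10
n_bootstrap: 100
m_max: 500
boost_penalty: 200.0
master_seed: 0
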