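"""Fit all five estimation procedures on one replicate and compare.

Prints each method's estimate for the five relevant exposures (true
effects alternate -1/+1) together with its selection decision.  Expect the
common exposures (3%, 0.6%) to be recovered by everyone and the rare ones
to separate the methods.  Runs in roughly half a minute.
"""

import numpy as np

import rarepen as rp

sample = rp.simulate_replicate(seed=7)
rel = [0, 12, 25, 38, 49]
truth = sample.truth.beta[rel]

fits = {
    "ml": rp.fit_ml_backward(sample),
    "firth": rp.fit_firth_backward(sample),
    "ridge": rp.fit_ridge(sample, seed=1),
    "lasso": rp.fit_lasso_cv(sample, seed=2),
    "boosting": rp.fit_boosting(sample),
}

header = "          " + "".join(f"{p:>12}" for p in
                               ("3%", "0.6%", "0.1%", "0.02%", "0.005%"))
print(header)
print("truth     " + "".join(f"{t:>12.0f}" for t in truth))
for name, fit in fits.items():
    cells = []
    for j in rel:
        mark = "*" if fit.selected[j] else " "
        cells.append(f"{fit.coefficients[j]:>11.2f}{mark}")
    print(f"{name:<10}" + "".join(cells))
print()
print("* = selected by the method's own rule (backward elimination p<0.157,")
print("nonzero at lambda_min, bootstrap interval excluding 0, or nonzero at")
print("the AIC-optimal boosting step). A blank with 0.00 means the variable")
print("was eliminated or never entered; rare exposures often vanish entirely.")
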