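"""The five estimation-and-selection procedures compared by the package.

* :func:`fit_ml_backward` -- maximum likelihood with Wald backward
  elimination at p < 0.157 (an AIC surrogate); variables whose likelihood
  fails to converge (separation, all-zero columns) are considered not
  selected.
* :func:`fit_firth_backward` -- Firth-penalized likelihood with backward
  elimination driven by profile-penalized-likelihood-ratio tests.
* :func:`fit_lasso_cv` -- L1 path + one 10-fold CV pass (see ``lasso``).
* :func:`fit_ridge` / :func:`fit_ridge_cv` / :func:`ridge_bootstrap_select`
  -- L2 with CV tuning and bootstrap percentile selection (see ``ridge``).
* :func:`fit_boosting` -- component-wise likelihood boosting with df-based
  AIC stopping (see ``boosting``).

Every procedure maps one :class:`~rarepen.cohort.CohortSample` to a
:class:`~rarepen.estimators_base.FitResult` whose ``coefficients`` are the
p slope estimates (0 for eliminated variables) and whose ``selected`` mask
is the method's selection decision.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .boosting import fit_boosting
from .estimators_base import FitResult
from .firth import firth_fit, firth_plr_pvalue
from .glm import irls_fit, wald_pvalues
from .lasso import fit_lasso_cv
from .ridge import fit_ridge, fit_ridge_cv, ridge_bootstrap_select

__all__ = [
    "FitResult",
    "fit_ml_backward",
    "fit_firth_backward",
    "fit_lasso_cv",
    "fit_ridge",
    "fit_ridge_cv",
    "ridge_bootstrap_select",
    "fit_boosting",
    "DEFAULT_ALPHA",
]

#: backward-elimination threshold; retention at p < 0.157 mimics AIC selection
DEFAULT_ALPHA = 0.157


def _check_alpha(alpha):
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def fit_ml_backward(sample, alpha: float = DEFAULT_ALPHA) -> FitResult:
    """Maximum likelihood with backward elimination at Wald p < ``alpha``.

    Starts from the full model.  At every refit, coefficients flagged as
    divergent (monotone likelihood) and all-constant columns are dropped
    immediately and marked nonconvergent -- hence not selected.  Otherwise
    the variable with the highest Wald p-value is eliminated (ties go to
    the lowest index) until all remaining p-values fall below ``alpha``.
    All pathologies end up as not-selected flags; nothing raises.
    """
    _check_alpha(alpha)
    X, y = sample.observed()
    X = np.asarray(X, dtype=float)
    p = X.shape[1]

    nonconvergent = np.zeros(p, dtype=bool)
    eliminated = np.zeros(p, dtype=bool)
    elimination_order: list[tuple[int, float]] = []

    active = np.arange(p)
    const = np.ptp(X, axis=0) == 0.0
    nonconvergent[const] = True
    active = active[~const]

    warm = None
    fit = None
    while True:
        fit = irls_fit(X[:, active], y, beta0=warm)
        flags = fit.divergence_flags[1:]
        if flags.any():
            nonconvergent[active[flags]] = True
            warm = np.delete(fit.coefficients, np.flatnonzero(flags) + 1)
            active = active[~flags]
            continue
        if not fit.converged:
            if active.size == 0:
                break
            # no divergent coefficient yet no convergence: treat the most
            # extreme coefficient as the monotone-likelihood culprit
            j = int(np.argmax(np.abs(fit.coefficients[1:])))
            nonconvergent[active[j]] = True
            warm = np.delete(fit.coefficients, j + 1)
            active = np.delete(active, j)
            continue
        if active.size == 0:
            break
        pvals = wald_pvalues(fit)[1:]
        if np.nanmax(pvals) < alpha:
            break
        j = int(np.nanargmax(pvals))
        elimination_order.append((int(active[j]), float(pvals[j])))
        eliminated[active[j]] = True
        warm = np.delete(fit.coefficients, j + 1)
        active = np.delete(active, j)

    coefficients = np.zeros(p)
    selected = np.zeros(p, dtype=bool)
    final_pvalues = np.full(p, np.nan)
    if active.size and fit is not None and fit.converged:
        coefficients[active] = fit.coefficients[1:]
        selected[active] = True
        final_pvalues[active] = wald_pvalues(fit)[1:]
    return FitResult(
        method="ml",
        intercept=float(fit.intercept) if fit is not None else 0.0,
        coefficients=coefficients,
        selected=selected,
        tuning={"alpha": alpha,
                "elimination_order": elimination_order,
                "final_p_values": final_pvalues},
        diagnostics={"nonconvergent": nonconvergent,
                     "eliminated": eliminated},
    )


def fit_firth_backward(sample, alpha: float = DEFAULT_ALPHA) -> FitResult:
    """Firth correction with PLR-test backward elimination at p < ``alpha``.

    Each elimination round refits every remaining variable's constrained
    model (that coefficient fixed at 0, penalty from the current working
    design) and compares twice the penalized-likelihood drop to a
    chi-square(1).  The highest p-value above ``alpha`` is eliminated and
    the working model refit.  All-constant columns cannot be estimated
    (singular information) and are flagged not selected up front.
    """
    _check_alpha(alpha)
    X, y = sample.observed()
    X = np.asarray(X, dtype=float)
    p = X.shape[1]

    nonconvergent = np.zeros(p, dtype=bool)
    eliminated = np.zeros(p, dtype=bool)
    elimination_order: list[tuple[int, float]] = []

    active = np.arange(p)
    const = np.ptp(X, axis=0) == 0.0
    nonconvergent[const] = True
    active = active[~const]

    from .firth import _Workspace
    Xa = _Workspace(sp.csr_matrix(X[:, active]))
    full = firth_fit(Xa, y)
    final_pvalues = np.full(p, np.nan)
    while active.size:
        k = active.size
        pvals = np.empty(k)
        for m in range(k):
            free = np.ones(k + 1, dtype=bool)
            free[m + 1] = False
            warm = full.coefficients.copy()
            warm[m + 1] = 0.0
            constrained = firth_fit(Xa, y, free=free, beta0=warm)
            pvals[m] = firth_plr_pvalue(full, constrained)
        if pvals.max() < alpha:
            final_pvalues[active] = pvals
            break
        j = int(np.argmax(pvals))
        elimination_order.append((int(active[j]), float(pvals[j])))
        eliminated[active[j]] = True
        warm = np.delete(full.coefficients, j + 1)
        active = np.delete(active, j)
        Xa = _Workspace(sp.csr_matrix(X[:, active]))
        full = firth_fit(Xa, y, beta0=warm)

    coefficients = np.zeros(p)
    selected = np.zeros(p, dtype=bool)
    if active.size:
        coefficients[active] = full.coefficients[1:]
        selected[active] = True
    return FitResult(
        method="firth",
        intercept=float(full.intercept) if active.size else 0.0,
        coefficients=coefficients,
        selected=selected,
        tuning={"alpha": alpha,
                "elimination_order": elimination_order,
                "final_p_values": final_pvalues},
        diagnostics={"nonconvergent": nonconvergent,
                     "eliminated": eliminated,
                     "converged": bool(full.converged)},
    )


#: registry used by the experiment driver and the CLI
METHODS = {
    "ml": fit_ml_backward,
    "firth": fit_firth_backward,
    "ridge": fit_ridge,
    "lasso": fit_lasso_cv,
    "boosting": fit_boosting,
}
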