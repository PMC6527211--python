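"""Binomial-logit numerical core shared by all estimators.

Provides the log-likelihood, an iteratively reweighted least squares (IRLS)
fitter with optional ridge penalty and step-halving, the observed Fisher
information, and Wald p-values.  Conventions used throughout the package:

* fit functions take the slope design ``X`` (n x p, no constant column) and
  prepend the intercept themselves; returned coefficient vectors put the
  intercept first;
* the intercept is never penalized;
* a fit never raises on numerical pathology -- separation, ill-conditioning
  and degenerate columns surface as ``converged=False`` and/or per-coefficient
  divergence flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats
from scipy.special import expit

#: |beta_j| beyond which a coefficient is treated as a monotone-likelihood
#: symptom (odds ratio > e^10); deliberately far outside the plausible range.
DIVERGENCE_THRESHOLD = 10.0


@dataclass(eq=False)
class LogisticFit:
    """Result of one (possibly penalized) logistic fit."""

    coefficients: np.ndarray              # intercept first
    standard_errors: np.ndarray | None
    log_likelihood: float
    converged: bool
    n_iterations: int
    divergence_flags: np.ndarray          # bool, aligned with coefficients
    penalized_log_likelihood: float | None = None
    ll_trace: tuple = field(default_factory=tuple)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


def log_likelihood(beta, X, y, offset=None) -> float:
    """Binomial log-likelihood sum(y log pi + (1-y) log(1-pi)).

    Evaluated as ``sum(y eta - log(1 + exp(eta)))`` with ``logaddexp`` so no
    probability is ever materialized at exactly 0 or 1.
    """
    eta = np.asarray(X, dtype=float) @ beta
    if offset is not None:
        eta = eta + offset
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fisher_information(beta, X) -> np.ndarray:
    """Observed Fisher information ``X' W X`` with ``W = diag(pi (1-pi))``.

    ``X`` is used exactly as passed (include the constant column yourself).
    """
    X = np.asarray(X, dtype=float)
    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    return X.T @ (X * w[:, None])


def irls_fit(X, y, offset=None, l2: float = 0.0, beta0=None,
             max_iter: int = 50, tol: float = 1e-8, l2_scale=None,
             compute_se: bool = True,
             divergence_threshold: float = DIVERGENCE_THRESHOLD) -> LogisticFit:
    """Newton/IRLS fit of the logistic model, optionally ridge-penalized.

    Maximizes ``l(beta) - l2 * sum_j (s_j beta_j)^2`` (slopes only) by
    damped Newton steps until the free-coordinate gradient satisfies
    ``max |grad| < tol`` or ``max_iter`` is reached.  The optional
    per-slope scales ``s_j`` (``l2_scale``) express penalties on a
    standardized-covariate scale; by default every ``s_j = 1``.  With
    ``l2 = 0``, constant slope columns are excluded from the solve
    (coefficient 0) and flagged, since the unpenalized information matrix
    would be singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    k = p + 1

    pen = np.zeros(k)
    # d/dbeta of l2 * (s beta)^2 penalty (intercept free)
    if l2_scale is None:
        pen[1:] = 2.0 * l2
    else:
        s = np.broadcast_to(np.asarray(l2_scale, dtype=float), (p,))
        pen[1:] = 2.0 * l2 * np.where(s > 0, s, 1.0) ** 2

    free = np.ones(k, dtype=bool)
    degenerate = np.zeros(k, dtype=bool)
    if l2 == 0.0 and p:
        col_const = np.ptp(X, axis=0) == 0.0
        degenerate[1:] = col_const
        free[1:] = ~col_const

    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    beta[~free] = 0.0

    def pen_ll(b):
        return log_likelihood(b, Xd, y, offset) - 0.5 * float(pen @ (b * b))

    ll_trace = [pen_ll(beta)]
    converged = False
    finite_ok = True
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        if offset is not None:
            eta = eta + offset
        pi = expit(eta)
        w = pi * (1.0 - pi)
        if not np.all(np.isfinite(w)):
            finite_ok = False
            break
        grad = Xd.T @ (y - pi) - pen * beta
        if np.max(np.abs(grad[free])) < tol:
            converged = True
            it -= 1
            break
        H = Xd[:, free].T @ (Xd[:, free] * w[:, None]) + np.diag(pen[free])
        try:
            delta = scipy.linalg.solve(H, grad[free], assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            delta = np.linalg.lstsq(H, grad[free], rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            finite_ok = False
            break
        # step-halving: never accept a step that decreases the objective
        f0 = ll_trace[-1]
        trial = beta.copy()
        for _ in range(11):
            trial[free] = beta[free] + delta
            f1 = pen_ll(trial)
            if np.isfinite(f1) and f1 >= f0 - 1e-10:
                break
            delta = 0.5 * delta
        beta = trial
        ll_trace.append(f1)
    else:
        it = max_iter

    if finite_ok and not converged:
        eta = Xd @ beta
        if offset is not None:
            eta = eta + offset
        pi = expit(eta)
        grad = Xd.T @ (y - pi) - pen * beta
        converged = bool(np.max(np.abs(grad[free]), initial=0.0) < tol)

    flags = np.abs(beta) > divergence_threshold
    flags |= degenerate
    converged = converged and finite_ok and not flags.any()

    se = None
    if finite_ok and compute_se:
        eta = Xd @ beta
        if offset is not None:
            eta = eta + offset
        w = expit(eta) * (1.0 - expit(eta))
        Hf = Xd[:, free].T @ (Xd[:, free] * w[:, None]) + np.diag(pen[free])
        try:
            cov = np.linalg.inv(Hf)
            se = np.full(k, np.nan)
            se[free] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = None

    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=log_likelihood(beta, Xd, y, offset),
        converged=converged,
        n_iterations=it,
        divergence_flags=flags,
        penalized_log_likelihood=pen_ll(beta) if finite_ok else -np.inf,
        ll_trace=tuple(ll_trace),
    )


def wald_pvalues(fit: LogisticFit) -> np.ndarray:
    """Two-sided normal-reference p-values for beta_j / SE_j.

    Coefficients without a standard error (degenerate columns) get ``nan``.
    """
    if fit.standard_errors is None:
        raise ValueError("fit has no standard errors; Wald tests unavailable")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.coefficients / fit.standard_errors
    return 2.0 * stats.norm.sf(np.abs(z))
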