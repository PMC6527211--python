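"""Firth bias-reduced logistic regression.

Maximizes the penalized log-likelihood

    l*(beta) = l(beta) + 0.5 * log det I(beta),

where ``I`` is the observed Fisher information of the working design.  The
penalty keeps estimates finite under separation and shrinks them towards
zero.  Fitting uses Firth-modified scoring: the score is adjusted by the
hat-value terms ``h_i (1/2 - pi_i)`` and steps are damped by halving when
the penalized likelihood would decrease.  Convergence is declared when the
Newton step vanishes or the penalized likelihood reaches a plateau with a
small adjusted score -- the objective can be extremely flat along
rare-column directions, where coefficient-based criteria alone stall.

``firth_fit`` also supports fixing a subset of coefficients at zero while
the penalty keeps using the *full* working design's information -- this is
the constrained fit behind profile-penalized-likelihood-ratio tests.

All heavy pieces (information matrix, hat values, score) are assembled
through sparse products, since the binary exposure designs this package
fits are a few percent ones; callers may pass a ``scipy.sparse`` design
directly to amortize the conversion across repeated fits.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy import stats
from scipy.special import expit

from .glm import DIVERGENCE_THRESHOLD, LogisticFit


def _as_sparse(X):
    if sp.issparse(X):
        return sp.csr_matrix(X)
    return sp.csr_matrix(np.asarray(X, dtype=float))


class _Workspace:
    """Precomputed sparsity structure of one design, shared across fits.

    Keeps the flat (row, col, value) triplets of the slope design plus a
    mutable weighted copy, so each scoring iteration assembles the
    information matrix with plain array indexing instead of repeated
    sparse-format conversions.
    """

    def __init__(self, X):
        self.Xs = _as_sparse(X)
        self.n, self.p = self.Xs.shape
        self.rows = np.repeat(np.arange(self.n), np.diff(self.Xs.indptr))
        self.cols = self.Xs.indices
        self.data = self.Xs.data
        self.Xw = self.Xs.copy()  # data overwritten with w-weighted values

    def eta(self, beta):
        out = np.full(self.n, beta[0])
        if self.data.size:
            out += np.bincount(self.rows,
                               weights=self.data * beta[1:][self.cols],
                               minlength=self.n)
        return out

    def info(self, w):
        """Observed information of (intercept, slopes) at weights w."""
        k = self.p + 1
        wdata = self.data * w[self.rows]
        self.Xw.data = wdata
        out = np.empty((k, k))
        out[1:, 1:] = (self.Xw.T @ self.Xs).toarray()
        out[0, 0] = float(w.sum())
        out[0, 1:] = out[1:, 0] = np.bincount(
            self.cols, weights=wdata, minlength=self.p)
        return out

    def transpose_dot(self, v):
        """[sum v, X' v] -- the design-transpose product with intercept."""
        out = np.empty(self.p + 1)
        out[0] = float(v.sum())
        out[1:] = np.bincount(self.cols, weights=self.data * v[self.rows],
                              minlength=self.p)
        return out

    def row_quadratic(self, V):
        """Per-row x_i' M x_i pieces: (x V)_i . x_i for dense M=V given X V."""
        T = self.Xs @ V
        q = np.zeros(self.n)
        if self.data.size:
            q = np.bincount(self.rows,
                            weights=self.data * T[self.rows, self.cols],
                            minlength=self.n)
        return q


def _state(ws, y, beta):
    """Likelihood pieces at beta; None when the information is singular."""
    eta = ws.eta(beta)
    pi = expit(eta)
    w = pi * (1.0 - pi)
    info = ws.info(w)
    try:
        cho = scipy.linalg.cho_factor(info)
    except (scipy.linalg.LinAlgError, ValueError):
        return None
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return {"pi": pi, "w": w, "info": info, "cho": cho,
            "ll": ll, "pll": ll + 0.5 * logdet}


def firth_fit(X, y, free=None, beta0=None, max_iter: int = 40,
              tol: float = 1e-6, pll_tol: float = 1e-8,
              score_tol: float = 1e-2) -> LogisticFit:
    """Firth-penalized fit; ``free`` marks coefficients to estimate.

    ``free`` is a boolean mask over (intercept, slopes); masked-out
    coefficients are held at zero while the penalty continues to use the
    full design's information matrix, giving the constrained fits needed
    for profile-penalized-likelihood-ratio tests.

    ``X`` may be a dense array, a sparse matrix, or a prebuilt
    :class:`_Workspace` (which amortizes structure setup across the many
    constrained fits of a backward-elimination round).
    """
    ws = X if isinstance(X, _Workspace) else _Workspace(X)
    y = np.asarray(y, dtype=float)
    k = ws.p + 1
    free = np.ones(k, dtype=bool) if free is None else np.asarray(free, bool)
    eye = np.eye(k)

    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    beta[~free] = 0.0

    st = _state(ws, y, beta)
    if st is None and beta0 is not None:  # bad warm start; retry cold
        beta = np.zeros(k)
        st = _state(ws, y, beta)
    if st is None:
        return _failed_fit(beta, k)

    all_free = bool(free.all())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # hat values of the full design: h_i = w_i x_i' I^-1 x_i, expanded
        # into intercept, cross and slope-block terms over the sparse rows
        Vinv = scipy.linalg.cho_solve(st["cho"], eye)
        u = ws.Xs @ Vinv[0, 1:]
        q = ws.row_quadratic(Vinv[1:, 1:])
        h = st["w"] * (Vinv[0, 0] + 2.0 * u + q)
        adj = y - st["pi"] + h * (0.5 - st["pi"])
        score = ws.transpose_dot(adj)
        try:
            if all_free:
                delta = Vinv @ score
            else:
                If = st["info"][np.ix_(free, free)]
                delta = scipy.linalg.solve(If, score[free], assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            break
        if not np.all(np.isfinite(delta)):
            break
        if np.max(np.abs(delta), initial=0.0) < tol:
            converged = True
            it -= 1
            break
        trial = beta.copy()
        new_st = None
        for _ in range(11):
            if all_free:
                trial = beta + delta
            else:
                trial[free] = beta[free] + delta
            new_st = _state(ws, y, trial)
            if new_st is not None and new_st["pll"] >= st["pll"] - 1e-10:
                break
            delta = 0.5 * delta
        if new_st is None:
            break
        plateau = new_st["pll"] - st["pll"] < pll_tol
        beta, st = trial, new_st
        if plateau and np.max(np.abs(score[free]), initial=0.0) < score_tol:
            converged = True
            break

    flags = np.abs(beta) > DIVERGENCE_THRESHOLD
    se = None
    try:
        cov = scipy.linalg.cho_solve(st["cho"], eye)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se[~free] = np.nan
    except (scipy.linalg.LinAlgError, ValueError):
        pass

    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=st["ll"],
        converged=bool(converged and not flags.any()),
        n_iterations=it,
        divergence_flags=flags,
        penalized_log_likelihood=st["pll"],
    )


def _failed_fit(beta, k) -> LogisticFit:
    return LogisticFit(
        coefficients=beta, standard_errors=None, log_likelihood=-np.inf,
        converged=False, n_iterations=0,
        divergence_flags=np.zeros(k, dtype=bool),
        penalized_log_likelihood=-np.inf)


def firth_plr_pvalue(full_fit: LogisticFit, constrained_fit: LogisticFit) -> float:
    """Profile-penalized-likelihood-ratio p-value against chi-square(1)."""
    if (full_fit.penalized_log_likelihood is None
            or constrained_fit.penalized_log_likelihood is None
            or not np.isfinite(constrained_fit.penalized_log_likelihood)):
        return 1.0
    lr = 2.0 * (full_fit.penalized_log_likelihood
                - constrained_fit.penalized_log_likelihood)
    return float(stats.chi2.sf(max(lr, 0.0), 1))
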