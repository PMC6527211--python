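"""Synthetic case-control cohorts with rare, weakly correlated binary exposures.

The generator emulates an unmatched case-control study of rare drug-like
exposures.  A large source population is built in four stages:

1. a grid of exposure prevalences, log-evenly spaced so that ultra-rare
   exposures (down to 1 in 20,000) are represented;
2. a random pairwise association structure expressed through joint
   "common probabilities" ``P(x_i=1, x_j=1) = P(x_i) P(x_j) 2**h_ij`` with
   ``h_ij ~ N(0, 0.25)`` (variance 0.25, i.e. sd 0.5), clamped to the
   Frechet bounds so that every joint probability is consistent with its
   margins;
3. correlated binary exposures obtained by thresholding a latent
   multivariate normal whose pairwise correlations are solved (per pair, by
   bisection on the bivariate orthant probability) so that the joint
   success probabilities match the requested common probabilities, with a
   nearest-positive-semidefinite repair of the latent correlation matrix;
4. a Bernoulli outcome from a logistic model with five signed unit effects
   and two unobserved 50%-prevalence binary confounders whose shared effect
   magnitude ``gamma`` is calibrated to a target signal-to-noise ratio.

A case-control sample of fixed size is then drawn without replacement
within outcome strata.  Estimators only ever see the exposures and the
outcome: the confounder matrix ``Z`` travels with the sample for bookkeeping
but is never part of the estimator-facing design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit


class ConfigurationError(ValueError):
    """Generation parameters are out of range or mutually inconsistent."""


class GenerationError(RuntimeError):
    """A population cannot supply the requested case-control sample."""


#: default prevalence-grid endpoints: 3% down to 0.005% (1 in 20,000)
DEFAULT_P_MAX = 0.03
DEFAULT_P_MIN = 5e-5
#: 0-based positions of the five relevant exposures (x1, x13, x26, x39, x50)
DEFAULT_RELEVANT = (0, 12, 25, 38, 49)
#: alternating effect signs of the generating model -x1 +x13 -x26 +x39 -x50
DEFAULT_SIGNS = (-1, 1, -1, 1, -1)
#: sd of the pairwise association exponents h_ij ~ N(0, 0.25)
H_SD = 0.5


def _rng(seed) -> np.random.Generator:
    """Accept an int, a SeedSequence or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_prevalence_grid(p_count: int,
                         p_max: float = DEFAULT_P_MAX,
                         p_min: float = DEFAULT_P_MIN) -> np.ndarray:
    """Log-evenly spaced prevalences, descending from ``p_max`` to ``p_min``.

    Endpoints are exact; interior points follow
    ``p_k = p_max * (p_min / p_max) ** ((k - 1) / (p_count - 1))``.
    """
    if p_count < 2:
        raise ConfigurationError(f"p_count must be >= 2, got {p_count}")
    if not (0.0 < p_min <= p_max < 1.0):
        raise ConfigurationError(
            f"prevalence bounds must satisfy 0 < p_min <= p_max < 1, "
            f"got p_min={p_min}, p_max={p_max}")
    grid = np.geomspace(p_max, p_min, p_count)
    grid[0], grid[-1] = p_max, p_min  # keep endpoints exact
    return grid


@dataclass(frozen=True, eq=False)
class ExposureSpec:
    """Truth of the generating model: prevalence grid, relevant set, signs."""

    prevalences: np.ndarray
    relevant_indices: tuple = DEFAULT_RELEVANT
    effect_signs: tuple = DEFAULT_SIGNS

    def __post_init__(self):
        object.__setattr__(self, "prevalences",
                           np.asarray(self.prevalences, dtype=float))
        p = self.prevalences.size
        if len(self.relevant_indices) != len(self.effect_signs):
            raise ConfigurationError("one sign per relevant exposure required")
        if len(set(self.relevant_indices)) != len(self.relevant_indices):
            raise ConfigurationError("relevant indices must be unique")
        if any(not 0 <= j < p for j in self.relevant_indices):
            raise ConfigurationError("relevant index out of range")
        if any(s not in (-1, 1) for s in self.effect_signs):
            raise ConfigurationError("effect signs must be +1 or -1")

    @property
    def n_exposures(self) -> int:
        return self.prevalences.size

    @property
    def beta(self) -> np.ndarray:
        """Signed unit effects; 0 for irrelevant exposures."""
        b = np.zeros(self.n_exposures)
        b[list(self.relevant_indices)] = self.effect_signs
        return b

    @property
    def irrelevant_indices(self) -> np.ndarray:
        mask = np.ones(self.n_exposures, dtype=bool)
        mask[list(self.relevant_indices)] = False
        return np.flatnonzero(mask)

    @classmethod
    def default(cls) -> "ExposureSpec":
        """The 50-exposure study design with relevant set {x1,x13,x26,x39,x50}."""
        return cls(make_prevalence_grid(50))


@dataclass(frozen=True, eq=False)
class AssociationDraw:
    """Pairwise association exponents and the implied joint probabilities."""

    h: np.ndarray            # symmetric matrix of exponents, diagonal unused
    common_prob: np.ndarray  # symmetric joint success probabilities


@dataclass(frozen=True)
class PopulationConfig:
    """Source-population parameters."""

    n_pop: int = 100_000
    intercept: float = 0.0
    snr: float = 3.0
    confounder_prevalence: float = 0.5

    def __post_init__(self):
        if self.n_pop <= 0:
            raise ConfigurationError(f"n_pop must be positive, got {self.n_pop}")
        if self.snr <= 0:
            raise ConfigurationError(f"snr must be positive, got {self.snr}")
        if not 0 < self.confounder_prevalence < 1:
            raise ConfigurationError("confounder prevalence must be in (0, 1)")


@dataclass(eq=False)
class CohortSample:
    """One case-control replicate.

    ``Z`` is retained for generation bookkeeping only; estimators receive
    ``X`` and ``y`` through :meth:`observed` and never see the confounders.
    """

    X: np.ndarray
    y: np.ndarray
    Z: np.ndarray | None = None
    truth: ExposureSpec | None = None
    gamma: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_exposures(self) -> int:
        return self.X.shape[1]

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Estimator-facing view: exposures and outcome, never ``Z``."""
        return self.X, self.y

    def to_frame(self) -> pd.DataFrame:
        """Exposures plus outcome as a DataFrame (x1..xp, y); ``Z`` withheld."""
        cols = {f"x{j + 1}": self.X[:, j] for j in range(self.n_exposures)}
        cols["y"] = self.y
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# pairwise association structure

def common_probability(p_i, p_j, h):
    """Joint success probability ``p_i p_j 2**h`` clamped to Frechet bounds."""
    p_i, p_j, h = np.broadcast_arrays(np.asarray(p_i, float), p_j, h)
    raw = p_i * p_j * np.exp2(h)
    lower = np.maximum(0.0, p_i + p_j - 1.0)
    upper = np.minimum(p_i, p_j)
    return np.clip(raw, lower, upper)


def draw_common_probabilities(prevalences, seed) -> AssociationDraw:
    """Draw ``h_ij ~ N(0, H_SD**2)`` and derive clamped joint probabilities."""
    p = np.asarray(prevalences, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ConfigurationError("all prevalences must lie in (0, 1)")
    k = p.size
    rng = _rng(seed)
    h = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    h[iu] = rng.normal(0.0, H_SD, size=iu[0].size)
    h += h.T
    common = common_probability(p[:, None], p[None, :], h)
    np.fill_diagonal(common, p)
    return AssociationDraw(h=h, common_prob=common)


# ---------------------------------------------------------------------------
# latent-Gaussian threshold sampling

_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_RHO_MAX = 1.0 - 1e-7


def bivariate_normal_cdf(a, b, rho):
    """Standard bivariate normal ``P(U <= a, V <= b)`` with correlation rho.

    Evaluated through the tetrachoric integral
    ``Phi(a) Phi(b) + (1/2pi) int_0^rho exp(-(a^2 - 2abr + b^2)/(2(1-r^2)))
    / sqrt(1-r^2) dr`` with 64-point Gauss-Legendre quadrature.  The additive
    form keeps the tail-pair values accurate even when ``Phi(a) Phi(b)`` is
    itself tiny, which matters for exposures with prevalence ~1e-4.
    """
    a, b, rho = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(rho, float))
    return stats.norm.cdf(a) * stats.norm.cdf(b) + _bvn_correction(a, b, rho)


def _bvn_correction(a, b, rho):
    """The correlation integral term of the tetrachoric expansion."""
    r = 0.5 * rho[..., None] * (_GL_X + 1.0)
    omr2 = 1.0 - r * r
    aa = a[..., None]
    bb = b[..., None]
    integrand = np.exp(-(aa * aa - 2.0 * aa * bb * r + bb * bb) / (2.0 * omr2))
    integrand /= np.sqrt(omr2)
    return 0.5 * rho * (integrand @ _GL_W) / (2.0 * np.pi)


def solve_latent_correlation(a, b, target, tol: float = 1e-10) -> np.ndarray:
    """Solve ``Phi2(a, b; rho) = target`` for rho, elementwise.

    The correction integral is strictly increasing in rho, so a vectorized
    bisection is used.  Targets at (or numerically beyond) the Frechet
    bounds saturate at rho = +/-(1 - 1e-7); non-finite inputs fall back to
    independence with a warning.
    """
    a, b, target = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(target, float))
    shape = a.shape
    a, b = a.ravel(), b.ravel()
    # correction needed relative to the independence orthant probability
    t = target.ravel() - stats.norm.cdf(a) * stats.norm.cdf(b)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{bad.sum()} pair(s) had non-finite joint-probability "
                      "targets; falling back to independence for them")
        t = np.where(bad, 0.0, t)
    lo = np.full(a.size, -_RHO_MAX)
    hi = np.full(a.size, _RHO_MAX)
    f_lo = _bvn_correction(a, b, lo) - t
    f_hi = _bvn_correction(a, b, hi) - t
    rho = np.zeros(a.size)
    saturated_hi = f_hi <= 0
    saturated_lo = f_lo >= 0
    rho[saturated_hi] = _RHO_MAX
    rho[saturated_lo] = -_RHO_MAX
    free = ~(saturated_hi | saturated_lo | bad | (t == 0.0))
    while np.any((hi[free] - lo[free]) > tol):
        mid = 0.5 * (lo + hi)
        f_mid = _bvn_correction(a, b, mid) - t
        go_up = f_mid < 0
        lo = np.where(free & go_up, mid, lo)
        hi = np.where(free & ~go_up, mid, hi)
    rho[free] = 0.5 * (lo + hi)[free]
    return rho.reshape(shape)


def sample_correlated_binary(prevalences, assoc: AssociationDraw, n: int,
                             seed, psd_eps: float = 1e-8) -> np.ndarray:
    """Correlated Bernoulli matrix by thresholding a latent Gaussian.

    Per pair, the latent correlation is solved so the bivariate lower-orthant
    probability equals the requested common probability; the resulting
    correlation matrix is repaired to the nearest PSD matrix by eigenvalue
    clipping before Cholesky sampling.
    """
    p = np.asarray(prevalences, dtype=float)
    k = p.size
    thresholds = stats.norm.ppf(p)  # success := latent <= threshold
    iu = np.triu_indices(k, 1)
    rho = solve_latent_correlation(thresholds[iu[0]], thresholds[iu[1]],
                                   assoc.common_prob[iu])
    R = np.eye(k)
    R[iu] = rho
    R.T[iu] = rho
    w, V = np.linalg.eigh(R)
    if w.min() < psd_eps:
        w = np.clip(w, psd_eps, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
    latent = _rng(seed).standard_normal((n, k)) @ L.T
    return (latent <= thresholds).astype(np.int8)


# ---------------------------------------------------------------------------
# outcome model

def calibrate_gamma(X, spec: ExposureSpec, snr: float = 3.0,
                    confounder_prevalence: float = 0.5) -> float:
    """Confounder effect magnitude hitting the target signal-to-noise ratio.

    With independent confounders z1, z2 of prevalence q and effects
    +gamma/-gamma, ``Var(gamma z1 - gamma z2) = 2 gamma^2 q(1-q)``, so
    ``gamma = sqrt(Var(X beta) / (snr * 2 q (1-q)))`` where the signal
    variance is taken empirically over the population.
    """
    var_signal = float(np.var(np.asarray(X, dtype=float) @ spec.beta))
    if var_signal <= 0.0:
        raise ConfigurationError(
            "signal variance is zero; cannot calibrate confounder effects")
    q = confounder_prevalence
    return float(np.sqrt(var_signal / (snr * 2.0 * q * (1.0 - q))))


def outcome_probability(X, Z, spec: ExposureSpec, gamma: float,
                        intercept: float = 0.0) -> np.ndarray:
    """P(y=1 | x, z) under the generating logistic model."""
    eta = intercept + np.asarray(X, dtype=float) @ spec.beta
    eta += gamma * Z[:, 0] - gamma * Z[:, 1]
    return expit(eta)


def simulate_outcome(X, Z, spec: ExposureSpec, gamma: float,
                     intercept: float, seed) -> np.ndarray:
    """Bernoulli outcomes from :func:`outcome_probability`."""
    prob = outcome_probability(X, Z, spec, gamma, intercept)
    return (_rng(seed).random(prob.size) < prob).astype(np.int8)


def draw_case_control(X, Z, y, n_cases: int, n_controls: int, seed,
                      truth: ExposureSpec | None = None,
                      gamma: float | None = None,
                      meta: dict | None = None) -> CohortSample:
    """Sample exactly ``n_cases``/``n_controls`` without replacement per stratum."""
    y = np.asarray(y)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size < n_cases:
        raise GenerationError(
            f"population holds {cases.size} cases but {n_cases} were "
            f"requested (short by {n_cases - cases.size})")
    if controls.size < n_controls:
        raise GenerationError(
            f"population holds {controls.size} controls but {n_controls} were "
            f"requested (short by {n_controls - controls.size})")
    rng = _rng(seed)
    idx = np.concatenate([rng.choice(cases, size=n_cases, replace=False),
                          rng.choice(controls, size=n_controls, replace=False)])
    return CohortSample(X=X[idx], y=y[idx],
                        Z=None if Z is None else Z[idx],
                        truth=truth, gamma=gamma, meta=dict(meta or {}))


def simulate_replicate(spec: ExposureSpec | None = None,
                       pop: PopulationConfig | None = None,
                       n_cases: int = 5000, n_controls: int = 5000,
                       seed=0) -> CohortSample:
    """One full replicate: population, calibrated outcome, case-control draw.

    Every stage (association draw, exposures, confounders, outcomes,
    sampling) consumes its own stream spawned from ``seed``, so replicates
    are bit-reproducible and stages individually re-runnable.
    """
    spec = spec or ExposureSpec.default()
    pop = pop or PopulationConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_assoc, s_x, s_z, s_y, s_draw = ss.spawn(5)
    assoc = draw_common_probabilities(spec.prevalences, s_assoc)
    X = sample_correlated_binary(spec.prevalences, assoc, pop.n_pop, s_x)
    Z = _rng(s_z).binomial(1, pop.confounder_prevalence,
                           size=(pop.n_pop, 2)).astype(np.int8)
    gamma = calibrate_gamma(X, spec, pop.snr, pop.confounder_prevalence)
    y = simulate_outcome(X, Z, spec, gamma, pop.intercept, s_y)
    return draw_case_control(
        X, Z, y, n_cases, n_controls, s_draw, truth=spec, gamma=gamma,
        meta={"seed_entropy": ss.entropy, "n_pop": pop.n_pop,
              "intercept": pop.intercept, "snr": pop.snr})


# ---------------------------------------------------------------------------
# persistence

def write_cohort(sample: CohortSample, csv_path) -> Path:
    """Write the estimator-facing cohort CSV plus a JSON truth sidecar."""
    csv_path = Path(csv_path)
    sample.to_frame().to_csv(csv_path, index=False)
    sidecar = {"gamma": sample.gamma, "meta": sample.meta}
    if sample.truth is not None:
        sidecar["truth"] = {
            "prevalences": sample.truth.prevalences.tolist(),
            "relevant_indices": list(sample.truth.relevant_indices),
            "effect_signs": list(sample.truth.effect_signs),
        }
    side_path = csv_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return side_path


def read_cohort(csv_path) -> CohortSample:
    """Load a cohort written by :func:`write_cohort`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    y = df.pop("y").to_numpy(dtype=np.int8)
    X = df.to_numpy(dtype=np.int8)
    truth = gamma = None
    meta: dict = {}
    side_path = csv_path.with_suffix(".json")
    if side_path.exists():
        sidecar = json.loads(side_path.read_text())
        gamma = sidecar.get("gamma")
        meta = sidecar.get("meta", {})
        if "truth" in sidecar:
            t = sidecar["truth"]
            truth = ExposureSpec(np.asarray(t["prevalences"]),
                                 tuple(t["relevant_indices"]),
                                 tuple(t["effect_signs"]))
    return CohortSample(X=X, y=y, Z=None, truth=truth, gamma=gamma, meta=meta)
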