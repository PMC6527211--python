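"""Aggregation of replicate fits into selection-rate, bias and MSE summaries.

Selection rates are reported as percentages over (replicate, variable)
pairs: for relevant variables they are true-positive rates, for irrelevant
variables false-positive rates.  Bias and MSE use the convention that an
unselected variable contributes an estimate of exactly 0 -- which is why a
relevant variable that is never selected shows a mean bias of exactly
-beta_j (i.e. +/-1 for the unit effects used here).

Irrelevant variables are grouped by prevalence into equal-size bins (9 per
group for the 50-exposure design), rarest group first, mirroring the
canonical false-positive-rate table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ExposureSpec
from .estimators_base import FitResult


@dataclass(eq=False)
class ReplicateRecord:
    """All methods' fits on one simulated dataset, plus the generating truth."""

    replicate_id: int
    truth: ExposureSpec
    fits: dict[str, FitResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "replicate_id": self.replicate_id,
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
        }


@dataclass(eq=False)
class SummaryTables:
    """Selection-rate, bias and MSE aggregates across replicates."""

    selection_relevant: pd.DataFrame      # methods x relevant prevalences (%)
    selection_irrelevant: pd.DataFrame    # methods x prevalence groups (%)
    selection_relevant_se: pd.DataFrame   # binomial Monte-Carlo SEs (pp)
    selection_irrelevant_se: pd.DataFrame
    mean_bias: pd.DataFrame               # methods x variables
    mse: pd.DataFrame                     # methods x variables
    n_replicates: int


def bias(estimate, truth):
    """Per-replicate bias beta_hat - beta."""
    return np.asarray(estimate, dtype=float) - truth


def mse(estimates, truth) -> float:
    """Mean squared error over replicates for one variable."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("mse needs at least one replicate")
    return float(np.mean((estimates - truth) ** 2))


def _selection_matrix(records, method) -> np.ndarray:
    """(replicates x variables) boolean selection matrix for one method."""
    rows = []
    for rec in records:
        if method not in rec.fits:
            raise KeyError(f"method {method!r} missing from replicate "
                           f"{rec.replicate_id}")
        rows.append(rec.fits[method].selected)
    return np.asarray(rows, dtype=bool)


def selection_rate(records, method: str, variables) -> float:
    """100 x selected-pairs / total-pairs for the given variable set."""
    variables = np.atleast_1d(np.asarray(variables, dtype=int))
    sel = _selection_matrix(records, method)
    if variables.size and (variables.min() < 0 or
                           variables.max() >= sel.shape[1]):
        raise KeyError(f"variable index out of range: {variables}")
    return float(100.0 * sel[:, variables].mean())


def prevalence_groups(spec: ExposureSpec, n_groups: int = 5):
    """Partition the irrelevant variables into prevalence bins.

    Variables are sorted by true prevalence (descending) and cut into
    ``n_groups`` consecutive equal-size chunks; returned rarest-first as
    (label, indices) pairs.  For the 50-exposure design this reproduces the
    9-per-interval grouping whose boundaries match the log grid.
    """
    irrelevant = spec.irrelevant_indices
    if irrelevant.size % n_groups:
        raise ValueError(
            f"{irrelevant.size} irrelevant variables cannot be split into "
            f"{n_groups} equal groups")
    order = irrelevant[np.argsort(-spec.prevalences[irrelevant],
                                  kind="stable")]
    chunks = np.split(order, n_groups)[::-1]  # rarest group first
    out = []
    for chunk in chunks:
        prevs = spec.prevalences[chunk]
        label = f"{_pct(prevs.min())}-{_pct(prevs.max())}"
        out.append((label, np.sort(chunk)))
    return out


def _pct(p: float) -> str:
    return f"{100.0 * p:.3g}%"


def _binomial_se(rate_pct: float, n_pairs: int) -> float:
    r = rate_pct / 100.0
    return 100.0 * float(np.sqrt(r * (1.0 - r) / n_pairs))


def build_summary_tables(records, methods=None) -> SummaryTables:
    """Selection-rate tables plus per-variable mean-bias and MSE tables."""
    records = list(records)
    if not records:
        raise ValueError("no replicates to summarize")
    truth = records[0].truth
    if methods is None:
        methods = list(records[0].fits)
    missing = [(m, rec.replicate_id) for rec in records for m in methods
               if m not in rec.fits]
    if missing:
        raise ValueError(f"incomplete replicate set; missing cells: {missing}")
    B = len(records)
    beta = truth.beta
    p = truth.n_exposures

    # relevant variables, most rare first to mirror the canonical layout
    rel = sorted(truth.relevant_indices, key=lambda j: truth.prevalences[j])
    rel_labels = [_pct(truth.prevalences[j]) for j in rel]
    groups = prevalence_groups(truth)

    sel_rel, sel_irr, se_rel, se_irr = {}, {}, {}, {}
    bias_rows, mse_rows = {}, {}
    for m in methods:
        sel = _selection_matrix(records, m)
        est = np.array([rec.fits[m].effective_estimates() for rec in records])
        sel_rel[m] = [100.0 * sel[:, j].mean() for j in rel]
        se_rel[m] = [_binomial_se(r, B) for r in sel_rel[m]]
        sel_irr[m] = [100.0 * sel[:, idx].mean() for _, idx in groups]
        se_irr[m] = [_binomial_se(r, B * len(idx))
                     for r, (_, idx) in zip(sel_irr[m], groups)]
        bias_rows[m] = (est - beta).mean(axis=0)
        mse_rows[m] = ((est - beta) ** 2).mean(axis=0)

    var_labels = [f"x{j + 1}" for j in range(p)]
    group_labels = [lab for lab, _ in groups]
    return SummaryTables(
        selection_relevant=pd.DataFrame.from_dict(
            sel_rel, orient="index", columns=rel_labels),
        selection_irrelevant=pd.DataFrame.from_dict(
            sel_irr, orient="index", columns=group_labels),
        selection_relevant_se=pd.DataFrame.from_dict(
            se_rel, orient="index", columns=rel_labels),
        selection_irrelevant_se=pd.DataFrame.from_dict(
            se_irr, orient="index", columns=group_labels),
        mean_bias=pd.DataFrame.from_dict(
            bias_rows, orient="index", columns=var_labels),
        mse=pd.DataFrame.from_dict(
            mse_rows, orient="index", columns=var_labels),
        n_replicates=B,
    )
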