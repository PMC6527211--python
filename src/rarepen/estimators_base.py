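"""Shared result container for the five estimation-and-selection procedures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(eq=False)
class FitResult:
    """One method's slope estimates and selection decisions on one sample.

    ``coefficients`` holds the p slope estimates on the log-odds scale with
    eliminated/degenerate variables reported as 0; ``selected`` is the
    method's selection decision per variable.  For the lasso and boosting
    ``selected`` is equivalent to a nonzero coefficient; for ML and Firth it
    means the variable survived backward elimination; for ridge it reflects
    the bootstrap percentile interval.  ``tuning`` records the method's
    tuning trace (penalty grids, CV deviances, elimination order, ...) and
    ``diagnostics`` per-variable convergence bookkeeping.
    """

    method: str
    intercept: float
    coefficients: np.ndarray
    selected: np.ndarray
    tuning: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_exposures(self) -> int:
        return self.coefficients.size

    def effective_estimates(self) -> np.ndarray:
        """Estimates as they enter bias/MSE summaries: 0 unless selected."""
        return np.where(self.selected, self.coefficients, 0.0)

    def to_dict(self, full: bool = False) -> dict:
        """JSON-ready representation; ``full`` keeps large tuning arrays."""
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer, np.bool_)):
                return v.item()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            return v

        tuning = self.tuning if full else {
            k: v for k, v in self.tuning.items()
            if not (isinstance(v, np.ndarray) and v.ndim > 1)}
        return {
            "method": self.method,
            "intercept": float(self.intercept),
            "coefficients": self.coefficients.tolist(),
            "selected": self.selected.astype(bool).tolist(),
            "tuning": conv(tuning),
            "diagnostics": conv(self.diagnostics),
        }

    def to_json(self, path, full: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(full), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            method=d["method"],
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            selected=np.asarray(d["selected"], dtype=bool),
            tuning=d.get("tuning", {}),
            diagnostics=d.get("diagnostics", {}),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))
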