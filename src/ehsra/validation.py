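"""Validation of the score against tympanic temperature.

Two routes: an empirical ordinary-least-squares regression on scored
records, and a closed-form R-squared computed directly from a printed
correlation matrix, standard deviations and the index constants (the
linear-combination oracle, positive air-velocity sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_index import VARIABLES, IndexSpec
from .errors import InputError, NumericalError


@dataclass(frozen=True)
class ValidationReport:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "residual_sd": self.residual_sd,
        }


def regress(scores, tympanic) -> ValidationReport:
    """OLS of tympanic temperature on the score."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(tympanic, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InputError(f"need at least 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite values in regression input")
    if np.var(x) == 0:
        raise InputError("score variance is zero; regression undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    residual_sd = float(np.sqrt(resid @ resid / (x.size - 2)))
    return ValidationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
        residual_sd=residual_sd,
    )


def closed_form_r2(
    correlations,
    sds,
    spec: IndexSpec | None = None,
    outcome: str = "tympanic",
) -> float:
    """R-squared of the linear score against the outcome, from moments alone.

    With weights w_i = c_i * sd_i / range_i (positive air-velocity sign),

        R^2 = (w' r)^2 / (w' R w)

    where R is the predictor correlation block and r the outcome column.
    The overall x10 scale cancels, as does any rescaling of the weights.
    """
    spec = spec or IndexSpec()
    names = list(VARIABLES) + [outcome]
    if isinstance(correlations, pd.DataFrame):
        missing = [v for v in names if v not in correlations.columns]
        if missing:
            raise InputError(f"correlation input lacks variable(s): {missing}")
        C = correlations.loc[names, names].to_numpy(dtype=float)
    else:
        C = np.asarray(correlations, dtype=float)
    p = len(names)
    if C.shape != (p, p):
        raise InputError(f"expected {p}x{p} correlation matrix, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise InputError("correlation matrix is not symmetric")
    if np.linalg.eigvalsh(C).min() <= 0:
        raise NumericalError("correlation matrix is not positive definite")

    sd = np.asarray(sds, dtype=float)
    if isinstance(sds, (pd.Series, dict)):
        sd = np.asarray([dict(sds)[v] for v in VARIABLES], dtype=float)
    sd = sd[: len(VARIABLES)]
    if (sd <= 0).any():
        raise InputError(f"standard deviations must be positive: {sd}")

    w = np.asarray(spec.coefficients) * sd / np.asarray(spec.norm_range)
    R = C[:-1, :-1]
    r = C[:-1, -1]
    return float((w @ r) ** 2 / (w @ R @ w))
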