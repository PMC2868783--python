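"""Shared fit statistics: no-intercept least squares and ratio estimators.

Conventions (chosen to match the reported statistics of the binding
fits): ``r`` is the Pearson correlation between observed and fitted
values, and the residual SD uses an n - p denominator with p the number
of fitted coefficients.  Coefficient standard errors come from the
unscaled covariance sd**2 * (X'X)**-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NumericalError, ValidationError

__all__ = ["FitStats", "lstsq_no_intercept", "ratio_mean_estimator"]


@dataclass(frozen=True)
class FitStats:
    coefficients: tuple[float, ...]
    stderr: tuple[float, ...]
    r: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("residual SD cannot be negative")


def lstsq_no_intercept(x, y) -> FitStats:
    """Least squares of y on the columns of x with no intercept.

    Minimizes ||y - X b||^2.  Raises on rank deficiency rather than
    returning a minimum-norm solution, since a collinear design means the
    coefficients are not identified.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(y).size == x.shape[1]:
        x = x.T
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n != y.size:
        raise ValidationError("X and y have incompatible lengths")
    if n < p:
        raise ValidationError("more coefficients than observations")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise NumericalError("predictor matrix is rank deficient (collinear design)")
    fitted = x @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    dof = n - p
    sd = math.sqrt(rss / dof) if dof > 0 else 0.0
    if n >= 2 and np.std(y) > 0 and np.std(fitted) > 0:
        r = float(np.corrcoef(y, fitted)[0, 1])
    else:
        r = 1.0 if rss == 0 else float("nan")
    cov = sd * sd * np.linalg.inv(x.T @ x)
    stderr = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    return FitStats(tuple(float(b) for b in beta), stderr, r, sd, n)


def ratio_mean_estimator(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the per-pair ratios y_i / x_i."""
    if len(pairs) == 0:
        raise ValidationError("at least one pair is required")
    if any(x <= 0 for _, x in pairs):
        raise ValidationError("all denominators must be positive")
    ratios = np.array([y / x for y, x in pairs], dtype=float)
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return mean, sd
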