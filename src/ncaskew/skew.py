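"""Skewness measures and the logit scale transforms.

Two skewness notions are used throughout: the method-of-moments sample
skewness ``g1 = m3 / m2**1.5`` (central moments with denominator ``n``,
no small-sample bias correction), and the analytic skewness of a
``Beta(alpha, beta)`` distribution. Both are plain functions with no I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import BoundaryEffectError, InvalidShapeError, UndefinedSkewnessError

__all__ = [
    "BetaShape",
    "sample_skewness",
    "beta_skewness",
    "logit",
    "inv_logit",
]


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters of a beta distribution; both must be positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidShapeError(
                f"beta shape parameters must be positive, got ({self.alpha}, {self.beta})"
            )


def sample_skewness(values) -> float:
    """Method-of-moments sample skewness g1 = m3 / m2^(3/2).

    Central moments use denominator ``n`` (no Fisher-Pearson adjustment),
    matching the classical moment-ratio estimator.

    Raises
    ------
    UndefinedSkewnessError
        For samples shorter than 3 or with zero variance.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise UndefinedSkewnessError("sample skewness needs at least 3 values")
    if not np.all(np.isfinite(arr)):
        raise UndefinedSkewnessError("sample skewness needs finite values")
    if np.ptp(arr) == 0.0:
        raise UndefinedSkewnessError("sample skewness undefined for constant input")
    return float(stats.skew(arr, bias=True))


def beta_skewness(shape: BetaShape) -> float:
    """Analytic skewness of Beta(alpha, beta):
    ``2 (beta - alpha) sqrt(alpha + beta + 1) / ((alpha + beta + 2) sqrt(alpha beta))``.
    """
    a, b = shape.alpha, shape.beta
    return 2.0 * (b - a) * math.sqrt(a + b + 1.0) / ((a + b + 2.0) * math.sqrt(a * b))


def logit(p: float) -> float:
    """Log-odds transform; defined on the open interval (0, 1).

    Raises
    ------
    BoundaryEffectError
        For p equal to 0 or 1 (a boundary effect size); the caller decides
        whether to exclude or otherwise handle such values.
    """
    if not 0.0 < p < 1.0:
        if p == 0.0 or p == 1.0:
            raise BoundaryEffectError(f"logit undefined at boundary effect {p}")
        raise ValueError(f"logit requires p in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def inv_logit(z: float) -> float:
    """Inverse logit (expit), mapping the real line into (0, 1)."""
    return float(stats.logistic.cdf(z))
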