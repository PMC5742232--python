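"""Meta-models linking skewness and sample size to expected necessity.

Two regression families are fitted on simulation output:

* **Effect models** — OLS of ``logit(effect)`` on ``{1, Skew(X), Skew(Y),
  Skew(X)*Skew(Y)}`` across per-dataset records (observed sample
  skewnesses by default). The logit link keeps predictions inside (0, 1).
* **SE models** — OLS of ``log(SE)`` on ``{1, sqrt(N), Skew(X), Skew(Y)}``
  across per-cell empirical standard errors (design skewnesses). The log
  link keeps predicted standard errors positive.

Published coefficient sets from the original simulation study ship as
module constants (``PUBLISHED_EFFECT_CE`` etc.) so expected effects and
confidence intervals are available without any simulation run. The
confidence interval is the plain two-standard-error band
``expected +/- 2 * SE``; bounds are deliberately *not* truncated to [0, 1].

``meta_nca`` turns the method on itself: it measures how strongly the
skewness of X (upper-right corner: low skew enables high effects), the
skewness of Y, and sample size cap the CR-FDH values produced by the
simulation, with a bottleneck table from the CR ceiling line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import UnfittableModelError
from .nca import BottleneckTable, XYDataset, bottleneck, nca_effect
from .skew import inv_logit

__all__ = [
    "EffectModel",
    "SEModel",
    "ExpectationReport",
    "PUBLISHED_EFFECT_CE",
    "PUBLISHED_EFFECT_CR",
    "PUBLISHED_SE_CE",
    "PUBLISHED_SE_CR",
    "fit_effect_model",
    "fit_se_model",
    "predict_effect",
    "predict_se",
    "confidence_interval",
    "expected_table",
    "assess_observed",
    "meta_nca",
    "MetaNCAResult",
]

logger = logging.getLogger(__name__)

Estimator = Literal["CE-FDH", "CR-FDH"]


@dataclass(frozen=True)
class EffectModel:
    """Logit-scale effect regression:
    ``logit(effect) = b0 + b_x*Skew(X) + b_y*Skew(Y) + b_xy*Skew(X)*Skew(Y)``.
    """

    estimator: Estimator
    b0: float
    b_x: float
    b_y: float
    b_xy: float
    r2: Optional[float] = None
    n_used: Optional[int] = None


@dataclass(frozen=True)
class SEModel:
    """Log-scale standard-error regression:
    ``log(SE) = c0 + c_n*sqrt(N) + c_x*Skew(X) + c_y*Skew(Y)``.
    """

    estimator: Estimator
    c0: float
    c_n: float
    c_x: float
    c_y: float
    r2: Optional[float] = None
    n_used: Optional[int] = None


# Published coefficient sets from the original simulation study
# (245,000 datasets; full replication count).
PUBLISHED_EFFECT_CE = EffectModel("CE-FDH", b0=-3.19, b_x=-1.14, b_y=1.14,
                                  b_xy=0.10, r2=0.70)
PUBLISHED_EFFECT_CR = EffectModel("CR-FDH", b0=-3.02, b_x=-0.88, b_y=0.95,
                                  b_xy=-0.027, r2=0.64)
PUBLISHED_SE_CE = SEModel("CE-FDH", c0=-3.14, c_n=-0.013, c_x=-0.67,
                          c_y=0.65, r2=0.71)
PUBLISHED_SE_CR = SEModel("CR-FDH", c0=-3.09, c_n=-0.0078, c_x=-0.40,
                          c_y=0.48, r2=0.87)

_EFFECT_COL = {"CE-FDH": "ce", "CR-FDH": "cr"}
_SE_COL = {"CE-FDH": "se_ce", "CR-FDH": "se_cr"}


@dataclass(frozen=True)
class ExpectationReport:
    """Expected effect with two-SE confidence interval at one design point,
    optionally compared against an observed effect. CI bounds may fall
    outside [0, 1]; they are reported untruncated."""

    estimator: Estimator
    skew_x: float
    skew_y: float
    n: int
    expected: float
    se: float
    ci_low: float
    ci_high: float
    multiplier: float = 2.0
    observed: Optional[float] = None
    verdict: Literal["within", "above", "below", "n/a"] = "n/a"

    @property
    def ci_outside_unit(self) -> bool:
        return self.ci_low < 0.0 or self.ci_high > 1.0


def _ols(y: np.ndarray, X: np.ndarray):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnfittableModelError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    return fit.params, float(fit.rsquared)


def fit_effect_model(records: pd.DataFrame, estimator: Estimator = "CE-FDH",
                     skew_source: Literal["observed", "design"] = "observed",
                     ) -> EffectModel:
    """Fit the logit-scale effect regression on simulation records.

    Records with a missing effect or a boundary effect (exactly 0 or 1,
    where the logit is undefined) are excluded with a logged count.
    ``skew_source`` selects per-dataset observed skewnesses (default) or
    the cell design skewnesses as predictors.
    """
    col = _EFFECT_COL[estimator]
    if skew_source == "observed":
        sx_col, sy_col = "skew_x_obs", "skew_y_obs"
    elif skew_source == "design":
        sx_col, sy_col = "pop_skew_x", "pop_skew_y"
    else:
        raise ValueError(f"unknown skew_source {skew_source!r}")
    eff = records[col].to_numpy(dtype=float)
    usable = np.isfinite(eff) & (eff > 0.0) & (eff < 1.0)
    n_excl = int(len(eff) - usable.sum())
    if n_excl:
        logger.info("effect model (%s): excluded %d boundary/missing records",
                    estimator, n_excl)
    if usable.sum() < 10:
        raise UnfittableModelError(
            f"only {int(usable.sum())} usable records; need at least 10")
    sx = records.loc[usable, sx_col].to_numpy(dtype=float)
    sy = records.loc[usable, sy_col].to_numpy(dtype=float)
    z = np.log(eff[usable] / (1.0 - eff[usable]))
    X = np.column_stack([np.ones_like(sx), sx, sy, sx * sy])
    params, r2 = _ols(z, X)
    return EffectModel(estimator, *map(float, params), r2=r2,
                       n_used=int(usable.sum()))


def fit_se_model(cells: pd.DataFrame, estimator: Estimator = "CE-FDH",
                 ) -> SEModel:
    """Fit the log-scale SE regression on per-cell summaries.

    Predictors are sqrt(sample size) and the cell *design* skewnesses.
    Cells with zero or missing SE (log undefined) are excluded with a
    warning.
    """
    col = _SE_COL[estimator]
    se = cells[col].to_numpy(dtype=float)
    usable = np.isfinite(se) & (se > 0.0)
    n_excl = int(len(se) - usable.sum())
    if n_excl:
        logger.warning("SE model (%s): excluded %d cells with zero/missing SE",
                       estimator, n_excl)
    if usable.sum() < 5:
        raise UnfittableModelError(
            f"only {int(usable.sum())} usable cells; need at least 5")
    sub = cells.loc[usable]
    sqrt_n = np.sqrt(sub["n"].to_numpy(dtype=float))
    sx = sub["pop_skew_x"].to_numpy(dtype=float)
    sy = sub["pop_skew_y"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(sqrt_n), sqrt_n, sx, sy])
    params, r2 = _ols(np.log(se[usable]), X)
    return SEModel(estimator, *map(float, params), r2=r2,
                   n_used=int(usable.sum()))


def predict_effect(model: EffectModel, skew_x: float, skew_y: float) -> float:
    """Expected effect in (0, 1): inverse logit of the linear predictor."""
    z = model.b0 + model.b_x * skew_x + model.b_y * skew_y \
        + model.b_xy * skew_x * skew_y
    return inv_logit(z)


def predict_se(model: SEModel, n: float, skew_x: float, skew_y: float) -> float:
    """Predicted standard error (> 0): exp of the linear predictor."""
    return math.exp(model.c0 + model.c_n * math.sqrt(n)
                    + model.c_x * skew_x + model.c_y * skew_y)


def confidence_interval(expected: float, se: float,
                        multiplier: float = 2.0) -> tuple[float, float]:
    """Approximate 95% interval: expected +/- multiplier * SE, untruncated."""
    if se <= 0:
        raise ValueError("se must be positive")
    return expected - multiplier * se, expected + multiplier * se


def _one_report(effect_model: EffectModel, se_model: SEModel,
                skew_x: float, skew_y: float, n: int,
                multiplier: float = 2.0,
                observed: Optional[float] = None) -> ExpectationReport:
    expected = predict_effect(effect_model, skew_x, skew_y)
    se = predict_se(se_model, n, skew_x, skew_y)
    low, high = confidence_interval(expected, se, multiplier)
    verdict = "n/a"
    if observed is not None:
        verdict = "above" if observed > high else "below" if observed < low \
            else "within"
    return ExpectationReport(effect_model.estimator, skew_x, skew_y, int(n),
                             expected, se, low, high, multiplier, observed,
                             verdict)


def expected_table(skew_x_values: Sequence[float], skew_y: float,
                   n_values: Sequence[int],
                   effect_models: Sequence[EffectModel] = (PUBLISHED_EFFECT_CE,
                                                           PUBLISHED_EFFECT_CR),
                   se_models: Sequence[SEModel] = (PUBLISHED_SE_CE, PUBLISHED_SE_CR),
                   multiplier: float = 2.0) -> pd.DataFrame:
    """Expected effects and CIs over a grid of predictor skewnesses.

    One row per (skew_x, estimator); the expected effect plus a CI column
    pair per sample size. Defaults use the published coefficient sets.
    """
    rows = []
    for sx in skew_x_values:
        for em, sm_ in zip(effect_models, se_models):
            assert em.estimator == sm_.estimator
            row = {"skew_x": float(sx), "skew_y": float(skew_y),
                   "estimator": em.estimator,
                   "expected": predict_effect(em, sx, skew_y)}
            for n in n_values:
                rep = _one_report(em, sm_, sx, skew_y, n, multiplier)
                row[f"ci_low_n{n}"] = rep.ci_low
                row[f"ci_high_n{n}"] = rep.ci_high
            rows.append(row)
    return pd.DataFrame(rows)


def assess_observed(observed_ce: Optional[float], observed_cr: Optional[float],
                    skew_x: float, skew_y: float, n: int,
                    multiplier: float = 2.0,
                    ) -> tuple[Optional[ExpectationReport],
                               Optional[ExpectationReport]]:
    """Compare observed CE-FDH / CR-FDH effects against what skewness alone
    predicts, using the published models. Verdict is "above" only when the
    observed effect exceeds the two-SE band — the situation where a genuine
    necessity interpretation has support beyond distribution shape."""
    ce_rep = cr_rep = None
    if observed_ce is not None:
        ce_rep = _one_report(PUBLISHED_EFFECT_CE, PUBLISHED_SE_CE, skew_x, skew_y, n,
                             multiplier, observed_ce)
    if observed_cr is not None:
        cr_rep = _one_report(PUBLISHED_EFFECT_CR, PUBLISHED_SE_CR, skew_x, skew_y, n,
                             multiplier, observed_cr)
    return ce_rep, cr_rep


@dataclass(frozen=True)
class MetaNCAResult:
    """Necessity effects of the study design variables on CR-FDH output."""

    effects: pd.DataFrame          # predictor x estimator -> effect size
    estimates: dict                # (predictor, method) -> NCAEstimate
    bottleneck_skew_x: BottleneckTable
    bottleneck_skew_y: BottleneckTable
    levels: tuple


def meta_nca(records: pd.DataFrame,
             levels: Sequence[float] = (0.1, 0.3, 0.5)) -> MetaNCAResult:
    """NCA of the simulation output itself, with CR-FDH as the outcome.

    Predictors: observed Skew(X) (upper-right corner — *low* predictor
    skewness enables high necessity effects), observed Skew(Y)
    (upper-left), and sample size (upper-left). Records with missing
    CR-FDH are dropped. Bottleneck tables invert each skewness predictor's
    CR ceiling line at the given outcome levels: the Skew(X) table reads
    "at most", the Skew(Y) table "at least"."""
    valid = records.dropna(subset=["cr"])
    outcome = valid["cr"].to_numpy(dtype=float)
    predictors = {
        "skew_x": (valid["skew_x_obs"].to_numpy(dtype=float), "upper-right"),
        "skew_y": (valid["skew_y_obs"].to_numpy(dtype=float), "upper-left"),
        "n": (valid["n"].to_numpy(dtype=float), "upper-left"),
    }
    rows = []
    estimates = {}
    for name, (xvals, corner) in predictors.items():
        data = XYDataset(xvals, outcome)
        for method in ("CE-FDH", "CR-FDH"):
            est = nca_effect(data, method=method, corner=corner)
            estimates[(name, method)] = est
            rows.append({"predictor": name, "method": method,
                         "corner": corner, "effect": est.effect})
    effects = pd.DataFrame(rows)
    bx_est = estimates[("skew_x", "CR-FDH")]
    by_est = estimates[("skew_y", "CR-FDH")]
    bn_x = bottleneck(bx_est.line, bx_est.scope, levels, corner="upper-right")
    bn_y = bottleneck(by_est.line, by_est.scope, levels, corner="upper-left")
    return MetaNCAResult(effects=effects, estimates=estimates,
                         bottleneck_skew_x=bn_x, bottleneck_skew_y=bn_y,
                         levels=tuple(levels))
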