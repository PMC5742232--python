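"""Necessity effect estimation from bivariate data.

A necessity effect asks whether high outcome values require a minimum
predictor level. It is quantified as the fraction of the *scope* — the
rectangle spanned by the observed extrema,
``(x_max - x_min) * (y_max - y_min)`` — that lies in the empty upper-left
corner of the X-Y scatterplot, above a *ceiling* drawn through the frontier
points.

Two ceilings are provided:

* **CE-FDH** (ceiling envelopment with free disposal hull): a step function
  through the *peers*, the points whose y strictly exceeds the y of every
  point at smaller x. Its effect is always defined.
* **CR-FDH** (ceiling regression): the OLS line through those same peers,
  clipped to the scope before area integration so the effect stays in
  [0, 1]. Undefined when there are fewer than two peers.

Effects below 0.1 are conventionally read as small, 0.1-0.3 medium,
0.3-0.5 large, above 0.5 very large.

The default corner is upper-left ("at least this much X is needed for high
Y"). The upper-right corner — low X enabling high Y — is obtained by
reflecting x and mapping the ceiling back to original units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import FlatCeilingError, UndefinedScopeError

__all__ = [
    "XYDataset",
    "Scope",
    "PeerSet",
    "CeilingLine",
    "NCAEstimate",
    "BottleneckTable",
    "find_peers",
    "ce_fdh",
    "cr_fdh",
    "nca_effect",
    "bottleneck",
    "empty_zone_oracle",
]

Method = Literal["CE-FDH", "CR-FDH"]
Corner = Literal["upper-left", "upper-right"]


@dataclass(frozen=True)
class XYDataset:
    """Paired predictor/outcome observations, the unit of one analysis.

    Requires at least three finite pairs with non-constant x and y;
    otherwise the scope has zero area and the effect is undefined.
    """

    xs: np.ndarray
    ys: np.ndarray

    def __init__(self, xs, ys):
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if xs.ndim != 1 or ys.ndim != 1 or xs.size != ys.size:
            raise ValueError("xs and ys must be 1-d sequences of equal length")
        if xs.size < 3:
            raise ValueError("need at least 3 observations")
        if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
            raise ValueError("all values must be finite")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    @property
    def n(self) -> int:
        return int(self.xs.size)

    def scope(self) -> "Scope":
        return Scope.of(self.xs, self.ys)


@dataclass(frozen=True)
class Scope:
    """Observed-extrema bounding rectangle; the effect-size denominator."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @classmethod
    def of(cls, xs: np.ndarray, ys: np.ndarray) -> "Scope":
        s = cls(float(xs.min()), float(xs.max()), float(ys.min()), float(ys.max()))
        if s.area <= 0.0:
            raise UndefinedScopeError(
                "undefined scope: x or y is constant, scope area is zero"
            )
        return s

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class PeerSet:
    """Ordered ceiling points: strictly increasing in both coordinates."""

    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def points(self) -> Sequence[Tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


@dataclass(frozen=True)
class CeilingLine:
    """Ceiling regression line ``y = intercept + slope * x`` in data units."""

    intercept: float
    slope: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class NCAEstimate:
    """One necessity effect size.

    ``effect`` is ``zone_area / scope.area`` and lies in [0, 1]; it is
    ``None`` only for CR-FDH with fewer than two peers. ``line`` (for
    CR-FDH) and ``peers`` are in original data units regardless of corner.
    """

    method: Method
    corner: Corner
    effect: Optional[float]
    zone_area: float
    scope: Scope
    peers: PeerSet
    line: Optional[CeilingLine] = None

    @property
    def defined(self) -> bool:
        return self.effect is not None


@dataclass(frozen=True)
class BottleneckTable:
    """Required predictor level per target outcome level, from ceiling inversion.

    ``direction`` is "at-least" for the upper-left corner (X must be at
    least this high) and "at-most" for the upper-right corner.
    """

    levels: np.ndarray
    required: np.ndarray
    direction: Literal["at-least", "at-most"]

    def rows(self):
        return list(zip(self.levels.tolist(), self.required.tolist()))


def _peer_arrays(xs: np.ndarray, ys: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Frontier scan on raw arrays; assumes a valid (non-degenerate) scope.

    Ties in x collapse to the per-x maximum y first, so "all points with a
    lower x-value" is unambiguous; the strict y-dominance scan then keeps
    only the leftmost point attaining each new maximum.
    """
    order = np.argsort(xs, kind="stable")
    sx = xs[order]
    sy = ys[order]
    # group boundaries of distinct x in the sorted arrays
    starts = np.flatnonzero(np.concatenate(([True], sx[1:] != sx[:-1])))
    ux = sx[starts]
    uy = np.maximum.reduceat(sy, starts)
    running = np.maximum.accumulate(uy)
    prev = np.concatenate(([-np.inf], running[:-1]))
    keep = uy > prev
    return ux[keep], uy[keep]


def find_peers(data: XYDataset) -> PeerSet:
    """Ceiling points: after per-x deduplication (max y per distinct x),
    the points whose y strictly exceeds the y of every point at strictly
    smaller x, ordered by increasing x. The first peer sits at x_min.
    """
    data.scope()  # raises UndefinedScopeError on degenerate data
    px, py = _peer_arrays(data.xs, data.ys)
    assert np.all(np.diff(px) > 0) and np.all(np.diff(py) > 0)
    return PeerSet(px, py)


def _ce_zone(px: np.ndarray, py: np.ndarray, scope: Scope) -> float:
    # sum over peers of (x_next - x_i) * (y_max - y_i), x_next of last = x_max
    x_next = np.concatenate((px[1:], [scope.x_max]))
    return float(np.sum((x_next - px) * (scope.y_max - py)))


def ce_fdh(data: XYDataset) -> NCAEstimate:
    """Step-function (free disposal hull) necessity effect.

    The empty zone is the union of rectangles above the step ceiling:
    ``sum_i (x_{i+1} - x_i) * (y_max - y_i)`` over peers, the last strip
    ending at x_max.
    """
    scope = data.scope()
    px, py = _peer_arrays(data.xs, data.ys)
    zone = _ce_zone(px, py, scope)
    return NCAEstimate(
        method="CE-FDH",
        corner="upper-left",
        effect=zone / scope.area,
        zone_area=zone,
        scope=scope,
        peers=PeerSet(px, py),
    )


def _ols_line(px: np.ndarray, py: np.ndarray) -> CeilingLine:
    xm = px.mean()
    ym = py.mean()
    dx = px - xm
    slope = float(np.dot(dx, py - ym) / np.dot(dx, dx))
    return CeilingLine(intercept=ym - slope * xm, slope=slope)


def _clipped_line_zone(line: CeilingLine, scope: Scope) -> float:
    """Closed-form integral of ``y_max - clip(line(x), y_min, y_max)`` over
    [x_min, x_max]: split at the clip crossings, then exact trapezoids
    (the clipped height is piecewise linear)."""
    breaks = [scope.x_min, scope.x_max]
    if line.slope != 0.0:
        for target in (scope.y_min, scope.y_max):
            xc = (target - line.intercept) / line.slope
            if scope.x_min < xc < scope.x_max:
                breaks.append(xc)
    bx = np.array(sorted(breaks))
    h = scope.y_max - np.clip(line(bx), scope.y_min, scope.y_max)
    return float(np.sum((h[1:] + h[:-1]) / 2.0 * np.diff(bx)))


def cr_fdh(data: XYDataset) -> NCAEstimate:
    """Ceiling-regression necessity effect: OLS line through the CE-FDH
    peers, clipped to the scope, with the area above it integrated in
    closed form. Undefined (effect None) when there are fewer than two
    peers — reported as missing, not zero."""
    scope = data.scope()
    px, py = _peer_arrays(data.xs, data.ys)
    peers = PeerSet(px, py)
    if len(px) < 2:
        return NCAEstimate(
            method="CR-FDH",
            corner="upper-left",
            effect=None,
            zone_area=0.0,
            scope=scope,
            peers=peers,
        )
    line = _ols_line(px, py)
    zone = _clipped_line_zone(line, scope)
    return NCAEstimate(
        method="CR-FDH",
        corner="upper-left",
        effect=zone / scope.area,
        zone_area=zone,
        scope=scope,
        peers=peers,
        line=line,
    )


def _reflect_estimate(est: NCAEstimate, corner: Corner) -> NCAEstimate:
    """Map an estimate computed on x-negated data back to original units."""
    scope = Scope(
        x_min=-est.scope.x_max,
        x_max=-est.scope.x_min,
        y_min=est.scope.y_min,
        y_max=est.scope.y_max,
    )
    peers = PeerSet(-est.peers.x[::-1].copy(), est.peers.y[::-1].copy())
    line = None
    if est.line is not None:
        # y = a + b*(-x) becomes y = a - b*x in original units
        line = CeilingLine(intercept=est.line.intercept, slope=-est.line.slope)
    return NCAEstimate(
        method=est.method,
        corner=corner,
        effect=est.effect,
        zone_area=est.zone_area,
        scope=scope,
        peers=peers,
        line=line,
    )


def nca_effect(data: XYDataset, method: Method = "CE-FDH",
               corner: Corner = "upper-left") -> NCAEstimate:
    """Necessity effect for either corner.

    The upper-left corner delegates to :func:`ce_fdh` / :func:`cr_fdh`
    unchanged. The upper-right corner — where a *low* predictor enables a
    high outcome — applies the same estimator to the x-reflected dataset
    and maps ceiling and peers back to original units; the effect value is
    reflection-consistent by construction.
    """
    if method not in ("CE-FDH", "CR-FDH"):
        raise ValueError(f"unknown method {method!r}")
    if corner == "upper-left":
        return ce_fdh(data) if method == "CE-FDH" else cr_fdh(data)
    if corner != "upper-right":
        raise ValueError(f"unknown corner {corner!r}")
    reflected = XYDataset(-data.xs, data.ys)
    est = ce_fdh(reflected) if method == "CE-FDH" else cr_fdh(reflected)
    return _reflect_estimate(est, "upper-right")


def bottleneck(line: CeilingLine, scope: Scope, levels,
               corner: Corner = "upper-left") -> BottleneckTable:
    """Invert the ceiling line: the predictor level at which the ceiling
    reaches each target outcome level.

    For the upper-left corner the requirement reads "X at least this";
    for the upper-right corner, "X at most this".
    """
    if line.slope == 0.0:
        raise FlatCeilingError("no bottleneck: ceiling flat")
    levels = np.asarray(levels, dtype=float)
    required = (levels - line.intercept) / line.slope
    direction = "at-least" if corner == "upper-left" else "at-most"
    return BottleneckTable(levels=levels, required=required, direction=direction)


def empty_zone_oracle(data: XYDataset, resolution: int = 1000) -> float:
    """Brute-force rasterized empty-zone fraction, for verification only.

    The scope is divided into ``resolution x resolution`` cells; a cell
    center (u, v) counts as empty when no data point has ``x <= u`` and
    ``y >= v``. The returned fraction converges to the CE-FDH effect at
    rate O(1/resolution).
    """
    if resolution < 50:
        raise ValueError("resolution must be at least 50")
    scope = data.scope()
    r = int(resolution)
    u = scope.x_min + (np.arange(r) + 0.5) * (scope.x_max - scope.x_min) / r
    v = scope.y_min + (np.arange(r) + 0.5) * (scope.y_max - scope.y_min) / r
    # per column u: highest y among points with x <= u (-inf if none)
    covered = data.xs[:, None] <= u[None, :]
    col_top = np.where(covered, data.ys[:, None], -np.inf).max(axis=0)
    # cell (u, v) is empty iff v > every y reachable at x <= u
    empty_per_col = np.sum(v[None, :] > col_top[:, None], axis=1)
    return float(empty_per_col.sum()) / (r * r)
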