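"""Concentration curves and the concentration index.

The concentration index C summarizes socioeconomic-related inequality in a
health variable h over a population ranked from poorest to richest. Three
equivalent routes are implemented:

* from the concentration curve, ``C = 1 - 2 * integral of L_h(p)``;
* the discrete form ``C = 2/(N*mu) * sum(h_i * r_i) - 1 - 1/N`` with
  equal-weight ranks ``r_i = i/N``;
* the covariance form ``C = (2/mu) * cov(h, r)`` with weighted fractional
  ranks, which is the computational workhorse for weighted survey data.

With equal weights and the endpoint rank convention the discrete and
covariance forms agree to machine precision (an algebraic identity); the
curve form agrees with both to within the 1/N trapezoid discretization.

C is negative when h is concentrated among the poor (the curve lies above
the 45-degree diagonal), positive when concentrated among the rich, and
bounded in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RankedHealthSeries",
    "ConcentrationCurve",
    "ConcentrationResult",
    "fractional_ranks",
    "concentration_curve",
    "ci_from_curve",
    "ci_discrete",
    "ci_covariance",
    "ci_standard_error",
    "classify_direction",
    "significance_stars",
    "wagstaff_normalized",
    "erreygers_corrected",
    "analyze_series",
]

RankConvention = Literal["endpoint", "midpoint"]


@dataclass
class RankedHealthSeries:
    """A health variable ordered poorest -> richest with design weights.

    ``h`` must be nonnegative (binary for all the MCH indicators this
    package targets); ``fractional_rank`` lies in (0, 1] under the endpoint
    convention; ``weight`` are positive design weights on an arbitrary
    common scale.
    """

    h: np.ndarray
    fractional_rank: np.ndarray
    weight: np.ndarray
    mu: float = field(init=False)
    N: int = field(init=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.fractional_rank = np.asarray(self.fractional_rank, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.h.shape != self.fractional_rank.shape or self.h.shape != self.weight.shape:
            raise ValueError("h, fractional_rank and weight must have equal length")
        if np.any(self.weight <= 0):
            bad = int(np.argmax(self.weight <= 0))
            raise ValueError(f"nonpositive weight at index {bad}")
        if np.any(self.h < 0):
            bad = int(np.argmax(self.h < 0))
            raise ValueError(f"negative health value at index {bad}")
        self.N = int(self.h.size)
        self.mu = float(np.average(self.h, weights=self.weight)) if self.N else math.nan

    @classmethod
    def from_ordered(
        cls,
        h: Sequence[float],
        weights: Sequence[float] | None = None,
        convention: RankConvention = "endpoint",
    ) -> "RankedHealthSeries":
        """Build a series from values already sorted poorest -> richest."""
        h = np.asarray(h, dtype=float)
        w = np.ones_like(h) if weights is None else np.asarray(weights, dtype=float)
        r = fractional_ranks(w, convention=convention)
        return cls(h=h, fractional_rank=r, weight=w)


@dataclass(frozen=True)
class ConcentrationCurve:
    """Piecewise-linear concentration curve L_h(p).

    ``p`` is the cumulative population (weight) fraction walking units from
    poorest to richest; ``L`` the cumulative share of total h. The curve
    starts at (0, 0) and ends at (1, 1) and is nondecreasing for h >= 0.
    """

    p: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "L", np.asarray(self.L, dtype=float))


@dataclass(frozen=True)
class ConcentrationResult:
    """Concentration index estimate with inference and direction."""

    C: float
    se: float
    p_value: float
    method: str
    direction: str
    N: int
    mu: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def fractional_ranks(
    weights: Sequence[float], convention: RankConvention = "endpoint"
) -> np.ndarray:
    """Weighted fractional ranks for units ordered poorest -> richest.

    The default endpoint convention is ``r_i = (sum of w_j, j<=i) / W``,
    which reduces to ``r_i = i/N`` for equal weights. The midpoint
    convention ``r_i = (cum_before_i + w_i/2) / W`` is the common survey
    alternative; it does NOT reduce to i/N on small samples.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return w.copy()
    if np.any(w <= 0):
        bad = int(np.argmax(w <= 0))
        raise ValueError(f"nonpositive weight at index {bad}")
    cum = np.cumsum(w)
    W = cum[-1]
    if convention == "endpoint":
        return cum / W
    if convention == "midpoint":
        return (cum - w / 2.0) / W
    raise ValueError(f"unknown rank convention {convention!r}")


def concentration_curve(
    series: RankedHealthSeries, grid: np.ndarray | None = None
) -> ConcentrationCurve:
    """Concentration curve of a ranked series.

    Walks units poorest -> richest accumulating weight fraction on the x
    axis and share of total h on the y axis; endpoints (0,0) and (1,1) are
    appended. If ``grid`` is given, the piecewise-linear curve is evaluated
    on that p-grid instead of returning the native breakpoints.
    """
    if not (series.mu > 0):
        raise ValueError("concentration curve undefined: weighted mean of h is zero")
    cum_w = np.cumsum(series.weight)
    cum_h = np.cumsum(series.weight * series.h)
    p = np.concatenate(([0.0], cum_w / cum_w[-1]))
    L = np.concatenate(([0.0], cum_h / cum_h[-1]))
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        L = np.interp(grid, p, L)
        p = grid
    return ConcentrationCurve(p=p, L=L)


def ci_from_curve(curve: ConcentrationCurve) -> float:
    """Concentration index as one minus twice the area under the curve."""
    return 1.0 - 2.0 * float(np.trapezoid(curve.L, curve.p))


def ci_discrete(h: Sequence[float]) -> float:
    """Discrete-form concentration index for equal-weight data.

    Evaluates ``C = 2/(N*mu) * sum(h_i * i/N) - 1 - 1/N`` with units
    already ordered poorest (i=1) -> richest (i=N).
    """
    h = np.asarray(h, dtype=float)
    N = h.size
    mu = h.mean()
    if not (mu > 0):
        raise ValueError("concentration index undefined: mean of h is zero")
    r = np.arange(1, N + 1, dtype=float) / N
    return float(2.0 / (N * mu) * np.dot(h, r) - 1.0 - 1.0 / N)


def ci_covariance(series: RankedHealthSeries) -> float:
    """Covariance-form concentration index ``C = (2/mu) * cov_w(h, r)``.

    The covariance is the weighted population covariance (total-weight
    denominator), the convention under which this equals the discrete form
    exactly for equal weights with endpoint ranks.
    """
    if not (series.mu > 0):
        raise ValueError("concentration index undefined: weighted mean of h is zero")
    w = series.weight
    W = w.sum()
    r_bar = float(np.average(series.fractional_rank, weights=w))
    cov = float(np.sum(w * (series.h - series.mu) * (series.fractional_rank - r_bar)) / W)
    return 2.0 / series.mu * cov


def ci_standard_error(
    series: RankedHealthSeries,
    method: Literal["analytic", "bootstrap"] = "analytic",
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Standard error and two-sided p-value for the concentration index.

    The analytic path runs the "convenient regression": the transformed
    variable ``2 * var_w(r) * h_i / mu`` is regressed on the fractional
    rank by weighted least squares; the slope equals C and its
    heteroskedasticity-robust (HC1) standard error is the SE of C. The
    analytic path requires N >= 30. The bootstrap path resamples units
    (with their weights) B times, recomputing ranks and C per replicate.
    p-values use the normal reference in both cases.
    """
    if not (series.mu > 0):
        raise ValueError("standard error undefined: weighted mean of h is zero")
    C = ci_covariance(series)
    if method == "analytic":
        if series.N < 30:
            raise ValueError(
                f"analytic SE requires N >= 30 (got N={series.N}); use the bootstrap"
            )
        se = _convenient_regression_se(series)
    elif method == "bootstrap":
        if B < 100:
            import warnings

            warnings.warn(
                f"bootstrap with B={B} < 100 replicates is unreliable", stacklevel=2
            )
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        reps = np.empty(B)
        idx_all = np.arange(series.N)
        for b in range(B):
            idx = rng.choice(idx_all, size=series.N, replace=True)
            idx.sort()  # preserve poorest -> richest order of the resample
            sub = RankedHealthSeries(
                h=series.h[idx],
                fractional_rank=fractional_ranks(series.weight[idx]),
                weight=series.weight[idx],
            )
            reps[b] = ci_covariance(sub) if sub.mu > 0 else 0.0
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown SE method {method!r}")
    if se == 0.0:
        p = 1.0 if C == 0.0 else 0.0
    else:
        p = 2.0 * float(stats.norm.sf(abs(C) / se))
    return se, p


def _convenient_regression_se(series: RankedHealthSeries) -> float:
    """HC1 slope SE of the convenient regression of 2*var(r)*h/mu on r."""
    import statsmodels.api as sm

    w = series.weight
    r = series.fractional_rank
    var_r = float(np.average((r - np.average(r, weights=w)) ** 2, weights=w))
    y = 2.0 * var_r * series.h / series.mu
    X = sm.add_constant(r)
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
    return float(fit.bse[1])


def classify_direction(C: float, p_value: float, alpha: float = 0.1) -> str:
    """Direction label: pro-poor (C<0), pro-rich (C>0), or equal.

    'equal' is returned when the index is not significant at the loosest
    star threshold (p >= alpha, default 0.1) or exactly zero.
    """
    if p_value >= alpha or C == 0.0:
        return "equal"
    return "pro-poor" if C < 0 else "pro-rich"


def significance_stars(p_value: float) -> str:
    """Star ladder: *** p<0.01, ** p<0.05, * p<0.1, '' otherwise."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value < 0.01:
        return "***"
    if p_value < 0.05:
        return "**"
    if p_value < 0.1:
        return "*"
    return ""


def wagstaff_normalized(C: float, mu: float) -> float:
    """Wagstaff normalization C/(1 - mu) for a binary health variable.

    Rescales the plain index so its attainable range is [-1, 1] whatever
    the prevalence. Opt-in: equity tables report the plain C by default.
    """
    if not (0.0 < mu < 1.0):
        raise ValueError("Wagstaff normalization requires prevalence in (0, 1)")
    return C / (1.0 - mu)


def erreygers_corrected(C: float, mu: float) -> float:
    """Erreygers correction 4*mu*C for a binary health variable.

    Satisfies the mirror property between attainment (h) and shortfall
    (1-h). Opt-in post-correction, never the default.
    """
    if not (0.0 <= mu <= 1.0):
        raise ValueError("Erreygers correction requires prevalence in [0, 1]")
    return 4.0 * mu * C


def analyze_series(
    series: RankedHealthSeries,
    se_method: Literal["analytic", "bootstrap"] = "analytic",
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ConcentrationResult:
    """Full concentration analysis: C, SE, p-value, stars and direction."""
    C = ci_covariance(series)
    se, p = ci_standard_error(series, method=se_method, B=B, rng=rng)
    return ConcentrationResult(
        C=C,
        se=se,
        p_value=p,
        method="covariance",
        direction=classify_direction(C, p),
        N=series.N,
        mu=series.mu,
    )
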