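"""Ricker map, segment fitting, and per-segment information criteria.

The Ricker map ``N_{t+1} = N_t * exp(r * (1 - N_t / K))`` is the population
model underlying the whole toolkit: ``r`` is the per-step intrinsic growth
rate and ``K`` the carrying capacity (in the units of the abundance data,
which the toolkit treats as opaque — individuals, trap counts, hectares).
Observed series are modelled as the deterministic map plus additive Gaussian
error with standard deviation ``sigma``.

A *segment* is a contiguous span of the series fitted with a single (r, K)
pair by nonlinear least squares on its transition pairs
``(N_t, N_{t+1})``.  Segments are scored with a Gaussian least-squares
information criterion (AIC or small-sample AICc); the break-point engine sums
these scores across the segments of a candidate partition.

Bookkeeping conventions
-----------------------
A segment covering years ``[a, b]`` uses the transition pairs
``a->a+1, ..., b-1->b`` (``n_obs = b - a``).  Consecutive segments share the
boundary year but no transition pair, so the per-segment ``n_obs`` sum to
the total number of transitions in the series.  A segment's score is

    ``n_obs * ln(rss / n_obs) + 2k + 2k(k+1) / (n_pts - k - 1)``

with ``k = 3`` estimated quantities (r, K, residual variance) and
``n_pts = n_obs + 1`` the data points the segment spans.  The likelihood
term runs over the transitions so that its per-observation contributions
sum identically across competing partitions of the same series (counting
the shared boundary point twice would make summed scores depend on the
measurement units); the correction uses the points informing the segment.
Under AICc the correction requires ``n_pts >= k + 2``, i.e. at least four
transition pairs per segment, and the break-point engine drops combinations
whose leading block is too short for this.  The harshness of the correction
as ``n_pts`` approaches ``k + 1`` is what stops near-interpolating
mini-segments (whose fitted variance collapses toward zero) from swamping
the ranking.  The textbook formulas with caller-chosen ``n`` and ``k`` are
exposed as :func:`aic_least_squares` / :func:`aicc_least_squares`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, FitError, SeriesError

__all__ = [
    "MIN_SEGMENT_POINTS",
    "PopulationTimeSeries",
    "RickerParams",
    "SegmentFit",
    "predict_next",
    "fit_ricker",
    "segment_ic",
    "aic_least_squares",
    "aicc_least_squares",
]

#: Smallest number of sequential data points a fitted segment may contain.
MIN_SEGMENT_POINTS = 4

#: Quantities counted in the engine's per-segment IC: r, K, residual variance.
IC_N_PARAMS = 3

# Upper clip on the Ricker exponent during optimisation only; keeps trial
# steps with wild r from overflowing exp() while leaving any plausible
# parameter region untouched.
_EXP_MAX = 500.0

# Relative scale of the residual floor guarding ln(rss) on noiseless data.
_RSS_FLOOR_REL = 1e-8


@dataclasses.dataclass(frozen=True)
class RickerParams:
    """Parameters of one dynamic rule: growth rate, carrying capacity, noise.

    ``sigma`` is the residual standard deviation of the additive error term,
    in the same units as the abundances; it is 0.0 for purely deterministic
    parameter sets.
    """

    r: float
    k: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r) and np.isfinite(self.k)):
            raise ValueError("r and K must be finite")
        if self.k <= 0:
            raise ValueError(f"carrying capacity must be positive, got K={self.k}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


@dataclasses.dataclass(frozen=True)
class PopulationTimeSeries:
    """One abundance observation per consecutive year.

    Years must increase in steps of exactly one (the model links each year to
    the next; a gap would silently splice unrelated transitions) and all
    abundances must be finite and strictly positive.
    """

    years: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        abund = np.asarray(self.abundances, dtype=np.float64)
        if years.ndim != 1 or abund.ndim != 1 or years.size != abund.size:
            raise SeriesError("years and abundances must be 1-D and equally long")
        if years.size < MIN_SEGMENT_POINTS:
            raise SeriesError(
                f"series has {years.size} points; at least "
                f"{MIN_SEGMENT_POINTS} are required to fit anything"
            )
        steps = np.diff(years)
        if np.any(steps != 1):
            bad = int(years[np.argmax(steps != 1)])
            raise SeriesError(
                f"years must be consecutive; gap or duplicate after year {bad}"
            )
        if not np.all(np.isfinite(abund)):
            raise SeriesError("abundances must all be finite")
        if np.any(abund <= 0):
            bad = int(years[np.argmax(abund <= 0)])
            raise SeriesError(f"non-positive abundance at year {bad}")
        years.setflags(write=False)
        abund.setflags(write=False)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "abundances", abund)

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def index_of(self, year: int) -> int:
        if not self.first_year <= year <= self.last_year:
            raise SeriesError(
                f"year {year} outside series span "
                f"{self.first_year}-{self.last_year}"
            )
        return int(year - self.first_year)


def predict_next(n_t, params: RickerParams):
    """Deterministic Ricker expectation of next year's abundance.

    Accepts a scalar or array of current abundances; no noise is added.
    """
    n_t = np.asarray(n_t, dtype=np.float64)
    if not np.all(np.isfinite(n_t)) or np.any(n_t <= 0):
        raise ValueError("abundance must be finite and positive")
    out = n_t * np.exp(params.r * (1.0 - n_t / params.k))
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class SegmentFit:
    """Least-squares Ricker fit of one contiguous segment.

    ``n_obs`` counts the fitted transition pairs; the segment spans
    ``n_obs + 1`` data points.  ``ic`` is filled in by the break-point
    engine once a criterion is chosen.
    """

    start_year: int
    end_year: int
    params: RickerParams
    param_se: tuple[float, float]  # (se_r, se_k)
    rss: float
    n_obs: int
    converged: bool
    scale: float  # mean abundance of the segment, for the rss floor
    ic: float = math.nan


def _residuals(theta: np.ndarray, n_from: np.ndarray, n_to: np.ndarray) -> np.ndarray:
    r, k = theta
    expo = np.minimum(r * (1.0 - n_from / k), _EXP_MAX)
    return n_to - n_from * np.exp(expo)


def _jacobian(theta: np.ndarray, n_from: np.ndarray, n_to: np.ndarray) -> np.ndarray:
    r, k = theta
    expo = np.minimum(r * (1.0 - n_from / k), _EXP_MAX)
    pred = n_from * np.exp(expo)
    d_r = -pred * (1.0 - n_from / k)
    d_k = -pred * r * n_from / k**2
    return np.column_stack([d_r, d_k])


def fit_ricker(
    series: PopulationTimeSeries, start_year: int, end_year: int
) -> SegmentFit:
    """Fit r and K to the segment ``[start_year, end_year]`` (inclusive).

    Minimises the sum of squared one-step prediction errors over the
    segment's transition pairs with a bounded trust-region reflective solver
    and an analytic Jacobian.  Starting values are r = 1 and K = the mean
    segment abundance; K is bounded below by a vanishing fraction of that
    mean to exclude the sign-flip degeneracy, r is unbounded.

    Standard errors come from the Jacobian covariance at the solution scaled
    by ``rss / (n_obs - 2)``.  A series sitting identically at its carrying
    capacity makes r unidentifiable (every r fits perfectly); this surfaces
    as a singular Jacobian and infinite standard errors rather than an error.
    """
    i0 = series.index_of(start_year)
    i1 = series.index_of(end_year)
    n_obs = i1 - i0
    if n_obs < MIN_SEGMENT_POINTS - 1:
        raise FitError(
            f"segment {start_year}-{end_year} has {n_obs} transition pairs; "
            f"need at least {MIN_SEGMENT_POINTS - 1}"
        )
    n_from = series.abundances[i0:i1]
    n_to = series.abundances[i0 + 1 : i1 + 1]
    scale = float(np.mean(series.abundances[i0 : i1 + 1]))

    x0 = np.array([1.0, scale])
    res = least_squares(
        _residuals,
        x0,
        jac=_jacobian,
        bounds=([-np.inf, 1e-9 * scale], [np.inf, np.inf]),
        args=(n_from, n_to),
        method="trf",
        x_scale="jac",
    )
    r_hat, k_hat = res.x
    rss = float(np.dot(res.fun, res.fun))
    converged = bool(res.success) and np.all(np.isfinite(res.x))

    dof = n_obs - 2
    if dof > 0 and converged:
        jtj = res.jac.T @ res.jac
        try:
            cov = (rss / dof) * np.linalg.inv(jtj)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.array([np.inf, np.inf])
        if not np.all(np.isfinite(se)):
            se = np.array([np.inf, np.inf])
    else:
        se = np.array([np.inf, np.inf])

    sigma = math.sqrt(rss / n_obs)
    return SegmentFit(
        start_year=int(start_year),
        end_year=int(end_year),
        params=RickerParams(r=float(r_hat), k=float(k_hat), sigma=sigma),
        param_se=(float(se[0]), float(se[1])),
        rss=rss,
        n_obs=n_obs,
        converged=converged,
        scale=scale,
    )


def aic_least_squares(rss: float, n: int, k: int = 3) -> float:
    """Gaussian least-squares AIC: ``n * ln(rss / n) + 2k``."""
    if rss < 0 or n <= 0:
        raise ValueError("rss must be non-negative and n positive")
    return n * math.log(rss / n) + 2 * k


def aicc_least_squares(rss: float, n: int, k: int = 3) -> float:
    """AIC with the small-sample correction ``2k(k+1) / (n - k - 1)``.

    Raises :class:`ConfigurationError` when ``n - k - 1 <= 0``, where the
    correction is undefined; callers should enlarge the segment or fall back
    to plain AIC.
    """
    if n - k - 1 <= 0:
        raise ConfigurationError(
            f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0); "
            "increase the minimum segment size or use AIC"
        )
    return aic_least_squares(rss, n, k) + 2 * k * (k + 1) / (n - k - 1)


def _rss_floor(fit: SegmentFit) -> float:
    return fit.n_obs * (_RSS_FLOOR_REL * fit.scale) ** 2


def segment_ic(fit: SegmentFit, criterion: str = "AICc") -> float:
    """Information-criterion score of one fitted segment (lower is better).

    Computes the Gaussian least-squares score over the segment's ``n_obs``
    transition pairs with ``k = 3`` estimated quantities; under AICc the
    small-sample correction is taken on the ``n_obs + 1`` data points the
    segment spans (see module notes for why the two counts differ).  A
    scale-relative floor on the residual sum of squares keeps the log term
    finite on (near-)noiseless segments.  Under AICc a segment spanning
    only four points (three transition pairs) is unscorable
    (``n_pts - k - 1 = 0``) and raises
    :class:`~shiftdetect.errors.ConfigurationError`.
    """
    if not fit.converged:
        raise ValueError("cannot score a non-converged segment fit")
    rss = max(fit.rss, _rss_floor(fit))
    k = IC_N_PARAMS
    aic = aic_least_squares(rss, fit.n_obs, k=k)
    if criterion == "AIC":
        return aic
    if criterion == "AICc":
        n_pts = fit.n_obs + 1
        if n_pts - k - 1 <= 0:
            raise ConfigurationError(
                f"AICc undefined for a segment spanning {n_pts} points; "
                "segments need at least 4 transition pairs under AICc"
            )
        return aic + 2 * k * (k + 1) / (n_pts - k - 1)
    raise ConfigurationError(f"unknown criterion {criterion!r}; use 'AICc' or 'AIC'")


def deterministic_trajectory(
    n1: float, params: RickerParams, length: int
) -> np.ndarray:
    """Iterate the noiseless Ricker map ``length`` steps from ``n1``."""
    out = np.empty(length, dtype=np.float64)
    out[0] = n1
    for t in range(1, length):
        out[t] = predict_next(out[t - 1], params)
    return out


def transition_pairs(
    series: PopulationTimeSeries, start_year: int, end_year: int
) -> Iterable[tuple[float, float]]:
    """Yield the (N_t, N_{t+1}) pairs a segment fit would use (diagnostics)."""
    i0 = series.index_of(start_year)
    i1 = series.index_of(end_year)
    for i in range(i0, i1):
        yield float(series.abundances[i]), float(series.abundances[i + 1])
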