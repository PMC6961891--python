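"""Exhaustive break-point enumeration, scoring, and Akaike weighting.

A *break-point combination* is a partition of the series into contiguous
segments, written as the set of years after which a new dynamic rule starts
("break after year y").  The engine enumerates every combination whose
partition blocks all hold at least ``min_segment`` data points, fits each
segment independently (see :mod:`shiftdetect.ricker`), sums the per-segment
information criteria, and converts the summed scores into Akaike weights:

    w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2),   delta_i = IC_i - min IC

Combinations within ``equivalence_delta`` (default 2) IC units of the best
form the *equivalence set* of effectively indistinguishable partitions.  The
*break weight* of a year is the summed weight of every retained combination
containing it — the relative-variable-importance reading of model weights —
and is classified as supported (> 0.8), erroneous (< 0.2), or ambiguous.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .config import DsdConfig
from .errors import SeriesError
from .ricker import PopulationTimeSeries, SegmentFit, fit_ricker, segment_ic

__all__ = [
    "BreakCombination",
    "CandidateRanking",
    "enumerate_combinations",
    "score_combination",
    "rank_combinations",
    "akaike_weights",
    "break_weights",
    "classify_break",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BreakCombination:
    """One scored partition: its break years, segment fits, summed IC."""

    breaks: tuple[int, ...]
    segment_fits: tuple[SegmentFit, ...]
    total_ic: float
    scorable: bool = True
    failure: str | None = None

    @property
    def n_breaks(self) -> int:
        return len(self.breaks)


@dataclasses.dataclass(frozen=True)
class CandidateRanking:
    """All retained combinations, ascending by summed IC, with weights.

    ``delta_ic`` and ``akaike_weight`` align with ``combinations``;
    ``equivalence_set`` holds the combinations within ``equivalence_delta``
    of the best; ``break_weights`` maps each break year occurring in a
    retained combination to its summed weight.
    """

    combinations: tuple[BreakCombination, ...]
    delta_ic: tuple[float, ...]
    akaike_weight: tuple[float, ...]
    equivalence_set: tuple[BreakCombination, ...]
    break_weights: dict[int, float]
    criterion: str
    n_enumerated: int
    n_unscorable: int
    n_pruned: int

    @property
    def best(self) -> BreakCombination:
        return self.combinations[0]

    def equivalence_break_sets(self) -> list[tuple[int, ...]]:
        return [c.breaks for c in self.equivalence_set]


def enumerate_combinations(
    n_points: int,
    min_segment: int = 4,
    max_breaks: int | None = None,
) -> list[tuple[int, ...]]:
    """Every admissible break set for a series of ``n_points`` points.

    Breaks are 1-based positions ("after point p"); a break set is
    admissible when every resulting partition block holds at least
    ``min_segment`` points.  Includes the empty set.  Ordered by number of
    breaks, then lexicographically.
    """
    if n_points < min_segment:
        raise SeriesError(
            f"series of {n_points} points is shorter than one minimum "
            f"segment ({min_segment})"
        )
    results: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...], start: int) -> None:
        # every cut keeps the tail >= min_segment, so the prefix is always
        # a complete admissible partition
        results.append(prefix)
        if max_breaks is not None and len(prefix) >= max_breaks:
            return
        for cut in range(start + min_segment, n_points - min_segment + 1):
            extend(prefix + (cut,), cut)

    extend((), 0)
    results.sort(key=lambda b: (len(b), b))
    return results


def _segment_spans(
    series: PopulationTimeSeries, breaks: Sequence[int]
) -> list[tuple[int, int]]:
    """Fitted segment year-spans for a break set given in years.

    Consecutive segments share the boundary year: a break after year y ends
    one span at y and starts the next at y, so every transition pair is used
    exactly once.
    """
    bounds = [series.first_year, *sorted(breaks), series.last_year]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def score_combination(
    series: PopulationTimeSeries,
    breaks: Iterable[int],
    criterion: str = "AICc",
    _fit_cache: dict[tuple[int, int], SegmentFit] | None = None,
) -> BreakCombination:
    """Fit every segment of one break set (years) and sum the IC scores.

    A combination containing any non-converged segment is returned with
    ``scorable=False`` and a failure reason; the ranking step drops it.
    """
    breaks = tuple(sorted(int(b) for b in breaks))
    fits: list[SegmentFit] = []
    for start, end in _segment_spans(series, breaks):
        key = (start, end)
        fit = _fit_cache.get(key) if _fit_cache is not None else None
        if fit is None:
            fit = fit_ricker(series, start, end)
            if _fit_cache is not None:
                _fit_cache[key] = fit
        fits.append(fit)

    bad = [f for f in fits if not f.converged]
    if bad:
        reason = "non-converged segment(s): " + ", ".join(
            f"{f.start_year}-{f.end_year}" for f in bad
        )
        return BreakCombination(breaks, tuple(fits), math.inf, False, reason)

    scored = [
        dataclasses.replace(f, ic=segment_ic(f, criterion)) for f in fits
    ]
    total = float(sum(f.ic for f in scored))
    if not math.isfinite(total):
        return BreakCombination(
            breaks, tuple(scored), math.inf, False, "non-finite summed IC"
        )
    return BreakCombination(breaks, tuple(scored), total)


def akaike_weights(scores: Sequence[float]) -> np.ndarray:
    """Akaike weights of a list of IC scores.

    Non-finite scores receive weight 0 and are excluded from the
    normalisation; at least one finite score is required.
    """
    scores_arr = np.asarray(scores, dtype=np.float64)
    finite = np.isfinite(scores_arr)
    if not finite.any():
        raise ValueError("akaike_weights needs at least one finite score")
    w = np.zeros_like(scores_arr)
    rel = np.exp(-(scores_arr[finite] - scores_arr[finite].min()) / 2.0)
    w[finite] = rel / rel.sum()
    return w


def break_weights(
    combinations: Sequence[BreakCombination], weights: Sequence[float]
) -> dict[int, float]:
    """Summed weight of every break year over the combinations containing it."""
    out: dict[int, float] = {}
    for combo, w in zip(combinations, weights):
        for year in combo.breaks:
            out[year] = out.get(year, 0.0) + float(w)
    return dict(sorted(out.items()))


def classify_break(
    weight: float, supported: float = 0.8, erroneous: float = 0.2
) -> str:
    """Label a break weight: supported (>0.8), erroneous (<0.2), ambiguous."""
    if not 0.0 <= weight <= 1.0 + 1e-9:
        raise ValueError(f"break weight must lie in [0, 1], got {weight}")
    if weight > supported:
        return "supported"
    if weight < erroneous:
        return "erroneous"
    return "ambiguous"


def rank_combinations(
    series: PopulationTimeSeries, config: DsdConfig | None = None
) -> CandidateRanking:
    """Run the full detector on one series.

    Enumerates all admissible break sets, scores them, computes Akaike
    weights over every scorable combination, prunes combinations below
    ``prune_threshold`` weight (equivalence-set members are always kept),
    renormalises the retained weights, and reports per-break weights.

    Ties in total IC rank the combination with fewer breaks first, then
    lexicographically by break years, so output is deterministic.
    """
    config = config or DsdConfig()
    position_sets = enumerate_combinations(
        len(series), config.min_segment, config.max_breaks
    )
    first = series.first_year
    cache: dict[tuple[int, int], SegmentFit] = {}
    scored: list[BreakCombination] = []
    n_unscorable = 0
    # Under AICc the leading segment must span >= 5 points (4 transition
    # pairs), else its small-sample correction is undefined; such
    # combinations are structurally unscorable.
    min_lead = 5 if config.criterion == "AICc" else 0
    for positions in position_sets:
        if positions and positions[0] < min_lead:
            n_unscorable += 1
            logger.debug(
                "combination %s unscorable: leading segment spans %d points "
                "(< %d required under AICc)", positions, positions[0], min_lead,
            )
            continue
        years = tuple(first + p - 1 for p in positions)
        combo = score_combination(series, years, config.criterion, cache)
        if combo.scorable:
            scored.append(combo)
        else:
            n_unscorable += 1
            logger.warning("dropping combination %s: %s", years, combo.failure)
    if not scored:
        raise SeriesError("no break-point combination could be scored")

    scored.sort(key=lambda c: (c.total_ic, c.n_breaks, c.breaks))
    best_ic = scored[0].total_ic
    weights = akaike_weights([c.total_ic for c in scored])
    deltas = [c.total_ic - best_ic for c in scored]

    keep = [
        i
        for i in range(len(scored))
        if weights[i] >= config.prune_threshold
        or deltas[i] < config.equivalence_delta
    ]
    n_pruned = len(scored) - len(keep)
    kept = [scored[i] for i in keep]
    kept_w = np.array([weights[i] for i in keep])
    kept_d = [deltas[i] for i in keep]
    if config.renormalize and kept_w.sum() > 0:
        kept_w = kept_w / kept_w.sum()

    equivalence = tuple(
        c for c, d in zip(kept, kept_d) if d < config.equivalence_delta
    )
    return CandidateRanking(
        combinations=tuple(kept),
        delta_ic=tuple(kept_d),
        akaike_weight=tuple(float(w) for w in kept_w),
        equivalence_set=equivalence,
        break_weights=break_weights(kept, kept_w),
        criterion=config.criterion,
        n_enumerated=len(position_sets),
        n_unscorable=n_unscorable,
        n_pruned=n_pruned,
    )
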