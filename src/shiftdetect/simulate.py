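"""Ricker time-series simulation with step changes in (r, K).

The generator emulates the method's reference benchmark conditions:
populations initialised away from equilibrium (N1 = 3000 around a
carrying capacity of K = 2000, so fits are informed by a transient), iterated
with the deterministic Ricker map, perturbed each step by multiplicative
Gaussian noise of relative standard deviation ``tau``, and subjected to
abrupt percent changes of r and K at specified or randomly placed break
positions.  Each break multiplies the *current* parameter values by
``1 +/- delta`` with the sign drawn at random per break and per parameter,
so successive shifts compound.

Break positions use the same "after point p" semantics as the detector, and
random placements are drawn uniformly from the admissible break sets (every
partition block at least ``min_segment`` points), matching the constraint the
detector itself enumerates under.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .engine import enumerate_combinations
from .errors import InfeasibleScenarioError
from .ricker import PopulationTimeSeries, RickerParams, predict_next

__all__ = [
    "SimulationScenario",
    "SimulatedSeries",
    "simulate_series",
    "random_break_locations",
    "make_scenario_grid",
    "BASE_SCENARIO",
]

#: Values every grid family holds fixed unless it is the one being varied.
BASE = dict(
    n1=3000.0,
    k0=2000.0,
    r0=2.0,
    series_length=20,
    delta_r=0.25,
    delta_k=0.75,
    tau=0.02,
)

_R0_GRID = (0.5, 1.0, 1.5, 2.0)
_DELTA_GRID = (0.0, 0.10, 0.25, 0.50, 0.75)
_TAU_GRID = (0.01, 0.02, 0.05, 0.10, 0.15)
_LENGTH_GRID = (15, 20, 25, 30)


@dataclasses.dataclass(frozen=True)
class SimulationScenario:
    """Full parameterisation of one simulated dataset.

    ``delta_r`` and ``delta_k`` are unsigned fractional changes applied at
    each break with a randomly drawn sign; ``tau`` is the noise standard
    deviation as a fraction of the expected population size.  ``breaks`` are
    1-based positions ("after point p"); leave empty and draw them with
    :func:`random_break_locations` for the benchmark design.
    """

    n1: float = BASE["n1"]
    k0: float = BASE["k0"]
    r0: float = BASE["r0"]
    series_length: int = BASE["series_length"]
    breaks: tuple[int, ...] = ()
    delta_r: float = BASE["delta_r"]
    delta_k: float = BASE["delta_k"]
    tau: float = BASE["tau"]
    seed: int | None = None
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.k0 <= 0:
            raise ValueError("n1 and k0 must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.series_length < 4:
            raise ValueError("series_length must allow at least one segment")
        breaks = tuple(sorted(int(b) for b in self.breaks))
        object.__setattr__(self, "breaks", breaks)
        bounds = (0, *breaks, self.series_length)
        blocks = np.diff(bounds)
        if breaks and blocks.min() < 4:
            raise InfeasibleScenarioError(
                f"breaks {breaks} leave a block shorter than 4 points in a "
                f"{self.series_length}-point series"
            )


BASE_SCENARIO = SimulationScenario(scenario_id="base")


@dataclasses.dataclass(frozen=True)
class SimulatedSeries:
    """A simulated series plus its ground truth."""

    series: PopulationTimeSeries
    true_breaks: tuple[int, ...]  # break years (series years start at 1)
    regimes: tuple[RickerParams, ...]  # (r, K) per regime, in order
    scenario: SimulationScenario

    def to_ground_truth(self) -> dict:
        return {
            "scenario": dataclasses.asdict(self.scenario),
            "true_breaks": list(self.true_breaks),
            "regimes": [{"r": p.r, "k": p.k} for p in self.regimes],
        }


def _draw_sign(rng: np.random.Generator) -> float:
    return 1.0 if rng.random() < 0.5 else -1.0


def simulate_series(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> SimulatedSeries:
    """Generate one series under ``scenario``; reproducible from its seed.

    The transition out of a break year is already governed by the shifted
    parameters — the same assignment convention the detector uses when it
    splits transition pairs between segments.  A multiplicative noise draw
    that would push the population non-positive is redrawn so the noise
    distribution is untruncated.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    r, k = scenario.r0, scenario.k0
    regimes = [RickerParams(r=r, k=k)]
    length = scenario.series_length
    breaks = set(scenario.breaks)

    abundances = np.empty(length, dtype=np.float64)
    abundances[0] = scenario.n1
    params = regimes[0]
    for p in range(1, length):
        if p in breaks:  # shift takes effect on the transition p -> p+1
            r = r * (1.0 + _draw_sign(rng) * scenario.delta_r)
            k = k * (1.0 + _draw_sign(rng) * scenario.delta_k)
            params = RickerParams(r=r, k=k)
            regimes.append(params)
        expected = predict_next(abundances[p - 1], params)
        if scenario.tau > 0:
            value = -1.0
            while value <= 0:
                value = expected * (1.0 + rng.normal(0.0, scenario.tau))
        else:
            value = expected
        abundances[p] = value

    series = PopulationTimeSeries(
        years=np.arange(1, length + 1), abundances=abundances
    )
    return SimulatedSeries(
        series=series,
        true_breaks=tuple(sorted(breaks)),
        regimes=tuple(regimes),
        scenario=scenario,
    )


def random_break_locations(
    series_length: int,
    n_breaks: int,
    min_segment: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[int, ...]:
    """Uniform draw from the admissible break sets of size ``n_breaks``.

    Raises :class:`InfeasibleScenarioError` when no placement exists (e.g.
    three breaks need at least four blocks of ``min_segment`` points).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_breaks == 0:
        return ()
    candidates = [
        b
        for b in enumerate_combinations(series_length, min_segment, n_breaks)
        if len(b) == n_breaks
    ]
    if not candidates:
        raise InfeasibleScenarioError(
            f"no admissible placement of {n_breaks} breaks in a "
            f"{series_length}-point series with min_segment={min_segment}"
        )
    return candidates[int(rng.integers(len(candidates)))]


def make_scenario_grid() -> list[SimulationScenario]:
    """The 94-scenario benchmark grid.

    Four families: starting r crossed with the percent-change grids for r
    and for K (40), noise level tau crossed with both change grids (50), and
    four series lengths (4).  Every non-varied field sits at its base value;
    the base parameter set therefore reappears in several families, exactly
    as the benchmark's scenario count tallies it.
    """
    grid: list[SimulationScenario] = []
    for r0 in _R0_GRID:
        for dr in _DELTA_GRID:
            grid.append(
                SimulationScenario(
                    r0=r0, delta_r=dr, scenario_id=f"r0={r0:g}_dr={dr:g}"
                )
            )
        for dk in _DELTA_GRID:
            grid.append(
                SimulationScenario(
                    r0=r0, delta_k=dk, scenario_id=f"r0={r0:g}_dk={dk:g}"
                )
            )
    for tau in _TAU_GRID:
        for dr in _DELTA_GRID:
            grid.append(
                SimulationScenario(
                    tau=tau, delta_r=dr, scenario_id=f"tau={tau:g}_dr={dr:g}"
                )
            )
        for dk in _DELTA_GRID:
            grid.append(
                SimulationScenario(
                    tau=tau, delta_k=dk, scenario_id=f"tau={tau:g}_dk={dk:g}"
                )
            )
    for length in _LENGTH_GRID:
        grid.append(
            SimulationScenario(series_length=length, scenario_id=f"len={length}")
        )
    return grid
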