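"""CSV ingestion and report assembly.

Input format: a two-column CSV of (year, abundance), header optional.  The
detector's contract is strict — consecutive years, no duplicates, strictly
positive abundances — and violations are hard errors naming the offending
year, because a silently spliced gap would corrupt every transition pair
downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DsdConfig
from .engine import CandidateRanking, classify_break, rank_combinations
from .errors import SeriesError
from .ricker import PopulationTimeSeries
from .simulate import SimulatedSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "write_simulated",
    "run_dsd",
    "report_to_text",
]

REPORT_SCHEMA_VERSION = "1.0"


def read_series_csv(path: str | Path) -> PopulationTimeSeries:
    """Read and validate a (year, abundance) CSV; header row optional."""
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise SeriesError(f"{path}: need two columns (year, abundance)")
    df = df.iloc[:, :2]
    # first row may be a header
    try:
        float(df.iloc[0, 0]), float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    try:
        years = df.iloc[:, 0].astype(float).to_numpy()
        abund = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise SeriesError(f"{path}: non-numeric cell in data rows") from exc
    if np.any(years != np.round(years)):
        raise SeriesError(f"{path}: years must be integers")
    order = np.argsort(years)
    years = years[order].astype(np.int64)
    abund = abund[order]

    dup = np.flatnonzero(np.diff(years) == 0)
    if dup.size:
        raise SeriesError(f"{path}: duplicate year {int(years[dup[0]])}")
    gap = np.flatnonzero(np.diff(years) > 1)
    if gap.size:
        missing = int(years[gap[0]]) + 1
        raise SeriesError(f"{path}: missing year {missing} (gaps not allowed)")
    if np.any(abund <= 0) or not np.all(np.isfinite(abund)):
        bad = int(years[np.argmax(~((abund > 0) & np.isfinite(abund)))])
        raise SeriesError(f"{path}: non-positive or non-finite abundance at year {bad}")
    return PopulationTimeSeries(years=years, abundances=abund)


def write_series_csv(
    series: PopulationTimeSeries, path: str | Path, header: bool = True
) -> None:
    df = pd.DataFrame({"year": series.years, "abundance": series.abundances})
    df.to_csv(path, index=False, header=header)


def write_simulated(sim: SimulatedSeries, stem: str | Path) -> tuple[Path, Path]:
    """Write a simulated series as CSV plus a JSON ground-truth sidecar."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".truth.json")
    write_series_csv(sim.series, csv_path)
    json_path.write_text(json.dumps(sim.to_ground_truth(), indent=2) + "\n")
    return csv_path, json_path


def _ranking_to_dict(ranking: CandidateRanking, config: DsdConfig) -> dict:
    equivalence = set(ranking.equivalence_break_sets())
    combos = [
        {
            "breaks": list(c.breaks),
            "total_ic": c.total_ic,
            "delta_ic": d,
            "weight": w,
            "in_equivalence_set": c.breaks in equivalence,
        }
        for c, d, w in zip(
            ranking.combinations, ranking.delta_ic, ranking.akaike_weight
        )
    ]
    weights = {
        str(year): {
            "weight": w,
            "label": classify_break(
                min(w, 1.0),
                config.supported_threshold,
                config.erroneous_threshold,
            ),
        }
        for year, w in ranking.break_weights.items()
    }
    segments = [
        {
            "start_year": f.start_year,
            "end_year": f.end_year,
            "r": f.params.r,
            "r_se": f.param_se[0],
            "k": f.params.k,
            "k_se": f.param_se[1],
            "sigma": f.params.sigma,
            "n_obs": f.n_obs,
            "ic": f.ic,
        }
        for f in ranking.best.segment_fits
    ]
    return {
        "combinations": combos,
        "break_weights": weights,
        "best_segments": segments,
    }


def run_dsd(series: PopulationTimeSeries, config: DsdConfig | None = None) -> dict:
    """Full analysis of one series, returned as a JSON-serialisable report."""
    config = config or DsdConfig()
    ranking = rank_combinations(series, config)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "series": {
            "n_points": len(series),
            "first_year": series.first_year,
            "last_year": series.last_year,
        },
        "criterion": ranking.criterion,
        "best": {
            "breaks": list(ranking.best.breaks),
            "total_ic": ranking.best.total_ic,
        },
        "n_enumerated": ranking.n_enumerated,
        "n_unscorable": ranking.n_unscorable,
        "n_pruned": ranking.n_pruned,
    }
    report.update(_ranking_to_dict(ranking, config))
    return report


def report_to_text(report: dict) -> str:
    """Human-readable summary of a :func:`run_dsd` report."""
    lines = []
    s = report["series"]
    lines.append(
        f"Series: {s['n_points']} points, years "
        f"{s['first_year']}-{s['last_year']}  (criterion: {report['criterion']})"
    )
    best = report["best"]
    label = (
        "no break" if not best["breaks"] else
        "break(s) after " + ", ".join(map(str, best["breaks"]))
    )
    lines.append(f"Best combination: {label}  (total IC {best['total_ic']:.2f})")
    lines.append(
        f"Candidates: {report['n_enumerated']} enumerated, "
        f"{report['n_unscorable']} unscorable, {report['n_pruned']} pruned"
    )
    lines.append("")
    lines.append("Equivalence set (delta IC < 2):")
    for c in report["combinations"]:
        if not c["in_equivalence_set"]:
            continue
        label = ",".join(map(str, c["breaks"])) or "(none)"
        lines.append(
            f"  breaks {label:<12} IC {c['total_ic']:>9.2f}  "
            f"delta {c['delta_ic']:.2f}  weight {c['weight']:.3f}"
        )
    if report["break_weights"]:
        lines.append("")
        lines.append("Break weights:")
        for year, info in report["break_weights"].items():
            lines.append(
                f"  after {year}: weight {info['weight']:.3f} ({info['label']})"
            )
    lines.append("")
    lines.append("Best-combination segments:")
    for seg in report["best_segments"]:
        lines.append(
            f"  {seg['start_year']}-{seg['end_year']}: "
            f"r = {seg['r']:.3g} ± {seg['r_se']:.2g}, "
            f"K = {seg['k']:.3g} ± {seg['k_se']:.2g} "
            f"(n_obs {seg['n_obs']})"
        )
    return "\n".join(lines) + "\n"
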