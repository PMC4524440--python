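"""Distributional statistics over collections of replicate outcomes.

The headline quantities mirror how simulated cohorts are usually
summarised in this literature: the median event time with a 90% band
(5th-95th percentiles of the replicate distribution, not a standard-error
interval), success probabilities at fixed horizons, resistance burden
metrics, and regressions of relapse time on properties of the resected
tumour.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .scenarios import OutcomeStatus, ReplicateOutcome, ScenarioKind

__all__ = [
    "ScenarioSummary",
    "RegressionFit",
    "detection_time_stats",
    "resistance_metrics",
    "driver_distribution",
    "relapse_regressions",
    "event_time",
]

#: Histogram bin width: 3 months in years.
BIN_WIDTH_YEARS = 0.25


def event_time(out: ReplicateOutcome) -> Optional[float]:
    """Time to the protocol's failure event, in years, or None.

    Prevention protocols fail at detection; the post-diagnostic protocol
    fails at relapse (clocked from resection); the second-chance protocol
    fails at the second detection, clocked from the initial M0 lesion.
    """
    if out.scenario is ScenarioKind.POST_DIAGNOSTIC:
        return out.time_to_relapse_years
    if out.scenario is ScenarioKind.SECOND_CHANCE:
        if out.time_to_relapse_years is None:
            return None
        return (out.time_to_detection_years or 0.0) + out.time_to_relapse_years
    return out.time_to_detection_years


@dataclass
class ScenarioSummary:
    n_replicates: int
    n_events: int
    median_years: Optional[float]
    mean_years: Optional[float]
    p5_years: Optional[float]
    p95_years: Optional[float]
    success_at_20y: float
    success_at_horizon: float
    horizon_years: float
    fraction_below_100_resistant_4y: Optional[float]
    mean_resistant_fraction_at_event: Optional[float]
    mean_drivers_at_event: Optional[float]
    histogram_bin_edges: List[float]
    histogram_mass: List[float]

    def to_dict(self) -> dict:
        return asdict(self)


def _success_fraction(times: Sequence[Optional[float]], horizon: float) -> float:
    """Fraction of replicates with no failure event by ``horizon`` years
    (extinct and still-controlled tumours both count as successes)."""
    ok = sum(1 for t in times if t is None or t > horizon)
    return ok / len(times)


def detection_time_stats(
    outcomes: Sequence[ReplicateOutcome],
    horizon_years: float = 50.0,
    assign_undetected_to_horizon: bool = False,
) -> ScenarioSummary:
    """Summarise failure-time distribution and success probabilities.

    Percentiles use linear interpolation between order statistics and are
    computed over replicates with an observed event; undetected and
    extinct replicates enter only the success metrics, unless
    ``assign_undetected_to_horizon`` is set, in which case they are
    scored at ``horizon_years`` (the convention used when plotting whole
    cohorts including non-failures).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one outcome")
    times = [event_time(o) for o in outcomes]
    observed = [t for t in times if t is not None]
    scored = (
        [t if t is not None else horizon_years for t in times]
        if assign_undetected_to_horizon
        else observed
    )
    if scored:
        arr = np.asarray(scored, dtype=float)
        median = float(np.median(arr))
        mean = float(np.mean(arr))
        p5, p95 = (float(q) for q in np.percentile(arr, [5, 95]))
        upper = max(arr.max(), BIN_WIDTH_YEARS)
        edges = np.arange(0.0, upper + BIN_WIDTH_YEARS, BIN_WIDTH_YEARS)
        hist, edges = np.histogram(arr, bins=edges)
        mass = hist / hist.sum() if hist.sum() else hist.astype(float)
    else:
        median = mean = p5 = p95 = None
        edges = np.array([0.0, BIN_WIDTH_YEARS])
        mass = np.array([0.0])

    with_event = [o for o, t in zip(outcomes, times) if t is not None]
    frac100 = _fraction_below_100(outcomes)
    return ScenarioSummary(
        n_replicates=len(outcomes),
        n_events=len(observed),
        median_years=median,
        mean_years=mean,
        p5_years=p5,
        p95_years=p95,
        success_at_20y=_success_fraction(times, 20.0),
        success_at_horizon=_success_fraction(times, horizon_years),
        horizon_years=horizon_years,
        fraction_below_100_resistant_4y=frac100,
        mean_resistant_fraction_at_event=(
            float(np.mean([o.resistant_fraction_at_end for o in with_event]))
            if with_event
            else None
        ),
        mean_drivers_at_event=(
            float(np.mean([o.mean_drivers_at_end for o in with_event])) if with_event else None
        ),
        histogram_bin_edges=[float(e) for e in edges],
        histogram_mass=[float(m) for m in mass],
    )


def _fraction_below_100(outcomes: Sequence[ReplicateOutcome]) -> Optional[float]:
    counts = [o.resistant_count_at_4y for o in outcomes]
    if any(c is None for c in counts):
        return None
    # extinct tumours carry a zero count and are trivially below 100
    return sum(1 for c in counts if c < 100) / len(counts)


def resistance_metrics(
    outcomes: Sequence[ReplicateOutcome],
) -> Tuple[Optional[float], Optional[float]]:
    """(mean resistant fraction at the failure event, fraction of all
    replicates with < 100 resistant cells 4 years into treatment)."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one outcome")
    frac100 = _fraction_below_100(outcomes)
    if frac100 is None:
        raise ValueError("outcomes lack 4-year resistant-count snapshots")
    with_event = [o for o in outcomes if event_time(o) is not None]
    mean_rf = (
        float(np.mean([o.resistant_fraction_at_end for o in with_event]))
        if with_event
        else None
    )
    return mean_rf, frac100


def driver_distribution(
    outcomes: Sequence[ReplicateOutcome], event: str = "at_end"
) -> Tuple[np.ndarray, float]:
    """Mean subclone sizes over replicates at a named event.

    Returns the (N + 1, 2) array of mean cell counts per subclone and the
    cell-weighted mean number of extra drivers of that mean composition.
    ``event`` is one of the snapshot labels recorded by the scenario
    (``at_discovery``, ``post_resection``, ``at_start``, ``at_end``).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one outcome")
    missing = [o for o in outcomes if event not in o.snapshots]
    if missing:
        raise ValueError(f"snapshot {event!r} absent from {len(missing)} outcomes")
    mean_counts = np.mean([o.snapshots[event] for o in outcomes], axis=0)
    total = mean_counts.sum()
    i = np.arange(mean_counts.shape[0])
    mean_drivers = float((mean_counts.sum(axis=1) @ i) / total) if total else 0.0
    return mean_counts, mean_drivers


@dataclass
class RegressionFit:
    """Least-squares fit summary; params are (intercept, slope) for the
    linear model and (a, b) for y = a * exp(-b x)."""

    params: Tuple[float, float]
    r_squared: float
    n: int


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def relapse_regressions(
    outcomes: Iterable[ReplicateOutcome],
) -> Tuple[Optional[RegressionFit], Optional[RegressionFit]]:
    """Fit relapse time against two predictors of the resected tumour.

    Returns (linear fit of relapse time on discovery time, negative
    exponential fit ``y = a exp(-b x)`` of relapse time on the mean driver
    count at discovery).  Requires >= 10 paired observations; a predictor
    with degenerate variance yields ``None`` for that fit.
    """
    pairs = [
        (o.time_to_detection_years, o.mean_drivers_at_discovery, o.time_to_relapse_years)
        for o in outcomes
        if o.time_to_relapse_years is not None
        and o.time_to_detection_years is not None
        and o.mean_drivers_at_discovery is not None
    ]
    if len(pairs) < 10:
        raise ValueError("need at least 10 paired observations")
    t_disc, drivers, t_rel = (np.asarray(col, dtype=float) for col in zip(*pairs))

    linear: Optional[RegressionFit] = None
    if np.ptp(t_disc) > 0:
        res = stats.linregress(t_disc, t_rel)
        linear = RegressionFit(
            params=(float(res.intercept), float(res.slope)),
            r_squared=float(res.rvalue**2),
            n=len(t_rel),
        )

    expo: Optional[RegressionFit] = None
    if np.ptp(drivers) > 0:
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(-b * x),
                drivers,
                t_rel,
                p0=(max(t_rel.max(), 1.0), 0.3),
                maxfev=10000,
            )
            y_hat = popt[0] * np.exp(-popt[1] * drivers)
            expo = RegressionFit(
                params=(float(popt[0]), float(popt[1])),
                r_squared=_r_squared(t_rel, y_hat),
                n=len(t_rel),
            )
        except RuntimeError:
            expo = None
    return linear, expo
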