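"""Intervention protocols run per replicate.

Four protocols are modelled:

* ``prevention_fixed`` — a preformed lesion of identical i = 0 cells (a
  fraction kappa of them resistant) is put under a constant measure until
  it is detected, goes extinct, or the horizon passes.
* ``prevention_grown`` — the lesion is instead grown from a single
  sensitive cell to size M0 (accumulating drivers and resistance on the
  way), then treated as above.
* ``post_diagnostic`` — the tumour grows untreated from one cell until
  clinical discovery, is resected to a small residual population, and the
  residual is treated until relapse at the detection threshold.
* ``second_chance`` — prevention from a grown lesion which, on failure
  (detection), is followed by resection back to M0 cells and continued
  treatment at the same intensity; final failure means reaching the
  detection threshold a second time within the horizon.

Growth phases from a single cell condition on non-extinction: attempts
that die out are discarded and redrawn, matching the convention of
counting replicates excluding extinctions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GrowthOutcome,
    PopulationState,
    TreatmentPolicy,
    grow_to_size,
    resect,
)
from .params import ModelParams

__all__ = [
    "ScenarioKind",
    "OutcomeStatus",
    "ScenarioConfig",
    "ReplicateOutcome",
    "run_replicate",
    "run_replicates",
    "sweep",
    "outcomes_to_dataframe",
]

#: Safety cap applied when a scenario is run with an uncapped horizon.
HARD_CAP_YEARS = 150.0

#: Upper bound on discarded growth attempts per replicate before giving up.
MAX_GROWTH_ATTEMPTS = 10**7


class ScenarioKind(str, Enum):
    PREVENTION_FIXED = "prevention_fixed"
    PREVENTION_GROWN = "prevention_grown"
    POST_DIAGNOSTIC = "post_diagnostic"
    SECOND_CHANCE = "second_chance"


class OutcomeStatus(str, Enum):
    DETECTED = "detected"
    RELAPSED = "relapsed"
    EXTINCT = "extinct"
    UNDETECTED_AT_HORIZON = "undetected_at_horizon"


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one intervention protocol.

    ``sigma`` is the per-cycle intensity of the constant measure.  The
    ``horizon_years`` of ``None`` means uncapped (subject to a hard
    safety cap); success-probability protocols typically use 50 years.
    ``resistant_count`` overrides the fraction ``resistant_fraction``
    (kappa) when given.
    """

    kind: ScenarioKind
    sigma: float = 0.0
    initial_size: int = 10**6
    resistant_fraction: Optional[float] = None
    resistant_count: Optional[int] = None
    discovery_threshold: int = 10**9
    residual_size: int = 10**6
    horizon_years: Optional[float] = None
    replicates: int = 100
    base_seed: int = 0
    metronomic: bool = False
    exclude_extinctions: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScenarioKind(self.kind))
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.initial_size < 1:
            raise ValueError("initial_size must be positive")
        if self.residual_size > self.discovery_threshold:
            raise ValueError("residual_size must not exceed discovery_threshold")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.resistant_count is not None and self.resistant_count > self.initial_size:
            raise ValueError("resistant_count exceeds initial_size")
        if self.resistant_fraction is not None and not 0 <= self.resistant_fraction <= 1:
            raise ValueError("resistant_fraction must lie in [0, 1]")
        if self.horizon_years is not None and self.horizon_years < 0:
            raise ValueError("horizon_years must be non-negative")

    def policy(self) -> TreatmentPolicy:
        if self.metronomic:
            return TreatmentPolicy.metronomic(self.sigma)
        if self.sigma == 0:
            return TreatmentPolicy.none()
        return TreatmentPolicy.constant(self.sigma)

    def initial_resistant(self, params: ModelParams) -> int:
        if self.resistant_count is not None:
            return self.resistant_count
        kappa = (
            self.resistant_fraction
            if self.resistant_fraction is not None
            else params.pre_resistance
        )
        return int(round(kappa * self.initial_size))

    def horizon_steps(self, params: ModelParams) -> int:
        years = self.horizon_years if self.horizon_years is not None else HARD_CAP_YEARS
        return params.steps(years)


@dataclass
class ReplicateOutcome:
    """Endpoint of one simulated patient trajectory."""

    status: OutcomeStatus
    seed: int
    scenario: ScenarioKind
    sigma: float
    #: years from treatment start to detection (prevention protocols), or
    #: years from tumour initiation to clinical discovery (post-diagnostic)
    time_to_detection_years: Optional[float] = None
    #: years from resection to relapse at the detection threshold
    time_to_relapse_years: Optional[float] = None
    resistant_fraction_at_end: float = 0.0
    mean_drivers_at_end: float = 0.0
    resistant_count_at_4y: Optional[int] = None
    below_threshold_at_20y: Optional[bool] = None
    #: cell-weighted mean driver count of the primary tumour at discovery
    mean_drivers_at_discovery: Optional[float] = None
    second_chance_used: bool = False
    growth_attempts: int = 1
    #: subclone counts at named events: at_discovery, post_resection, at_end
    snapshots: Dict[str, np.ndarray] = field(default_factory=dict)


def _grow_conditioned(
    size: int, params: ModelParams, rng: np.random.Generator
) -> tuple[PopulationState, int, int]:
    """Grow a single sensitive cell to ``size`` untreated, redrawing
    attempts that go extinct.  Returns (state, steps, attempts)."""
    untreated = TreatmentPolicy.none()
    for attempt in range(1, MAX_GROWTH_ATTEMPTS + 1):
        start = PopulationState.single_cell(params)
        result = grow_to_size(start, size, untreated, params, rng)
        if result.outcome is GrowthOutcome.REACHED:
            return result.state, result.steps, attempt
    raise RuntimeError("growth phase failed to reach target size")


def _treatment_phase(
    state: PopulationState,
    config: ScenarioConfig,
    params: ModelParams,
    rng: np.random.Generator,
    horizon_steps: Optional[int] = None,
):
    """Run the measure until detection, extinction or horizon, recording
    the resistant burden four years in."""
    steps_4y = params.steps(4.0)
    cap = horizon_steps if horizon_steps is not None else config.horizon_steps(params)
    result = grow_to_size(
        state,
        params.detection_threshold,
        config.policy(),
        params,
        rng,
        max_steps=cap,
        checkpoint_steps=(steps_4y,),
    )
    # runs ending before the 4-year mark use their final resistant count
    resistant_4y = result.checkpoints.get(steps_4y, result.state.resistant)
    return result, resistant_4y


_STATUS_FROM_GROWTH = {
    GrowthOutcome.EXTINCT: OutcomeStatus.EXTINCT,
    GrowthOutcome.HORIZON: OutcomeStatus.UNDETECTED_AT_HORIZON,
}


def _finish(
    outcome: ReplicateOutcome, result, params: ModelParams, detected_status: OutcomeStatus
) -> ReplicateOutcome:
    """Fill end-state fields shared by every protocol."""
    end = result.state
    outcome.resistant_fraction_at_end = end.resistant_fraction
    outcome.mean_drivers_at_end = end.mean_drivers()
    outcome.snapshots["at_end"] = end.counts.copy()
    if result.outcome is GrowthOutcome.REACHED:
        outcome.status = detected_status
        years = params.years(result.steps)
        if detected_status is OutcomeStatus.RELAPSED:
            outcome.time_to_relapse_years = years
        else:
            outcome.time_to_detection_years = years
        outcome.below_threshold_at_20y = years > 20.0
    else:
        outcome.status = _STATUS_FROM_GROWTH[result.outcome]
        outcome.below_threshold_at_20y = True
    return outcome


def run_replicate(
    config: ScenarioConfig, params: ModelParams, replicate_index: int = 0
) -> ReplicateOutcome:
    """Simulate one patient under the configured protocol.

    The replicate RNG is seeded with ``base_seed + replicate_index`` so
    outcome sets are reproducible and independent of execution order.
    """
    seed = config.base_seed + replicate_index
    rng = np.random.default_rng(seed)
    outcome = ReplicateOutcome(
        status=OutcomeStatus.UNDETECTED_AT_HORIZON,
        seed=seed,
        scenario=config.kind,
        sigma=config.sigma,
    )

    if config.kind is ScenarioKind.PREVENTION_FIXED:
        r0 = config.initial_resistant(params)
        state = PopulationState.uniform_lesion(params, config.initial_size, r0)
        result, outcome.resistant_count_at_4y = _treatment_phase(state, config, params, rng)
        return _finish(outcome, result, params, OutcomeStatus.DETECTED)

    if config.kind is ScenarioKind.PREVENTION_GROWN:
        state, _, outcome.growth_attempts = _grow_conditioned(config.initial_size, params, rng)
        outcome.snapshots["at_start"] = state.counts.copy()
        result, outcome.resistant_count_at_4y = _treatment_phase(state, config, params, rng)
        return _finish(outcome, result, params, OutcomeStatus.DETECTED)

    if config.kind is ScenarioKind.POST_DIAGNOSTIC:
        state, growth_steps, outcome.growth_attempts = _grow_conditioned(
            config.discovery_threshold, params, rng
        )
        outcome.time_to_detection_years = params.years(growth_steps)
        outcome.snapshots["at_discovery"] = state.counts.copy()
        residual = resect(state, config.residual_size, rng)
        outcome.snapshots["post_resection"] = residual.counts.copy()
        outcome.mean_drivers_at_discovery = state.mean_drivers()
        result, outcome.resistant_count_at_4y = _treatment_phase(residual, config, params, rng)
        return _finish(outcome, result, params, OutcomeStatus.RELAPSED)

    if config.kind is ScenarioKind.SECOND_CHANCE:
        # horizon clock starts at the M0 lesion, per protocol definition
        horizon = config.horizon_steps(params) if config.horizon_years is not None else params.steps(50.0)
        state, _, outcome.growth_attempts = _grow_conditioned(config.initial_size, params, rng)
        outcome.snapshots["at_start"] = state.counts.copy()
        result, outcome.resistant_count_at_4y = _treatment_phase(
            state, config, params, rng, horizon_steps=horizon
        )
        if result.outcome is not GrowthOutcome.REACHED:
            return _finish(outcome, result, params, OutcomeStatus.DETECTED)
        # initial failure: resect back to M0 and continue at the same sigma
        outcome.second_chance_used = True
        first_detect_steps = result.steps
        outcome.time_to_detection_years = params.years(first_detect_steps)
        outcome.snapshots["at_discovery"] = result.state.counts.copy()
        residual = resect(result.state, config.initial_size, rng)
        outcome.snapshots["post_resection"] = residual.counts.copy()
        remaining = max(horizon - first_detect_steps, 0)
        result2, _ = _treatment_phase(residual, config, params, rng, horizon_steps=remaining)
        return _finish(outcome, result2, params, OutcomeStatus.RELAPSED)

    raise ValueError(f"unknown scenario kind: {config.kind}")


def run_replicates(config: ScenarioConfig, params: ModelParams) -> List[ReplicateOutcome]:
    """Run all configured replicates serially with deterministic seeds."""
    return [run_replicate(config, params, k) for k in range(config.replicates)]


_PARAM_FIELDS = {
    "driver_advantage",
    "resistance_cost",
    "driver_mut_rate",
    "resistance_mut_rate",
    "max_extra_drivers",
    "detection_threshold",
    "pre_resistance",
    "cycle_days",
}


def sweep(
    base_config: ScenarioConfig,
    grid: Dict[str, Sequence],
    params: ModelParams,
) -> pd.DataFrame:
    """Run the protocol over the Cartesian product of ``grid``.

    Grid keys may name ``ScenarioConfig`` fields (e.g. ``sigma``,
    ``initial_size``) or ``ModelParams`` fields (e.g. ``driver_advantage``,
    ``max_extra_drivers``).  Each grid point gets a disjoint, deterministic
    seed block so the sweep is reproducible and order-independent.
    Returns one row per replicate, tagged with its grid coordinates.
    """
    if not grid:
        raise ValueError("sweep grid must not be empty")
    keys = list(grid)
    rows = []
    for point_index, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        point = dict(zip(keys, values))
        cfg_over = {k: v for k, v in point.items() if k not in _PARAM_FIELDS}
        par_over = {k: v for k, v in point.items() if k in _PARAM_FIELDS}
        seed0 = base_config.base_seed + point_index * base_config.replicates
        cfg = replace(base_config, base_seed=seed0, **cfg_over)
        par = params.with_(**par_over) if par_over else params
        for out in run_replicates(cfg, par):
            row = dict(point)
            row.update(_outcome_row(out))
            rows.append(row)
    return pd.DataFrame(rows)


def _outcome_row(out: ReplicateOutcome) -> dict:
    return {
        "scenario": out.scenario.value,
        "sigma_cycle": out.sigma,
        "status": out.status.value,
        "t_detect_years": out.time_to_detection_years,
        "t_relapse_years": out.time_to_relapse_years,
        "resistant_fraction": out.resistant_fraction_at_end,
        "mean_drivers": out.mean_drivers_at_end,
        "resistant_count_4y": out.resistant_count_at_4y,
        "below_M_20y": out.below_threshold_at_20y,
        "seed": out.seed,
    }


def outcomes_to_dataframe(outcomes: Iterable[ReplicateOutcome]) -> pd.DataFrame:
    """Per-replicate table with one row per outcome."""
    rows = []
    for k, out in enumerate(outcomes):
        row = {"replicate_id": k}
        row.update(_outcome_row(out))
        rows.append(row)
    return pd.DataFrame(rows)
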