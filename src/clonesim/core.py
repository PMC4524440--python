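"""Stochastic engine: fitness, per-cell fate probabilities, multinomial
population updates, growth to a target size, and resection.

The model is a discrete-time multitype Galton-Watson branching process.
Each step every cell independently either dies or divides; on division the
daughter may acquire a driver mutation (probability ``u``) or a resistance
mutation (probability ``v``), mutually exclusively.  Cells do not compete:
subclone updates are independent multinomial draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "PopulationState",
    "TreatmentPolicy",
    "StepOutcomeProbs",
    "GrowthOutcome",
    "GrowthResult",
    "fitness",
    "birth_death_probs",
    "outcome_probs",
    "step",
    "grow_to_size",
    "resect",
    "critical_intensity",
]


@dataclass
class PopulationState:
    """Integer cell counts on the (driver, resistance) lattice.

    ``counts[i, j]`` is the number of cells with ``i`` extra drivers and
    resistance status ``j``; ``step_index`` counts elapsed steps.
    """

    counts: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must have shape (N + 1, 2)")
        if np.any(counts < 0):
            raise ValueError("cell counts must be non-negative")
        self.counts = counts

    @classmethod
    def empty(cls, params: ModelParams) -> "PopulationState":
        return cls(np.zeros((params.max_extra_drivers + 1, 2), dtype=np.int64))

    @classmethod
    def single_cell(cls, params: ModelParams) -> "PopulationState":
        """One sensitive founder cell with no extra drivers."""
        state = cls.empty(params)
        state.counts[0, 0] = 1
        return state

    @classmethod
    def uniform_lesion(
        cls, params: ModelParams, size: int, resistant: int = 0
    ) -> "PopulationState":
        """A lesion of ``size`` identical i = 0 cells, ``resistant`` of
        which carry the resistance mutation."""
        if resistant > size:
            raise ValueError("resistant count exceeds lesion size")
        state = cls.empty(params)
        state.counts[0, 0] = size - resistant
        state.counts[0, 1] = resistant
        return state

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def sensitive(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def resistant(self) -> int:
        return int(self.counts[:, 1].sum())

    @property
    def resistant_fraction(self) -> float:
        total = self.total
        return self.resistant / total if total else 0.0

    def mean_drivers(self) -> float:
        """Cell-weighted mean number of extra drivers (0 if empty)."""
        total = self.total
        if total == 0:
            return 0.0
        i = np.arange(self.counts.shape[0])
        return float((self.counts.sum(axis=1) @ i) / total)

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.step_index)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format snapshot with columns step, i, j, count."""
        n, _ = self.counts.shape
        i, j = np.meshgrid(np.arange(n), np.arange(2), indexing="ij")
        return pd.DataFrame(
            {
                "step": self.step_index,
                "i": i.ravel(),
                "j": j.ravel(),
                "count": self.counts.ravel(),
            }
        )


class PolicyKind(str, Enum):
    NONE = "none"
    CONSTANT = "constant"
    METRONOMIC = "metronomic"


@dataclass(frozen=True)
class TreatmentPolicy:
    """Maps population state to the per-cycle intensity applied this step.

    ``constant`` applies ``sigma`` every step; ``none`` is constant 0;
    ``metronomic`` applies ``sigma`` only while sensitive cells outnumber
    resistant cells, otherwise 0.
    """

    kind: PolicyKind = PolicyKind.NONE
    sigma: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PolicyKind(self.kind))
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind is PolicyKind.NONE and self.sigma != 0:
            raise ValueError("policy 'none' requires sigma = 0")

    @classmethod
    def none(cls) -> "TreatmentPolicy":
        return cls(PolicyKind.NONE, 0.0)

    @classmethod
    def constant(cls, sigma: float) -> "TreatmentPolicy":
        return cls(PolicyKind.CONSTANT, sigma)

    @classmethod
    def metronomic(cls, sigma: float) -> "TreatmentPolicy":
        return cls(PolicyKind.METRONOMIC, sigma)

    def sigma_at(self, state: PopulationState) -> float:
        """Per-cycle intensity applied to the given state."""
        if self.kind is PolicyKind.METRONOMIC:
            return self.sigma if state.sensitive > state.resistant else 0.0
        return self.sigma


class StepOutcomeProbs(NamedTuple):
    """Probabilities of the four per-cell fates within one step."""

    p_death: float
    p_div_plain: float
    p_div_driver: float
    p_div_resist: float


def fitness(i: int, j: int, sigma: float, params: ModelParams) -> float:
    """Per-cycle fitness f_ij = s(i+1) - sigma(1-j) - c*j.

    Fitness is the difference between the per-step birth and death
    probabilities of a cell.  Treatment (``sigma``) only touches
    sensitive cells (j = 0); resistance carries the constant cost ``c``.
    """
    i_arr = np.asarray(i)
    j_arr = np.asarray(j)
    if np.any(i_arr < 0) or np.any(i_arr > params.max_extra_drivers):
        raise ValueError(f"driver index out of range [0, {params.max_extra_drivers}]")
    if not np.all(np.isin(j_arr, (0, 1))):
        raise ValueError("resistance status must be 0 or 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s, c = params.driver_advantage, params.resistance_cost
    out = s * (i_arr + 1) - sigma * (1 - j_arr) - c * j_arr
    return float(out) if out.ndim == 0 else out


def birth_death_probs(f) -> Tuple[float, float]:
    """Split per-cycle fitness into (division, death) probabilities.

    Uses b = (1 + f) / 2 and d = (1 - f) / 2 so that b - d = f and
    b + d = 1 (every cell either divides or dies each step); the expected
    offspring per cell per step is then 2b = 1 + f.  Fitness outside
    [-1, 1] is clipped with a warning.
    """
    f_arr = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f_arr)):
        raise ValueError("fitness must be finite")
    if np.any(np.abs(f_arr) > 1):
        warnings.warn("fitness outside [-1, 1]; clipping", RuntimeWarning, stacklevel=2)
        f_arr = np.clip(f_arr, -1.0, 1.0)
    b = (1.0 + f_arr) / 2.0
    d = (1.0 - f_arr) / 2.0
    if f_arr.ndim == 0:
        return float(b), float(d)
    return b, d


def outcome_probs(i: int, j: int, sigma: float, params: ModelParams) -> StepOutcomeProbs:
    """Per-cell fate probabilities for one subclone and one step.

    A dividing cell's daughter mutates with probability ``u`` (driver) or
    ``v`` (resistance), mutually exclusively.  At the lattice boundaries
    (i = N, or j = 1) the corresponding mutation is wasted: its mass folds
    into plain division, keeping the four probabilities normalised.
    """
    b, d = birth_death_probs(fitness(i, j, sigma, params))
    u_eff = params.driver_mut_rate if i < params.max_extra_drivers else 0.0
    v_eff = params.resistance_mut_rate if j == 0 else 0.0
    return StepOutcomeProbs(
        p_death=d,
        p_div_plain=b * (1.0 - u_eff - v_eff),
        p_div_driver=b * u_eff,
        p_div_resist=b * v_eff,
    )


@lru_cache(maxsize=64)
def _fate_probs_lattice(sigma: float, params: ModelParams) -> np.ndarray:
    """Fate-probability array of shape (N + 1, 2, 4) for a given sigma.

    Last axis: (death, plain division, driver division, resistance
    division).  Rows sum to 1 exactly: plain division is computed as the
    residual mass.
    """
    n_types = params.max_extra_drivers + 1
    i = np.arange(n_types)[:, None]
    j = np.arange(2)[None, :]
    f = fitness(np.broadcast_to(i, (n_types, 2)), np.broadcast_to(j, (n_types, 2)), sigma, params)
    b, d = birth_death_probs(f)
    u_eff = np.where(i < params.max_extra_drivers, params.driver_mut_rate, 0.0)
    v_eff = np.where(j == 0, params.resistance_mut_rate, 0.0)
    probs = np.empty((n_types, 2, 4))
    probs[:, :, 0] = d
    probs[:, :, 2] = b * u_eff
    probs[:, :, 3] = b * v_eff
    probs[:, :, 1] = 1.0 - probs[:, :, 0] - probs[:, :, 2] - probs[:, :, 3]
    return probs


def _multinomial_step(
    counts: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one multinomial update of the whole lattice.

    Offspring rules: plain division -> two (i, j) cells; driver division
    -> one (i, j) + one (i + 1, j); resistance division -> one (i, j) +
    one (i, 1); death -> none.
    """
    fates = rng.multinomial(counts.ravel(), probs.reshape(-1, 4)).reshape(counts.shape + (4,))
    plain = fates[:, :, 1]
    driver = fates[:, :, 2]
    resist = fates[:, :, 3]
    nxt = 2 * plain + driver + resist
    nxt[1:, :] += driver[:-1, :]
    nxt[:, 1] += resist[:, 0]
    return nxt


def step(
    state: PopulationState,
    policy: TreatmentPolicy,
    params: ModelParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population by one cell cycle.

    Each subclone's cells are partitioned among the four fates by an
    independent multinomial draw; the input state is left unmodified.
    """
    sigma = policy.sigma_at(state)
    probs = _fate_probs_lattice(sigma, params)
    nxt = _multinomial_step(state.counts, probs, rng)
    return PopulationState(nxt, state.step_index + 1)


class GrowthOutcome(str, Enum):
    REACHED = "reached"
    EXTINCT = "extinct"
    HORIZON = "horizon"


@dataclass
class GrowthResult:
    outcome: GrowthOutcome
    state: PopulationState
    steps: int
    #: resistant cell count at each recorded checkpoint step (step -> count)
    checkpoints: dict = field(default_factory=dict)


def grow_to_size(
    start: PopulationState,
    target: int,
    policy: TreatmentPolicy,
    params: ModelParams,
    rng: np.random.Generator,
    max_steps: Optional[int] = None,
    checkpoint_steps: Tuple[int, ...] = (),
) -> GrowthResult:
    """Iterate ``step`` until the total reaches ``target``, the population
    dies out, or ``max_steps`` whole steps have elapsed.

    The size check happens after each completed step (and once before the
    first step, so a start at or above target returns immediately).
    ``checkpoint_steps`` are elapsed-step offsets (relative to ``start``)
    at which the resistant cell count is recorded, for metrics such as the
    resistant burden four years into treatment.
    """
    if target < 1:
        raise ValueError("target must be a positive cell count")
    state = state0 = start
    elapsed = 0
    checkpoints: dict = {}
    wanted = sorted(set(checkpoint_steps))

    # fast path shared by all scenarios: constant sigma -> fixed fate probs
    sigma_fixed = None
    if policy.kind is not PolicyKind.METRONOMIC:
        sigma_fixed = policy.sigma
        probs = _fate_probs_lattice(sigma_fixed, params)
    counts = state0.counts
    total = int(counts.sum())
    while True:
        for t in wanted:
            if elapsed == t and t not in checkpoints:
                checkpoints[t] = int(counts[:, 1].sum())
        if total >= target:
            outcome = GrowthOutcome.REACHED
            break
        if total == 0:
            outcome = GrowthOutcome.EXTINCT
            break
        if max_steps is not None and elapsed >= max_steps:
            outcome = GrowthOutcome.HORIZON
            break
        if sigma_fixed is None:
            probs = _fate_probs_lattice(
                policy.sigma_at(PopulationState(counts, state0.step_index + elapsed)), params
            )
        counts = _multinomial_step(counts, probs, rng)
        total = int(counts.sum())
        elapsed += 1
    final = PopulationState(counts, state0.step_index + elapsed)
    return GrowthResult(outcome, final, elapsed, checkpoints)


def resect(state: PopulationState, residual: int, rng: np.random.Generator) -> PopulationState:
    """Surgical resection leaving ``residual`` cells.

    The residual cells are allocated across subclones by a single
    multinomial draw with probabilities proportional to the pre-resection
    composition, so the total is conserved exactly and the expected
    subclone proportions are unchanged.
    """
    total = state.total
    if residual > total:
        raise ValueError("residual exceeds current population size")
    if residual == total:
        return state.copy()
    p = state.counts.ravel() / total
    new = rng.multinomial(residual, p).reshape(state.counts.shape)
    return PopulationState(new.astype(np.int64), state.step_index)


def critical_intensity(params: ModelParams) -> float:
    """Per-cycle intensity s(N + 1) above which every sensitive subclone,
    including the fittest possible one, is subcritical."""
    return params.driver_advantage * (params.max_extra_drivers + 1)
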