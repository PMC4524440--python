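"""Model parameters for the tumour branching process.

Cells are classified on a lattice of subclones indexed by ``(i, j)`` where
``i`` is the number of extra driver mutations (0..N) and ``j`` is the
resistance status (0 = sensitive, 1 = resistant).  All rates below are
per cell cycle (one discrete time step of ``cycle_days`` days).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any


@dataclass(frozen=True)
class ModelParams:
    """Biological constants of the branching-process model.

    Parameters
    ----------
    cycle_days:
        Length of one time step (cell cycle) in days.
    driver_advantage:
        Per-cycle fitness increment ``s`` contributed by each driver
        mutation (the founder cell counts as carrying one driver, so a
        sensitive cell with ``i`` extra drivers has baseline fitness
        ``s * (i + 1)``).
    resistance_cost:
        Constant per-cycle fitness cost ``c`` paid by resistant cells.
    driver_mut_rate:
        Probability ``u`` per division that the daughter cell gains one
        extra driver mutation.
    resistance_mut_rate:
        Probability ``v`` per division that the daughter cell becomes
        resistant.  No back mutation.
    max_extra_drivers:
        Maximum value of the driver index ``i`` (``N``).  At ``i = N``
        further driver mutations are wasted.
    detection_threshold:
        Total cell count ``M`` at which a tumour is clinically detected.
    pre_resistance:
        Initial resistant fraction ``kappa`` used by prevention scenarios
        that start from a preformed lesion.
    days_per_year:
        Calendar conversion constant.
    """

    cycle_days: float = 4.0
    driver_advantage: float = 0.004
    resistance_cost: float = 0.001
    driver_mut_rate: float = 3.4e-5
    resistance_mut_rate: float = 1e-6
    max_extra_drivers: int = 5
    detection_threshold: int = 10**9
    pre_resistance: float = 1e-4
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        if self.driver_advantage < 0:
            raise ValueError("driver_advantage must be non-negative")
        if self.resistance_cost < 0:
            raise ValueError("resistance_cost must be non-negative")
        if self.driver_mut_rate < 0 or self.resistance_mut_rate < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.driver_mut_rate + self.resistance_mut_rate > 1:
            raise ValueError("u + v must not exceed 1")
        if int(self.max_extra_drivers) != self.max_extra_drivers or self.max_extra_drivers < 0:
            raise ValueError("max_extra_drivers must be a non-negative integer")
        if int(self.detection_threshold) != self.detection_threshold or self.detection_threshold < 1:
            raise ValueError("detection_threshold must be a positive integer")
        if not 0 <= self.pre_resistance <= 1:
            raise ValueError("pre_resistance must lie in [0, 1]")
        if self.days_per_year <= 0:
            raise ValueError("days_per_year must be positive")

    @property
    def steps_per_year(self) -> float:
        return self.days_per_year / self.cycle_days

    def years(self, steps: float) -> float:
        """Convert a number of elapsed steps to calendar years."""
        return steps * self.cycle_days / self.days_per_year

    def steps(self, years: float) -> int:
        """Number of whole steps elapsed after ``years`` calendar years."""
        return int(round(years * self.steps_per_year))

    def with_(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: Baseline parameterisation: 4-day cycle, s = 0.4%, c = 0.1%,
#: u = 3.4e-5, v = 1e-6, detection at 1e9 cells, kappa = 0.01%.
BASELINE = ModelParams()
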