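"""Deterministic expectation dynamics of the branching process.

The expected subclone counts obey a linear recursion E[n(t+1)] = A E[n(t)]
whose matrix A is the exact first moment of the stochastic multinomial
update: each (i, j) cell contributes on average b(2 - u' - v') cells back
to its own subclone, b u' cells to (i+1, j) and, if sensitive, b v' cells
to (i, 1).  Iterating A therefore reproduces the stochastic engine's mean
behaviour exactly, which makes this module the analytic oracle for the
Monte-Carlo code.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np

from .core import birth_death_probs, fitness
from .params import ModelParams

__all__ = ["transition_matrix", "expected_trajectory", "deterministic_detection_time"]


def _flat(i: np.ndarray | int, j: np.ndarray | int) -> np.ndarray | int:
    """Lattice (i, j) -> flat index used by the transition matrix."""
    return 2 * np.asarray(i) + np.asarray(j)


@lru_cache(maxsize=64)
def transition_matrix(sigma: float, params: ModelParams) -> np.ndarray:
    """Expected one-step map A on the flattened (i, j) lattice.

    Entry A[target, source] is the expected number of target-type cells
    produced per source-type cell per step.  The total contribution of a
    source cell sums to 1 + f_ij, its expected offspring number.
    """
    n_types = params.max_extra_drivers + 1
    dim = 2 * n_types
    A = np.zeros((dim, dim))
    for i in range(n_types):
        for j in (0, 1):
            b, _ = birth_death_probs(fitness(i, j, sigma, params))
            u_eff = params.driver_mut_rate if i < params.max_extra_drivers else 0.0
            v_eff = params.resistance_mut_rate if j == 0 else 0.0
            src = _flat(i, j)
            A[src, src] += b * (2.0 - u_eff - v_eff)
            if u_eff:
                A[_flat(i + 1, j), src] += b * u_eff
            if v_eff:
                A[_flat(i, 1), src] += b * v_eff
    A.setflags(write=False)
    return A


def _as_vector(e0: np.ndarray, params: ModelParams) -> np.ndarray:
    e0 = np.asarray(e0, dtype=float)
    n_types = params.max_extra_drivers + 1
    if e0.shape == (n_types, 2):
        e0 = e0.ravel()
    if e0.shape != (2 * n_types,):
        raise ValueError(f"expectation state must have shape ({n_types}, 2) or ({2 * n_types},)")
    if np.any(e0 < 0) or not np.all(np.isfinite(e0)):
        raise ValueError("expected counts must be finite and non-negative")
    return e0


def expected_trajectory(
    e0: np.ndarray, sigma: float, params: ModelParams, t: int
) -> np.ndarray:
    """Expected subclone counts after ``t`` steps, shape (N + 1, 2).

    The iteration renormalises the state each step and accumulates the
    scale in log space, so trajectories stay finite for horizons far
    beyond overflow of the raw counts; the result is re-exponentiated
    (and may be ``inf`` only if genuinely beyond float range).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    vec = _as_vector(e0, params)
    n_types = params.max_extra_drivers + 1
    if t == 0 or vec.sum() == 0:
        return vec.reshape(n_types, 2).copy()
    A = transition_matrix(sigma, params)
    log_scale = 0.0
    for _ in range(t):
        vec = A @ vec
        norm = vec.sum()
        if norm == 0:
            return vec.reshape(n_types, 2)
        vec = vec / norm
        log_scale += np.log(norm)
    return (vec * np.exp(log_scale)).reshape(n_types, 2)


def _reachable(support: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Indices reachable from the support via nonzero entries of A."""
    dim = A.shape[0]
    reach = np.zeros(dim, dtype=bool)
    frontier = list(np.nonzero(support)[0])
    reach[frontier] = True
    while frontier:
        src = frontier.pop()
        for tgt in np.nonzero(A[:, src])[0]:
            if not reach[tgt]:
                reach[tgt] = True
                frontier.append(tgt)
    return reach


def deterministic_detection_time(
    e0: np.ndarray, sigma: float, params: ModelParams, max_years: float = 500.0
) -> Optional[float]:
    """Years until the total expectation first reaches the detection
    threshold, or ``None`` if it never will.

    If every subclone type reachable from the initial support is
    subcritical (per-capita growth <= 1) the expectation is bounded and
    ``None`` is returned without iterating.  ``max_years`` guards against
    marginally supercritical cases crawling toward the threshold.
    """
    vec = _as_vector(e0, params)
    if vec.sum() >= params.detection_threshold:
        return 0.0
    A = transition_matrix(sigma, params)
    reach = _reachable(vec, A)
    if reach.any():
        sub = A[np.ix_(reach, reach)]
        growth = np.max(np.abs(np.linalg.eigvals(sub)))
        if growth <= 1.0:
            return None
    else:
        return None
    n_types = params.max_extra_drivers + 1
    log_scale = np.log(vec.sum())
    vec = vec / vec.sum()
    log_m = np.log(float(params.detection_threshold))
    for t in range(1, int(max_years * params.steps_per_year) + 1):
        vec = A @ vec
        norm = vec.sum()
        vec = vec / norm
        log_scale += np.log(norm)
        if log_scale >= log_m:
            return params.years(t)
    return None
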