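"""Regularization-path fitting: schedule, warm-started solves, sparsity.

The hyperparameter schedule has 141 points: a coarse leg stepping down by
``t0/100`` from ``t0`` to ``t0/2``, then a fine leg stepping down by
``t0/200`` to ``t0/20``.  Solves are warm-started from the previous
solution (``z0 = w0 = w(l-1)``); the first entry is the exact pair
``(prior, 0)`` by definition of the path start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MaxEntProblem
from .exceptions import DegeneratePathError, InvalidInputError
from .regularizers import RegularizerSpec, optimality_residual, t_max
from .solvers import SolverConfig, SolveResult, solve

__all__ = [
    "PathSchedule",
    "PathResult",
    "make_schedule",
    "fit_path",
    "nonzero_profile",
    "SparsityProfile",
]

logger = logging.getLogger(__name__)

SCHEDULE_LENGTH = 141


@dataclass(frozen=True)
class PathSchedule:
    """Strictly decreasing hyperparameter grid ``t(0) > ... > t(140)``."""

    t0: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def make_schedule(t0: float) -> PathSchedule:
    """Two-branch schedule: ``(1 - l/100) t0`` for ``l <= 50`` then
    ``(0.5 - (l-50)/200) t0`` for ``l = 51..140``."""
    if t0 <= 0:
        raise DegeneratePathError(
            "path start t0 must be positive; a zero t0 means the prior already "
            "matches the empirical feature averages"
        )
    l = np.arange(SCHEDULE_LENGTH)
    values = np.where(
        l <= 50,
        (1.0 - l / 100.0) * t0,
        (0.5 - (l - 50) / 200.0) * t0,
    )
    return PathSchedule(t0=float(t0), values=values)


@dataclass
class PathResult:
    """Per-hyperparameter solutions and diagnostics along the path."""

    schedule: PathSchedule
    ws: np.ndarray  # (m, len(schedule)) dual coefficients
    ps: np.ndarray  # (n, len(schedule)) site probabilities
    converged: np.ndarray
    iterations: np.ndarray
    residuals: np.ndarray
    dual_objectives: np.ndarray
    reg: RegularizerSpec = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.schedule)

    @property
    def t_over_tmax(self) -> np.ndarray:
        return self.schedule.values / self.schedule.t0

    def nonzero_counts(self, zero_tol: float = 1e-8) -> np.ndarray:
        return np.count_nonzero(np.abs(self.ws) > zero_tol, axis=0)


def fit_path(
    problem: MaxEntProblem,
    reg: RegularizerSpec,
    config: SolverConfig | None = None,
    schedule: PathSchedule | None = None,
    method: str = "npdhg",
) -> PathResult:
    """Fit the whole path with warm starts.

    The first entry is ``(prior, 0)`` exactly; subsequent solves start from
    the previous dual solution.  Non-converged solves are recorded with
    ``converged=False`` and a warning, never raised.
    """
    config = config or SolverConfig()
    if schedule is None:
        schedule = make_schedule(t_max(problem, reg))
    L = len(schedule)
    m, n = problem.m, problem.n
    ws = np.zeros((m, L))
    ps = np.zeros((n, L))
    converged = np.zeros(L, dtype=bool)
    iterations = np.zeros(L, dtype=int)
    residuals = np.zeros(L)
    duals = np.zeros(L)

    from .core import dual_objective

    ps[:, 0] = problem.prior
    check0 = optimality_residual(
        problem.prior, np.zeros(m), problem, reg, schedule.values[0],
        tol=config.tolerance,
    )
    converged[0] = check0.satisfied
    residuals[0] = check0.residual
    duals[0] = dual_objective(np.zeros(m), problem, reg, schedule.values[0])

    w_prev = np.zeros(m)
    for l in range(1, L):
        t = float(schedule.values[l])
        result: SolveResult = solve(
            problem, reg, t,
            init_w=w_prev, init_z=w_prev,
            config=config, method=method,
        )
        ws[:, l] = result.w
        ps[:, l] = result.p
        converged[l] = result.converged
        iterations[l] = result.iterations
        residuals[l] = (
            result.residual_history[-1] if result.residual_history.size else np.nan
        )
        duals[l] = result.dual_objective
        if not result.converged:
            logger.warning("path point l=%d (t=%g) did not converge", l, t)
        w_prev = result.w
    return PathResult(
        schedule=schedule,
        ws=ws,
        ps=ps,
        converged=converged,
        iterations=iterations,
        residuals=residuals,
        dual_objectives=duals,
        reg=reg,
    )


@dataclass
class SparsityProfile:
    """Raw and cumulative nonzero counts plus group activation points.

    ``first_activation`` maps each group label to the index ``l`` of the
    first path point where some coefficient of the group exceeds the zero
    tolerance (None if the group never activates); ``first_activation_ratio``
    gives the corresponding ``t/t_max``.
    """

    raw_counts: np.ndarray
    cumulative_counts: np.ndarray
    first_activation: dict
    first_activation_ratio: dict
    group_counts: dict


def nonzero_profile(result: PathResult, zero_tol: float = 1e-8) -> SparsityProfile:
    """Count nonzero coefficients per path point, raw and cumulative."""
    if zero_tol <= 0:
        raise InvalidInputError("zero_tol must be positive")
    active = np.abs(result.ws) > zero_tol  # (m, L)
    raw = active.sum(axis=0)
    ever_active = np.logical_or.accumulate(active, axis=1)
    cumulative = ever_active.sum(axis=0)

    ratios = result.t_over_tmax
    first_activation: dict = {}
    first_ratio: dict = {}
    group_counts: dict = {}
    reg = result.reg
    if reg is not None and reg.kind == "group_lasso" and reg.groups is not None:
        items = zip(reg.groups.group_labels, reg.groups.indices)
    else:
        # one singleton "group" per feature, keyed by row index
        m = result.ws.shape[0]
        items = ((i, np.array([i])) for i in range(m))
    for label, idx in items:
        hits = np.flatnonzero(active[idx, :].any(axis=0))
        if hits.size:
            l0 = int(hits[0])
            first_activation[label] = l0
            first_ratio[label] = float(ratios[l0])
        else:
            first_activation[label] = None
            first_ratio[label] = None
        group_counts[label] = active[idx, :].sum(axis=0)
    return SparsityProfile(
        raw_counts=raw,
        cumulative_counts=cumulative,
        first_activation=first_activation,
        first_activation_ratio=first_ratio,
        group_counts=group_counts,
    )
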