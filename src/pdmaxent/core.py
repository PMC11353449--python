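"""Problem data and shared numerics for discrete maximum-entropy estimation.

The estimation problem over ``n`` discrete sites with ``m`` features is

    min_{p in simplex}  KL(p || prior) + t * Hstar((b - A p) / t),

where ``A`` maps a site distribution ``p`` to its feature-average vector
``A p = sum_j p(j) phi(j)``, ``b`` is the empirical feature average and
``Hstar`` a convex potential penalising the average mismatch.  This module
provides the feature operator with its cached norms, probability-vector
utilities (Gibbs distributions, KL divergence) and the primal/dual
objective values.  The penalties themselves live in
:mod:`pdmaxent.regularizers`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConvergenceError, InvalidInputError, InvalidPriorError

if TYPE_CHECKING:  # pragma: no cover
    from .regularizers import RegularizerSpec

__all__ = [
    "FeatureMatrix",
    "MaxEntProblem",
    "as_distribution",
    "validate_prior",
    "floor_prior",
    "gibbs_distribution",
    "model_average",
    "kl_divergence",
    "operator_norm_max_column",
    "spectral_norm",
    "primal_objective",
    "dual_objective",
]

#: Mass-conservation tolerance for probability vectors.
SIMPLEX_ATOL = 1e-12


@dataclass(frozen=True)
class FeatureMatrix:
    """An ``m x n`` feature matrix (rows = features, columns = sites).

    Parameters
    ----------
    values
        Dense array of shape ``(m, n)``; all entries must be finite.
    names
        Optional feature names, one per row.
    """

    values: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise InvalidInputError("feature matrix must be 2-dimensional")
        if values.shape[0] < 1 or values.shape[1] < 2:
            raise InvalidInputError(
                f"need m >= 1 features and n >= 2 sites, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", values)
        if self.names is not None:
            names = tuple(str(s) for s in self.names)
            if len(names) != values.shape[0]:
                raise InvalidInputError(
                    f"{len(names)} feature names for {values.shape[0]} features"
                )
            object.__setattr__(self, "names", names)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @cached_property
    def op_norm(self) -> float:
        """Maximum Euclidean column norm (the ell1 -> ell2 induced norm)."""
        return operator_norm_max_column(self)

    @cached_property
    def spec_norm(self) -> float:
        """Largest singular value, computed lazily by power iteration."""
        return spectral_norm(self)

    def feature_names(self) -> tuple[str, ...]:
        if self.names is not None:
            return self.names
        return tuple(f"f{i}" for i in range(self.m))


def as_distribution(p: np.ndarray, *, name: str = "distribution") -> np.ndarray:
    """Validate and return a probability vector (nonnegative, sums to one)."""
    p = np.asarray(p, dtype=float).ravel()
    if not np.all(np.isfinite(p)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    if np.any(p < 0):
        raise InvalidInputError(f"{name} has negative entries")
    total = p.sum()
    if abs(total - 1.0) > 1e-8:
        raise InvalidInputError(f"{name} sums to {total!r}, expected 1")
    if abs(total - 1.0) > SIMPLEX_ATOL:
        p = p / total
    return p


def validate_prior(prior: np.ndarray) -> np.ndarray:
    """Validate a prior: a strictly positive point of the simplex interior."""
    prior = as_distribution(prior, name="prior")
    if np.any(prior <= 0):
        raise InvalidPriorError("prior must be strictly positive on every site")
    return prior


def floor_prior(prior: np.ndarray, floor: float = 1e-300) -> np.ndarray:
    """Clamp prior entries below ``floor`` and renormalize.

    Off by default everywhere; use explicitly when a supplied prior has
    zero or denormal entries that should be treated as "very unlikely"
    rather than impossible.
    """
    prior = np.asarray(prior, dtype=float).ravel()
    clamped = np.maximum(prior, floor)
    return clamped / clamped.sum()


@dataclass(frozen=True)
class MaxEntProblem:
    """Bundle of problem data: features, strictly positive prior, empirical.

    ``empirical_avg`` (the vector of empirical feature averages) is computed
    once and cached.
    """

    features: FeatureMatrix
    prior: np.ndarray
    empirical: np.ndarray
    empirical_avg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not isinstance(self.features, FeatureMatrix):
            object.__setattr__(self, "features", FeatureMatrix(self.features))
        prior = validate_prior(self.prior)
        empirical = as_distribution(self.empirical, name="empirical")
        n = self.features.n
        if prior.size != n or empirical.size != n:
            raise InvalidInputError(
                f"prior/empirical of sizes {prior.size}/{empirical.size} "
                f"do not match n={n} sites"
            )
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "empirical", empirical)
        object.__setattr__(
            self, "empirical_avg", model_average(empirical, self.features)
        )

    @property
    def m(self) -> int:
        return self.features.m

    @property
    def n(self) -> int:
        return self.features.n

    @cached_property
    def prior_avg(self) -> np.ndarray:
        """Feature averages under the prior."""
        return model_average(self.prior, self.features)

    def gibbs(self, z: np.ndarray) -> np.ndarray:
        return gibbs_distribution(z, self)


def gibbs_distribution(z: np.ndarray, problem: MaxEntProblem) -> np.ndarray:
    """Gibbs distribution ``p(j) \\propto prior(j) * exp(<z, phi(j)>)``.

    Stabilized by max-subtraction so that dual vectors with norms up to
    ~1e3 do not overflow.
    """
    z = np.asarray(z, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("dual vector contains non-finite entries")
    if z.size != problem.m:
        raise InvalidInputError(f"dual vector of size {z.size}, expected {problem.m}")
    log_unnorm = np.log(problem.prior) + z @ problem.features.values
    log_unnorm -= log_unnorm.max()
    p = np.exp(log_unnorm)
    return p / p.sum()


def model_average(p: np.ndarray, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Feature-average vector ``sum_j p(j) phi(j)`` (linear in ``p``)."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    p = np.asarray(p, dtype=float).ravel()
    if p.size != values.shape[1]:
        raise InvalidInputError(
            f"distribution of size {p.size} does not match n={values.shape[1]}"
        )
    return values @ p


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence ``sum_j p(j) log(p(j)/q(j))`` in nats.

    Uses the ``0 * log 0 = 0`` convention.  Returns ``inf`` when some site
    has ``p(j) > 0`` but ``q(j) = 0``.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.size != q.size:
        raise InvalidInputError("distributions of different sizes")
    mask = p > 0
    if np.any(q[mask] <= 0):
        return math.inf
    ps, qs = p[mask], q[mask]
    return float(np.sum(ps * np.log(ps / qs)))


def operator_norm_max_column(features: FeatureMatrix | np.ndarray) -> float:
    """Exact max Euclidean column norm, in a single O(mn) pass."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if values.size == 0:
        raise InvalidInputError("empty feature matrix")
    return float(np.sqrt(np.max(np.einsum("ij,ij->j", values, values))))


def spectral_norm(
    features: FeatureMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> float:
    """Largest singular value via power iteration on the Gram matrix.

    Deterministic: starts from the normalized all-ones vector on the
    smaller side of the matrix.  Raises :class:`ConvergenceError` if the
    relative change in the estimate does not fall below ``tol`` within
    ``max_iter`` iterations.
    """
    if tol <= 0:
        raise InvalidInputError("tol must be positive")
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    m, n = values.shape
    # iterate on the smaller Gram side for O(min(m,n)) vectors
    A = values if m <= n else values.T
    v = np.ones(A.shape[0]) / math.sqrt(A.shape[0])
    sigma2 = 0.0
    for k in range(max_iter):
        u = A @ (A.T @ v)
        norm = np.linalg.norm(u)
        if norm == 0.0:
            return 0.0
        v = u / norm
        prev, sigma2 = sigma2, float(v @ (A @ (A.T @ v)))
        if k > 0 and abs(sigma2 - prev) <= tol * max(sigma2, 1e-300):
            return math.sqrt(sigma2)
    raise ConvergenceError(
        f"power iteration did not reach relative tolerance {tol:g} within "
        f"{max_iter} iterations (last estimate {math.sqrt(sigma2):.6g})"
    )


def primal_objective(
    p: np.ndarray,
    problem: MaxEntProblem,
    reg: "RegularizerSpec",
    t: float,
    feas_tol: float = 1e-8,
) -> float:
    """Primal value ``KL(p || prior) + t * Hstar((b - A p)/t)``.

    For the constraint-type potentials (group lasso, ell-infinity) the
    value is ``inf`` when the average mismatch is infeasible beyond
    ``feas_tol``; the sentinel is ``math.inf``, never a silent overflow.
    """
    if t <= 0:
        raise InvalidInputError("hyperparameter t must be positive")
    p = as_distribution(p)
    u = problem.empirical_avg - model_average(p, problem.features)
    kl = kl_divergence(p, problem.prior)
    if reg.kind == "elastic_net":
        hinge = np.maximum(0.0, np.abs(u) - t * reg.alpha)
        return kl + float(hinge @ hinge) / (2.0 * t * (1.0 - reg.alpha))
    if reg.kind == "group_lasso":
        for idx, wgt in zip(reg.groups.indices, reg.group_weights()):
            if np.linalg.norm(u[idx]) > t * wgt + feas_tol:
                return math.inf
        return kl
    if reg.kind == "linf":
        if np.abs(u).sum() > t + feas_tol:
            return math.inf
        return kl
    raise InvalidInputError(f"unknown regularizer kind {reg.kind!r}")


def dual_objective(
    w: np.ndarray,
    problem: MaxEntProblem,
    reg: "RegularizerSpec",
    t: float,
) -> float:
    """Dual value ``<w, b> - t H(w) - log sum_j prior(j) exp(<w, phi(j)>)``."""
    from .regularizers import regularizer_value

    if t < 0:
        raise InvalidInputError("hyperparameter t must be nonnegative")
    w = np.asarray(w, dtype=float).ravel()
    lse = float(logsumexp(w @ problem.features.values, b=problem.prior))
    return float(w @ problem.empirical_avg) - t * regularizer_value(w, reg) - lse
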