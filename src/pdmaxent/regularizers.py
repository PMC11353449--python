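"""Penalty definitions: proximal operators, path starts and stopping rules.

Three dual penalties ``H`` are supported:

* ``elastic_net``:  ``H(w) = alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2``
* ``group_lasso``:  ``H(w) = sum_g sqrt(m_g) * ||w_g||_2`` over a partition
  of the features into non-overlapping groups
* ``linf``:         ``H(w) = ||w||_inf``

Each comes with a closed-form proximal operator, the smallest
hyperparameter ``t_max`` at which the zero dual vector is optimal, and the
optimality-condition residual used as the solver stopping rule.

The group multiplier defaults to ``sqrt(m_g)`` (penalty, prox threshold and
``t_max`` divisor alike); set ``group_weighting="size"`` on the spec to use
the literal group size ``m_g`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .core import MaxEntProblem, model_average
from .exceptions import InvalidInputError

__all__ = [
    "GroupStructure",
    "RegularizerSpec",
    "elastic_net",
    "group_lasso",
    "linf",
    "soft_threshold",
    "prox_elastic_net",
    "prox_group_lasso",
    "project_l1_ball",
    "prox_linf",
    "prox",
    "regularizer_value",
    "t_max",
    "optimality_residual",
    "ResidualCheck",
]

Kind = Literal["elastic_net", "group_lasso", "linf"]


@dataclass(frozen=True)
class GroupStructure:
    """Non-overlapping partition of the m features into G groups.

    Built from a length-m sequence of arbitrary group labels; groups are
    ordered by first appearance.
    """

    labels: tuple
    indices: tuple = None  # type: ignore[assignment]
    sizes: tuple[int, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = tuple(np.asarray(self.labels).tolist())
        if len(labels) == 0:
            raise InvalidInputError("group structure needs at least one feature")
        order: dict = {}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        arrs = [
            np.flatnonzero(np.array([l == g for l in labels], dtype=bool))
            for g in order
        ]
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "indices", tuple(arrs))
        object.__setattr__(self, "sizes", tuple(int(a.size) for a in arrs))

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(self.sizes)

    @property
    def group_labels(self) -> tuple:
        """Distinct labels in group order."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)


@dataclass(frozen=True)
class RegularizerSpec:
    """Which penalty to use, with its parameters.

    ``gamma`` is the smoothness modulus of the potential used by the
    linear-rate solver: ``1 - alpha`` for the elastic net, 0 (non-smooth)
    otherwise.
    """

    kind: Kind
    alpha: float | None = None
    groups: GroupStructure | None = None
    group_weighting: Literal["sqrt", "size"] = "sqrt"

    def __post_init__(self) -> None:
        if self.kind == "elastic_net":
            if self.alpha is None or not 0.0 < float(self.alpha) < 1.0:
                raise InvalidInputError("elastic net requires alpha in (0, 1)")
        elif self.kind == "group_lasso":
            if self.groups is None:
                raise InvalidInputError("group lasso requires a GroupStructure")
        elif self.kind != "linf":
            raise InvalidInputError(f"unknown regularizer kind {self.kind!r}")

    @property
    def gamma(self) -> float:
        return 1.0 - self.alpha if self.kind == "elastic_net" else 0.0

    def group_weights(self) -> np.ndarray:
        if self.groups is None:
            raise InvalidInputError("no group structure on this regularizer")
        sizes = np.asarray(self.groups.sizes, dtype=float)
        return np.sqrt(sizes) if self.group_weighting == "sqrt" else sizes

    def validate_m(self, m: int) -> None:
        if self.kind == "group_lasso" and self.groups.m != m:
            raise InvalidInputError(
                f"group structure covers {self.groups.m} features, problem has {m}"
            )


def elastic_net(alpha: float) -> RegularizerSpec:
    return RegularizerSpec(kind="elastic_net", alpha=float(alpha))


def group_lasso(labels, weighting: Literal["sqrt", "size"] = "sqrt") -> RegularizerSpec:
    groups = labels if isinstance(labels, GroupStructure) else GroupStructure(labels)
    return RegularizerSpec(kind="group_lasso", groups=groups, group_weighting=weighting)


def linf() -> RegularizerSpec:
    return RegularizerSpec(kind="linf")


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Componentwise ``sign(v) * max(0, |v| - lam)``."""
    if lam < 0:
        raise InvalidInputError("soft-threshold parameter must be nonnegative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def prox_elastic_net(v: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    """Minimizer of ``lam*(alpha*||w||_1 + (1-alpha)/2*||w||_2^2) + ||w - v||^2/2``."""
    if not 0.0 <= alpha <= 1.0:
        raise InvalidInputError("alpha must lie in [0, 1]")
    if lam < 0:
        raise InvalidInputError("prox parameter must be nonnegative")
    return soft_threshold(v, lam * alpha) / (1.0 + lam * (1.0 - alpha))


def prox_group_lasso(
    v: np.ndarray,
    lam: float,
    groups: GroupStructure,
    weighting: Literal["sqrt", "size"] = "sqrt",
) -> np.ndarray:
    """Blockwise shrinkage ``max(0, 1 - lam*w_g/||v_g||) * v_g`` per group.

    A block with ``||v_g|| <= lam * w_g`` (including the zero block) maps
    to zero.
    """
    if lam < 0:
        raise InvalidInputError("prox parameter must be nonnegative")
    v = np.asarray(v, dtype=float).ravel()
    if groups.m != v.size:
        raise InvalidInputError(
            f"group structure covers {groups.m} features, input has {v.size}"
        )
    sizes = np.asarray(groups.sizes, dtype=float)
    weights = np.sqrt(sizes) if weighting == "sqrt" else sizes
    out = np.empty_like(v)
    for idx, wgt in zip(groups.indices, weights):
        block = v[idx]
        norm = np.linalg.norm(block)
        if norm <= lam * wgt:
            out[idx] = 0.0
        else:
            out[idx] = (1.0 - lam * wgt / norm) * block
    return out


def project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of ``v`` onto ``{w : ||w||_1 <= radius}``.

    Sort-based simplex thresholding, O(m log m).
    """
    if radius <= 0:
        raise InvalidInputError("l1-ball radius must be positive")
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("cannot project a non-finite vector")
    a = np.abs(v)
    if a.sum() <= radius:
        return v.copy()
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    j = np.arange(1, v.size + 1)
    rho = np.max(np.flatnonzero(u > (css - radius) / j))
    theta = (css[rho] - radius) / (rho + 1.0)
    return np.sign(v) * np.maximum(a - theta, 0.0)


def prox_linf(v: np.ndarray, lam: float) -> np.ndarray:
    """Prox of ``lam * ||.||_inf`` via Moreau: ``v - P_{l1 ball(lam)}(v)``."""
    if lam <= 0:
        raise InvalidInputError("prox parameter must be positive")
    v = np.asarray(v, dtype=float).ravel()
    return v - project_l1_ball(v, lam)


def prox(spec: RegularizerSpec, v: np.ndarray, lam: float) -> np.ndarray:
    """Proximal operator of ``lam * H`` for the spec's penalty ``H``."""
    if spec.kind == "elastic_net":
        return prox_elastic_net(v, lam, spec.alpha)
    if spec.kind == "group_lasso":
        return prox_group_lasso(v, lam, spec.groups, spec.group_weighting)
    if lam == 0:
        return np.asarray(v, dtype=float).copy()
    return prox_linf(v, lam)


def regularizer_value(w: np.ndarray, spec: RegularizerSpec) -> float:
    """Penalty value ``H(w)``; nonnegative, zero at the origin."""
    w = np.asarray(w, dtype=float).ravel()
    if spec.kind == "elastic_net":
        return float(
            spec.alpha * np.abs(w).sum() + 0.5 * (1.0 - spec.alpha) * (w @ w)
        )
    if spec.kind == "group_lasso":
        return float(
            sum(
                wgt * np.linalg.norm(w[idx])
                for idx, wgt in zip(spec.groups.indices, spec.group_weights())
            )
        )
    if spec.kind == "linf":
        return float(np.max(np.abs(w))) if w.size else 0.0
    raise InvalidInputError(f"unknown regularizer kind {spec.kind!r}")


def t_max(problem: MaxEntProblem, reg: RegularizerSpec) -> float:
    """Smallest hyperparameter at which ``(prior, 0)`` solves the problem.

    Computed from the optimality condition at the zero dual vector: with
    ``r = b - A prior``,

    * elastic net:  ``||r||_inf / alpha``
    * group lasso:  ``max_g ||r_g||_2 / weight_g``
    * ell-infinity: ``||r||_1``

    Returns 0 when the prior already matches the empirical averages.
    """
    reg.validate_m(problem.m)
    r = problem.empirical_avg - problem.prior_avg
    if reg.kind == "elastic_net":
        return float(np.max(np.abs(r)) / reg.alpha)
    if reg.kind == "group_lasso":
        return float(
            max(
                np.linalg.norm(r[idx]) / wgt
                for idx, wgt in zip(reg.groups.indices, reg.group_weights())
            )
        )
    return float(np.abs(r).sum())


class ResidualCheck(NamedTuple):
    residual: float
    threshold: float
    satisfied: bool


def optimality_residual(
    p: np.ndarray,
    w: np.ndarray,
    problem: MaxEntProblem,
    reg: RegularizerSpec,
    t: float,
    tol: float = 1e-5,
) -> ResidualCheck:
    """Stopping-rule residual for a primal/dual pair at hyperparameter ``t``.

    With ``r = b - A p``:

    * elastic net:  ``||r - t(1-alpha) w||_inf <= t*alpha*(1+tol)``
    * group lasso:  ``max_g ||r_g||_2 / weight_g <= t*(1+tol)``
    * ell-infinity: ``||r||_1 <= t*(1+tol)``
    """
    if t <= 0:
        raise InvalidInputError("hyperparameter t must be positive")
    r = problem.empirical_avg - model_average(p, problem.features)
    w = np.asarray(w, dtype=float).ravel()
    if reg.kind == "elastic_net":
        residual = float(np.max(np.abs(r - t * (1.0 - reg.alpha) * w)))
        threshold = t * reg.alpha * (1.0 + tol)
    elif reg.kind == "group_lasso":
        residual = float(
            max(
                np.linalg.norm(r[idx]) / wgt
                for idx, wgt in zip(reg.groups.indices, reg.group_weights())
            )
        )
        threshold = t * (1.0 + tol)
    else:
        residual = float(np.abs(r).sum())
        threshold = t * (1.0 + tol)
    return ResidualCheck(residual, threshold, residual <= threshold)
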