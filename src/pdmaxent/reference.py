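"""Dense reference minimizer of the primal problem, for cross-validation.

This is deliberately independent of the first-order solvers: it hands the
primal problem (with slack-variable reformulations of the non-smooth
constraints) to SciPy's SLSQP and is only meant for small instances.  Use
it to check that the fast solvers land on the right optimum, never as a
production path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .core import MaxEntProblem, kl_divergence
from .exceptions import ConvergenceError, InvalidInputError
from .regularizers import RegularizerSpec

__all__ = ["reference_primal_solution"]

_P_FLOOR = 1e-12


def _kl_and_grad(p: np.ndarray, prior: np.ndarray) -> tuple[float, np.ndarray]:
    ps = np.maximum(p, _P_FLOOR)
    val = float(np.sum(ps * np.log(ps / prior)))
    grad = np.log(ps / prior) + 1.0
    return val, grad


def reference_primal_solution(
    problem: MaxEntProblem,
    reg: RegularizerSpec,
    t: float,
    ftol: float = 1e-14,
    maxiter: int = 3000,
) -> tuple[np.ndarray, float]:
    """Minimize the primal by constrained dense optimization (SLSQP).

    Returns ``(p, objective_value)``.  Raises :class:`ConvergenceError`
    when SLSQP reports failure.
    """
    if t <= 0:
        raise InvalidInputError("hyperparameter t must be positive")
    Phi = problem.features.values
    b = problem.empirical_avg
    prior = problem.prior
    m, n = Phi.shape

    if reg.kind == "elastic_net":
        alpha = reg.alpha
        scale = 1.0 / (2.0 * t * (1.0 - alpha))

        # d/dp of scale*sum h^2 with u = b - Phi p is -Phi^T (2*scale*h*sign(u))
        def fun(p):
            kl, grad_kl = _kl_and_grad(p, prior)
            u = b - Phi @ p
            h = np.maximum(0.0, np.abs(u) - t * alpha)
            val = kl + scale * float(h @ h)
            grad = grad_kl - Phi.T @ (2.0 * scale * h * np.sign(u))
            return val, grad

        res = minimize(
            fun,
            prior.copy(),
            jac=True,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n,
            constraints=[
                {"type": "eq", "fun": lambda p: p.sum() - 1.0,
                 "jac": lambda p: np.ones(n)},
            ],
            options={"ftol": ftol, "maxiter": maxiter},
        )
        if not res.success:
            raise ConvergenceError(f"SLSQP failed: {res.message}")
        p = np.maximum(res.x, 0.0)
        p /= p.sum()
        return p, float(res.fun)

    if reg.kind == "group_lasso":
        weights = reg.group_weights()

        def fun(p):
            return _kl_and_grad(p, prior)

        constraints = [
            {"type": "eq", "fun": lambda p: p.sum() - 1.0,
             "jac": lambda p: np.ones(n)},
        ]
        for idx, wgt in zip(reg.groups.indices, weights):
            Pg = Phi[idx, :]
            bg = b[idx]
            cap = (t * wgt) ** 2

            def cons(p, Pg=Pg, bg=bg, cap=cap):
                ug = bg - Pg @ p
                return cap - float(ug @ ug)

            def cons_jac(p, Pg=Pg, bg=bg):
                ug = bg - Pg @ p
                return 2.0 * (Pg.T @ ug)

            constraints.append({"type": "ineq", "fun": cons, "jac": cons_jac})
        res = minimize(
            fun,
            prior.copy(),
            jac=True,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n,
            constraints=constraints,
            options={"ftol": ftol, "maxiter": maxiter},
        )
        if not res.success:
            raise ConvergenceError(f"SLSQP failed: {res.message}")
        p = np.maximum(res.x, 0.0)
        p /= p.sum()
        return p, kl_divergence(p, prior)

    if reg.kind == "linf":
        # variables x = (p, s) with |b - Phi p|_i <= s_i and sum s <= t
        def fun(x):
            p = x[:n]
            kl, grad_kl = _kl_and_grad(p, prior)
            grad = np.concatenate([grad_kl, np.zeros(m)])
            return kl, grad

        def cons_upper(x):  # s - u >= 0 elementwise
            p, s = x[:n], x[n:]
            return s - (b - Phi @ p)

        def cons_upper_jac(x):
            return np.hstack([Phi, np.eye(m)])

        def cons_lower(x):  # s + u >= 0 elementwise
            p, s = x[:n], x[n:]
            return s + (b - Phi @ p)

        def cons_lower_jac(x):
            return np.hstack([-Phi, np.eye(m)])

        def cons_budget(x):
            return t - x[n:].sum()

        def cons_budget_jac(x):
            g = np.zeros(n + m)
            g[n:] = -1.0
            return g

        u0 = np.abs(b - Phi @ prior)
        x0 = np.concatenate([prior.copy(), u0 + 1e-6])
        res = minimize(
            fun,
            x0,
            jac=True,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n + [(0.0, None)] * m,
            constraints=[
                {"type": "eq", "fun": lambda x: x[:n].sum() - 1.0,
                 "jac": lambda x: np.concatenate([np.ones(n), np.zeros(m)])},
                {"type": "ineq", "fun": cons_upper, "jac": cons_upper_jac},
                {"type": "ineq", "fun": cons_lower, "jac": cons_lower_jac},
                {"type": "ineq", "fun": cons_budget, "jac": cons_budget_jac},
            ],
            options={"ftol": ftol, "maxiter": maxiter},
        )
        if not res.success:
            raise ConvergenceError(f"SLSQP failed: {res.message}")
        p = np.maximum(res.x[:n], 0.0)
        p /= p.sum()
        return p, kl_divergence(p, prior)

    raise InvalidInputError(f"unknown regularizer kind {reg.kind!r}")
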