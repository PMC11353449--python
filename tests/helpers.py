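"""Independent numeric oracles shared by the test modules.

Each prox oracle minimizes the defining objective
``lam * H(w) + ||w - v||^2 / 2`` through a smooth slack-variable
reformulation handed to SLSQP — a code path entirely separate from the
closed-form operators under test.
"""

import numpy as np
from scipy.optimize import minimize


def _slsqp(fun, x0, cons, bounds=None):
    """SLSQP with fallback restarts; returns the best successful solution."""
    best = None
    for ftol, start in ((1e-14, x0), (1e-12, x0), (1e-12, np.zeros_like(x0))):
        res = minimize(fun, start, jac=True, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"ftol": ftol, "maxiter": 1000})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    assert best is not None, "SLSQP failed from every start"
    return best


def oracle_soft_threshold(v, lam):
    """min over w of lam*||w||_1 + 0.5*||w - v||^2 via slacks |w_i| <= s_i."""
    return oracle_elastic_net(v, lam, 1.0)


def oracle_elastic_net(v, lam, alpha):
    v = np.asarray(v, dtype=float).ravel()
    m = v.size

    def fun(x):
        w, s = x[:m], x[m:]
        val = lam * (alpha * s.sum() + 0.5 * (1 - alpha) * (w @ w)) + 0.5 * np.sum(
            (w - v) ** 2
        )
        grad = np.concatenate(
            [lam * (1 - alpha) * w + (w - v), np.full(m, lam * alpha)]
        )
        return val, grad

    cons = [
        {"type": "ineq", "fun": lambda x: x[m:] - x[:m],
         "jac": lambda x: np.hstack([-np.eye(m), np.eye(m)])},
        {"type": "ineq", "fun": lambda x: x[m:] + x[:m],
         "jac": lambda x: np.hstack([np.eye(m), np.eye(m)])},
    ]
    x0 = np.concatenate([v, np.abs(v)])
    res = _slsqp(fun, x0, cons)
    return res.x[:m]


def oracle_group_lasso(v, lam, indices, weights):
    """Blockwise: each block solved by 1-D minimization over its norm."""
    v = np.asarray(v, dtype=float).ravel()
    out = np.empty_like(v)
    for idx, wgt in zip(indices, weights):
        block = v[idx]
        norm = np.linalg.norm(block)
        if norm == 0.0:
            out[idx] = 0.0
            continue
        # optimal w is colinear with the block: w = r * block/norm, r >= 0
        def fun(r):
            return lam * wgt * r[0] + 0.5 * (r[0] - norm) ** 2

        res = minimize(fun, [norm], method="SLSQP", bounds=[(0.0, None)],
                       options={"ftol": 1e-16, "maxiter": 200})
        assert res.success, res.message
        out[idx] = res.x[0] * block / norm
    return out


def oracle_project_l1(v, radius):
    v = np.asarray(v, dtype=float).ravel()
    m = v.size

    def fun(x):
        w = x[:m]
        return 0.5 * np.sum((w - v) ** 2), np.concatenate([w - v, np.zeros(m)])

    cons = [
        {"type": "ineq", "fun": lambda x: x[m:] - x[:m],
         "jac": lambda x: np.hstack([-np.eye(m), np.eye(m)])},
        {"type": "ineq", "fun": lambda x: x[m:] + x[:m],
         "jac": lambda x: np.hstack([np.eye(m), np.eye(m)])},
        {"type": "ineq", "fun": lambda x: radius - x[m:].sum(),
         "jac": lambda x: np.concatenate([np.zeros(m), -np.ones(m)])},
    ]
    x0 = np.concatenate([np.zeros(m), np.full(m, radius / m)])
    res = _slsqp(fun, x0, cons)
    return res.x[:m]


def oracle_prox_linf(v, lam):
    """min lam*max_i|w_i| + 0.5||w-v||^2 via a scalar bound variable."""
    v = np.asarray(v, dtype=float).ravel()
    m = v.size

    def fun(x):
        w, u = x[:m], x[m]
        grad = np.concatenate([w - v, [lam]])
        return lam * u + 0.5 * np.sum((w - v) ** 2), grad

    cons = [
        {"type": "ineq", "fun": lambda x: x[m] - x[:m],
         "jac": lambda x: np.hstack([-np.eye(m), np.ones((m, 1))])},
        {"type": "ineq", "fun": lambda x: x[m] + x[:m],
         "jac": lambda x: np.hstack([np.eye(m), np.ones((m, 1))])},
    ]
    x0 = np.concatenate([v, [np.max(np.abs(v)) if m else 0.0]])
    res = _slsqp(fun, x0, cons)
    return res.x[:m]


def brute_force_model_average(p, values):
    """Elementwise double-loop feature averaging."""
    m, n = values.shape
    out = np.zeros(m)
    for i in range(m):
        for j in range(n):
            out[i] += p[j] * values[i, j]
    return out


def brute_force_kl(p, q):
    total = 0.0
    for pj, qj in zip(p, q):
        if pj > 0:
            total += pj * np.log(pj / qj)
    return total
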