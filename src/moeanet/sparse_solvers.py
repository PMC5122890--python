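"""Nonnegative lasso: the single-objective baseline and the MOEA seed oracle.

The penalized problem solved per node is

    min_{x >= 0}  (1 / 2m) ||Y - A x||_2^2  +  lam ||x||_1

i.e. the standard coordinate-descent lasso scaling with an added
nonnegativity constraint (link weights are 0 or >= 1, so sign freedom is
meaningless).  The squared, m-normalized error term puts useful lam values
on a data-independent scale; the unnormalized error/sparsity tradeoff that
the multiobjective model optimizes is recovered exactly by re-evaluating
returned weight vectors.

The numerical solver is scikit-learn's coordinate-descent ``Lasso`` with
``positive=True`` (lam = 0 falls back to nonnegative least squares); support
recovery is cross-checked in the test suite against exhaustive support
enumeration on small systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .linear_system import LocalSystem

__all__ = [
    "SparseSolution",
    "null_threshold",
    "lasso_solve",
    "lasso_path",
    "kkt_violation",
]


@dataclass
class SparseSolution:
    """One nonnegative lasso fit: weights plus the two raw objective values."""

    weights: np.ndarray
    lam: float
    error_term: float  # ||Y - A x||_2 (unsquared, unnormalized)
    l1_term: float     # ||x||_1
    n_iter: int
    converged: bool


def null_threshold(system: LocalSystem) -> float:
    """Smallest lam at which the nonnegative lasso solution is identically zero:
    max_j (A_j^T Y) / m (one-sided because of the positivity constraint)."""
    return float(np.max(system.A.T @ system.Y) / system.m)


def _solution(system: LocalSystem, w: np.ndarray, lam: float, n_iter: int,
              converged: bool) -> SparseSolution:
    w = np.asarray(w, dtype=float)
    resid = system.Y - system.A @ w
    return SparseSolution(
        weights=w,
        lam=float(lam),
        error_term=float(np.linalg.norm(resid)),
        l1_term=float(np.sum(np.abs(w))),
        n_iter=int(n_iter),
        converged=bool(converged),
    )


def lasso_solve(system: LocalSystem, lam: float, tol: float = 1e-8,
                max_iter: int = 10_000) -> SparseSolution:
    """Solve the nonnegative lasso at a single penalty ``lam``.

    Non-convergence is reported through ``converged=False`` rather than an
    exception.  lam = 0 is the penalty-free limit, solved by NNLS.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0; got {lam}")
    if lam == 0.0:
        w, _ = nnls(system.A, system.Y)
        return _solution(system, w, 0.0, n_iter=1, converged=True)
    est = Lasso(alpha=lam, fit_intercept=False, positive=True, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(system.A, system.Y)
    n_iter = int(np.atleast_1d(est.n_iter_)[0])
    return _solution(system, est.coef_, lam, n_iter=n_iter, converged=n_iter < max_iter)


def lasso_path(system: LocalSystem, lams, tol: float = 1e-8,
               max_iter: int = 10_000) -> list[SparseSolution]:
    """Solve the nonnegative lasso along a grid of penalties.

    Internally solved in decreasing-lam order with warm starts; the output
    order matches the input order.
    """
    lams = list(lams)
    if not lams:
        raise ValueError("lams must be nonempty")
    order = sorted(range(len(lams)), key=lambda k: -lams[k])
    out: list[SparseSolution | None] = [None] * len(lams)
    est = None
    cache: dict[float, SparseSolution] = {}
    for k in order:
        lam = float(lams[k])
        if lam in cache:
            sol = cache[lam]
        elif lam == 0.0:
            sol = lasso_solve(system, 0.0, tol=tol, max_iter=max_iter)
        else:
            if est is None:
                est = Lasso(alpha=lam, fit_intercept=False, positive=True, tol=tol,
                            max_iter=max_iter, warm_start=True)
            est.alpha = lam
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(system.A, system.Y)
            n_iter = int(np.atleast_1d(est.n_iter_)[0])
            sol = _solution(system, est.coef_.copy(), lam, n_iter, n_iter < max_iter)
        cache[lam] = sol
        out[k] = sol
    return out  # type: ignore[return-value]


def kkt_violation(system: LocalSystem, solution: SparseSolution) -> float:
    """Maximum violation of the nonnegative-lasso KKT conditions.

    With g_j = A_j^T (Y - A x) / m, optimality requires g_j <= lam whenever
    x_j = 0 and g_j = lam whenever x_j > 0.  Returns the largest one-sided
    slack, 0 at an exact optimum.
    """
    g = system.A.T @ (system.Y - system.A @ solution.weights) / system.m
    active = solution.weights > 0
    viol = 0.0
    if np.any(~active):
        viol = max(viol, float(np.max(g[~active]) - solution.lam))
    if np.any(active):
        viol = max(viol, float(np.max(np.abs(g[active] - solution.lam))))
    return max(viol, 0.0)
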