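"""Limited-memory BFGS with two-loop recursion and backtracking line search.

A small, self-contained quasi-Newton engine used both for the 1-D fusion
weight and the 2-D logistic-curve fit.  The inverse-Hessian action is
reconstructed from the most recent ``memory`` (s, y) displacement/
gradient-difference pairs by the standard two-loop recursion; the step is
chosen by backtracking until the Armijo sufficient-decrease condition
holds.  Pairs with non-positive curvature ``s.y`` are discarded to keep
the approximation positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass
class LBFGSResult:
    x: np.ndarray
    fun: float
    grad: np.ndarray
    iterations: int
    converged: bool


def _two_loop(grad: np.ndarray, pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Apply the implicit inverse-Hessian approximation to ``grad``."""
    q = grad.copy()
    alphas = []
    rhos = []
    for s, y in reversed(pairs):
        rho = 1.0 / float(y @ s)
        a = rho * float(s @ q)
        q -= a * y
        alphas.append(a)
        rhos.append(rho)
    if pairs:
        s, y = pairs[-1]
        q *= float(s @ y) / float(y @ y)  # initial scaling H0 = gamma I
    for (s, y), a, rho in zip(pairs, reversed(alphas), reversed(rhos)):
        b = rho * float(y @ q)
        q += (a - b) * s
    return q


def lbfgs_minimize(
    fun: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    x0,
    *,
    eps: float = 1e-5,
    memory: int = 10,
    max_iter: int = 500,
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
    max_backtracks: int = 60,
) -> LBFGSResult:
    """Minimise ``fun`` from ``x0``; stop when ``||grad||_inf <= eps``.

    Parameters mirror the quasi-Newton scheme: ``memory`` is the number of
    stored (s, y) vector pairs, ``eps`` the gradient threshold, and the
    one-dimensional search is backtracking with Armijo constant
    ``armijo_c`` and step-shrink factor ``shrink``.
    """
    if eps <= 0 or memory < 1 or max_iter < 1:
        raise ValueError("eps > 0, memory >= 1 and max_iter >= 1 required")
    x = np.atleast_1d(np.asarray(x0, dtype=np.float64)).copy()
    f = float(fun(x))
    g = np.atleast_1d(np.asarray(grad(x), dtype=np.float64))
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite objective or gradient at start")
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    k = 0
    while np.max(np.abs(g)) > eps and k < max_iter:
        p = -_two_loop(g, pairs)
        if float(p @ g) >= 0:  # not a descent direction; reset to steepest descent
            pairs.clear()
            p = -g.copy()
        step = 1.0
        gp = float(g @ p)
        f_new, x_new = f, x
        for _ in range(max_backtracks):
            x_new = x + step * p
            f_new = float(fun(x_new))
            if np.isfinite(f_new) and f_new <= f + armijo_c * step * gp:
                break
            step *= shrink
        else:
            break  # line search failed; gradient is numerically flat
        g_new = np.atleast_1d(np.asarray(grad(x_new), dtype=np.float64))
        s, y = x_new - x, g_new - g
        if float(s @ y) > 1e-12 * max(1.0, float(y @ y)):
            pairs.append((s, y))
            if len(pairs) > memory:
                pairs.pop(0)
        x, f, g = x_new, f_new, g_new
        k += 1
    return LBFGSResult(x=x, fun=f, grad=g, iterations=k, converged=bool(np.max(np.abs(g)) <= eps))
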