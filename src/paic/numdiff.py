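"""Central finite-difference gradients and Hessians.

Used as the fallback whenever a model does not supply analytic derivative
contracts.  Steps are relative: ``h_k = base * (1 + |theta_k|)`` with
``base = eps^(1/3)`` for first derivatives and ``eps^(1/4)`` for second
derivatives (the latter trades a slightly larger truncation error for much
smaller round-off amplification in the second-difference quotient).
"""
from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .model import DifferentiationError

_EPS = float(np.finfo(float).eps)
GRAD_STEP = _EPS ** (1.0 / 3.0)
HESS_STEP = _EPS ** 0.25


def _check(value: float, coord: str) -> float:
    if not np.isfinite(value):
        raise DifferentiationError(
            f"non-finite evaluation while differencing coordinate {coord}"
        )
    return value


def numeric_gradient(
    f: Callable[[np.ndarray], float],
    theta: np.ndarray,
    step: Optional[float] = None,
) -> np.ndarray:
    """Central-difference gradient of a scalar field."""
    theta = np.asarray(theta, dtype=float)
    base = GRAD_STEP if step is None else step
    h = base * (1.0 + np.abs(theta))
    g = np.empty(theta.size)
    for k in range(theta.size):
        e = np.zeros_like(theta)
        e[k] = h[k]
        fp = _check(f(theta + e), str(k))
        fm = _check(f(theta - e), str(k))
        g[k] = (fp - fm) / (2.0 * h[k])
    return g


def numeric_score_and_hessian(
    f: Callable[[np.ndarray], float],
    theta: np.ndarray,
    grad_step: Optional[float] = None,
    hess_step: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and symmetric Hessian of ``f`` at an interior point.

    Raises
    ------
    DifferentiationError
        If any stencil evaluation is non-finite; the message names the
        offending coordinate (or coordinate pair).
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    grad = numeric_gradient(f, theta, step=grad_step)

    base = HESS_STEP if hess_step is None else hess_step
    h = base * (1.0 + np.abs(theta))
    f0 = _check(f(theta), "center")
    H = np.empty((p, p))
    for k in range(p):
        e = np.zeros_like(theta)
        e[k] = h[k]
        fp = _check(f(theta + e), str(k))
        fm = _check(f(theta - e), str(k))
        H[k, k] = (fp - 2.0 * f0 + fm) / h[k] ** 2
    for j in range(p):
        for k in range(j + 1, p):
            ej = np.zeros_like(theta)
            ek = np.zeros_like(theta)
            ej[j] = h[j]
            ek[k] = h[k]
            pair = f"({j},{k})"
            fpp = _check(f(theta + ej + ek), pair)
            fpm = _check(f(theta + ej - ek), pair)
            fmp = _check(f(theta - ej + ek), pair)
            fmm = _check(f(theta - ej - ek), pair)
            H[j, k] = H[k, j] = (fpp - fpm - fmp + fmm) / (4.0 * h[j] * h[k])
    return grad, 0.5 * (H + H.T)
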