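"""Posterior mode search.

The mode maximises ``sum_i log g(y_i|theta) + log pi(theta)``.  Strictly
positive coordinates (variances and the like) are optimised on the log
scale, but the returned mode — and every derivative taken downstream —
lives in the model's declared coordinates: the trace bias correction is
invariant only under linear reparameterisations, so the coordinates the
model is declared in are part of its definition.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import optimize

from .model import (
    POSITIVE,
    BayesianModel,
    ModeNotConvergedError,
    ModeResult,
    PosteriorDraws,
)
from .numdiff import numeric_gradient


def _to_internal(theta: np.ndarray, positive: np.ndarray) -> np.ndarray:
    z = np.array(theta, dtype=float)
    z[positive] = np.log(z[positive])
    return z


def _from_internal(z: np.ndarray, positive: np.ndarray) -> np.ndarray:
    theta = np.array(z, dtype=float)
    # clip keeps exp() away from under/overflow when a line search overshoots
    theta[positive] = np.exp(np.clip(theta[positive], -300.0, 300.0))
    return theta


def _analytic_posterior_score(model: BayesianModel, theta: np.ndarray) -> np.ndarray:
    g = model.prior_score(theta).astype(float).copy()
    for i in range(model.n_obs):
        g += model.score(i, theta)
    return g


def find_posterior_mode(
    model: BayesianModel,
    draws: Optional[PosteriorDraws] = None,
    x0: Optional[np.ndarray] = None,
    gtol: float = 1e-8,
    accept_tol: float = 1e-5,
    maxiter: int = 500,
    boundary_tol: float = 1e-3,
) -> ModeResult:
    """Quasi-Newton maximisation of the unnormalised log posterior.

    Initialises at ``x0`` if given, otherwise at the posterior draw with
    the highest unnormalised log posterior.  Convergence targets an
    infinity-norm gradient of ``gtol`` (in the internal, log-transformed
    coordinates); a run that stalls with gradient norm below
    ``accept_tol`` is still accepted as converged.

    Raises
    ------
    ModeNotConvergedError
        After the iteration cap with gradient norm above ``accept_tol``;
        the error carries the best point found.
    """
    positive = np.array([d == POSITIVE for d in model.domain])

    if x0 is None:
        if draws is None:
            raise ValueError("either draws or x0 must be provided")
        logpost = model.loglik_matrix(draws.draws).sum(axis=1)
        logpost += model.logprior_per_draw(draws.draws)
        x0 = draws.draws[int(np.argmax(logpost))]
    x0 = np.asarray(x0, dtype=float)
    if np.any(positive & (x0 <= 0)):
        raise ValueError("initial point violates a strictly-positive domain")

    use_analytic = model.has_analytic_derivatives

    def negloglik(z: np.ndarray) -> float:
        theta = _from_internal(z, positive)
        val = model.log_unnorm_posterior(theta)
        # Large finite penalty keeps the line search inside the support.
        return -val if np.isfinite(val) else 1e300

    def neggrad(z: np.ndarray) -> np.ndarray:
        if use_analytic:
            theta = _from_internal(z, positive)
            g = _analytic_posterior_score(model, theta)
            return -np.where(positive, g * theta, g)  # chain rule, log coords
        # numeric fallback differentiates in the internal coordinates, so
        # the stencil never leaves a strictly-positive domain
        return -numeric_gradient(
            lambda zz: model.log_unnorm_posterior(_from_internal(zz, positive)),
            z,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # BFGS line-search chatter
        res = optimize.minimize(
            negloglik,
            _to_internal(x0, positive),
            jac=neggrad,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
    grad_norm = float(np.max(np.abs(res.jac)))
    theta_hat = _from_internal(res.x, positive)
    boundary = bool(np.any(positive & (theta_hat < boundary_tol)))
    mode = ModeResult(
        theta_hat=theta_hat,
        log_unnorm_post=float(-res.fun),
        grad_norm=grad_norm,
        converged=grad_norm <= accept_tol,
        boundary_flag=boundary,
    )
    if not mode.converged:
        raise ModeNotConvergedError(
            f"mode search stopped with gradient norm {grad_norm:.3e} "
            f"(tolerance {accept_tol:.1e})",
            best=mode,
        )
    if boundary:
        warnings.warn(
            "posterior mode has a strictly-positive coordinate within "
            f"{boundary_tol:g} of zero; curvature-based bias corrections "
            "are unreliable at the boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    return mode
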