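"""Model contracts and result containers.

A :class:`BayesianModel` is the contract every criterion in this package
evaluates against: a per-observation log density ``log g(y_i | theta)``, a
log prior ``log pi(theta)`` (possibly improper, represented as an additive
constant of zero with ``prior_proper=False``), parameter dimensions and
domains, and optional analytic derivatives and closed-form posterior
moments.  Posterior samples travel as a :class:`PosteriorDraws` matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

UNBOUNDED = "unbounded"
POSITIVE = "positive"


class PaicError(Exception):
    """Base class for errors raised by this package."""


class DifferentiationError(PaicError):
    """Finite differencing hit a non-finite evaluation."""


class ModeNotConvergedError(PaicError):
    """Posterior-mode search did not meet the gradient tolerance.

    Carries the best point found so far in ``best`` (a :class:`ModeResult`).
    """

    def __init__(self, message: str, best: Optional["ModeResult"] = None):
        super().__init__(message)
        self.best = best


class SingularInformationError(PaicError):
    """The empirical Hessian J_n is numerically singular."""


class ImproperPriorError(PaicError):
    """A criterion that needs a proper prior was asked to use an improper one."""


class SamplerConvergenceError(PaicError):
    """MCMC did not reach the configured split-R-hat target."""


@dataclass
class BayesianModel:
    """Contract for a Bayesian model with ``n_obs`` independent units.

    Parameters
    ----------
    n_obs : int
        Number of independent observation units n.
    dim : int
        Parameter dimension p (the cardinality K of theta).
    log_density : callable ``(i, theta) -> float``
        Per-observation log density log g(y_i | theta).
    log_prior : callable ``(theta) -> float``
        Log prior up to an additive constant.  For an improper flat prior
        return 0.0 and set ``prior_proper=False``.
    prior_proper : bool
        Whether pi(theta) is a proper density.  BPIC refuses improper priors.
    score, hessian : callables ``(i, theta) -> ndarray``, optional
        Analytic gradient (p,) and Hessian (p, p) of ``log_density`` in
        theta.  If any analytic contract is missing, central finite
        differences are used instead.
    prior_score, prior_hessian : callables ``(theta) -> ndarray``, optional
        Analytic gradient and Hessian of ``log_prior``.
    domain : sequence of {"unbounded", "positive"}, optional
        Per-coordinate domain descriptor; governs the optimizer transform.
    exact_moments : object, optional
        Closed-form posterior backend (see :class:`paic.conjugate.ConjugateMoments`
        for the methods recognised).  When present, posterior expectations
        are evaluated exactly and Monte-Carlo standard errors are zero.
    refit : callable ``(i) -> PosteriorDraws``, optional
        Leave-one-out refitting contract for exact cross-validation: returns
        draws from the posterior given all observations except unit ``i``
        (the parameter vector keeps its full layout).
    log_density_matrix : callable ``(draws) -> ndarray``, optional
        Vectorised evaluation returning the (S, n) matrix of per-draw,
        per-observation log densities.  Purely a fast path; must agree with
        ``log_density``.
    log_prior_vector : callable ``(draws) -> ndarray``, optional
        Vectorised log prior over an (S, p) draw matrix.
    param_names : sequence of str, optional
    """

    n_obs: int
    dim: int
    log_density: Callable[[int, np.ndarray], float]
    log_prior: Callable[[np.ndarray], float]
    prior_proper: bool = True
    score: Optional[Callable[[int, np.ndarray], np.ndarray]] = None
    hessian: Optional[Callable[[int, np.ndarray], np.ndarray]] = None
    prior_score: Optional[Callable[[np.ndarray], np.ndarray]] = None
    prior_hessian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    domain: Optional[Sequence[str]] = None
    exact_moments: Optional[object] = None
    refit: Optional[Callable[[int], "PosteriorDraws"]] = None
    log_density_matrix: Optional[Callable[[np.ndarray], np.ndarray]] = None
    log_prior_vector: Optional[Callable[[np.ndarray], np.ndarray]] = None
    param_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.domain is None:
            self.domain = (UNBOUNDED,) * self.dim
        self.domain = tuple(self.domain)
        if len(self.domain) != self.dim:
            raise ValueError("domain length must equal dim")
        for d in self.domain:
            if d not in (UNBOUNDED, POSITIVE):
                raise ValueError(f"unknown domain descriptor {d!r}")
        if self.param_names is None:
            self.param_names = tuple(f"theta{k}" for k in range(self.dim))
        self.param_names = tuple(self.param_names)

    # -- convenience evaluators -------------------------------------------
    @property
    def has_analytic_derivatives(self) -> bool:
        return all(
            f is not None
            for f in (self.score, self.hessian, self.prior_score, self.prior_hessian)
        )

    def loglik_vector(self, theta: np.ndarray) -> np.ndarray:
        """Per-observation log likelihood contributions at one point."""
        theta = np.asarray(theta, dtype=float)
        return np.array(
            [self.log_density(i, theta) for i in range(self.n_obs)], dtype=float
        )

    def log_unnorm_posterior(self, theta: np.ndarray) -> float:
        """log L(theta|y) + log pi(theta), up to an additive constant."""
        theta = np.asarray(theta, dtype=float)
        return float(self.loglik_vector(theta).sum() + self.log_prior(theta))

    def loglik_matrix(self, draws: np.ndarray) -> np.ndarray:
        """(S, n) matrix of log g(y_i | theta_s); vectorised when possible."""
        draws = np.atleast_2d(np.asarray(draws, dtype=float))
        if self.log_density_matrix is not None:
            out = np.asarray(self.log_density_matrix(draws), dtype=float)
            if out.shape != (draws.shape[0], self.n_obs):
                raise ValueError("log_density_matrix returned a wrong shape")
            return out
        out = np.empty((draws.shape[0], self.n_obs))
        for s, th in enumerate(draws):
            for i in range(self.n_obs):
                out[s, i] = self.log_density(i, th)
        return out

    def logprior_per_draw(self, draws: np.ndarray) -> np.ndarray:
        draws = np.atleast_2d(np.asarray(draws, dtype=float))
        if self.log_prior_vector is not None:
            return np.asarray(self.log_prior_vector(draws), dtype=float)
        return np.array([self.log_prior(th) for th in draws], dtype=float)


@dataclass
class PosteriorDraws:
    """An (S, p) matrix of post-warmup posterior samples with chain labels."""

    draws: np.ndarray
    chain_id: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] < 2:
            raise ValueError("at least 2 posterior draws are required")
        if self.chain_id is None:
            self.chain_id = np.zeros(self.draws.shape[0], dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype=int)
        if self.chain_id.shape != (self.draws.shape[0],):
            raise ValueError("chain_id must have one label per draw")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def dim(self) -> int:
        return self.draws.shape[1]

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        """Read draws from CSV: one column per parameter, optional `chain`."""
        df = pd.read_csv(path)
        chain = None
        if "chain" in df.columns:
            chain = df.pop("chain").to_numpy()
        return cls(draws=df.to_numpy(dtype=float), chain_id=chain)

    def to_csv(self, path, names: Optional[Sequence[str]] = None) -> None:
        names = list(names) if names is not None else [
            f"theta{k}" for k in range((self.dim))
        ]
        df = pd.DataFrame(self.draws, columns=names)
        df["chain"] = self.chain_id
        df.to_csv(path, index=False)


@dataclass
class ModeResult:
    """Posterior mode (in the model's declared coordinates)."""

    theta_hat: np.ndarray
    log_unnorm_post: float
    grad_norm: float
    converged: bool
    boundary_flag: bool = False


@dataclass
class InfoMatrices:
    """Empirical curvature/outer-product matrices at the posterior mode.

    ``J_n = -(1/n) sum_i H_i`` and ``I_n = (1/(n-1)) sum_i s_i s_i'`` where
    ``s_i`` and ``H_i`` are the gradient and Hessian of
    ``log g(y_i|theta) + (1/n) log pi(theta)`` evaluated at the mode.
    """

    J_n: np.ndarray
    I_n: np.ndarray
    cond_J: float


@dataclass
class CriterionResult:
    """One evaluated criterion on the -2 * (total log likelihood) scale.

    ``eta_hat_total`` is ``sum_i E_{theta|y}[log g(y_i|theta)]`` (so the
    per-observation estimator eta-hat is ``eta_hat_total / n_obs``);
    ``bias_total`` is n times the per-observation bias correction, and
    ``value = -2 * eta_hat_total + 2 * bias_total`` always reconstructs.
    """

    name: str
    eta_hat_total: float
    bias_total: float
    value: float
    per_obs: np.ndarray
    mc_se: float
    n_obs: int
    dim: int
    extras: dict = field(default_factory=dict)

    @property
    def eta_hat(self) -> float:
        return self.eta_hat_total / self.n_obs

    @property
    def bias(self) -> float:
        """Per-observation bias correction b."""
        return self.bias_total / self.n_obs

    def to_dict(self) -> dict:
        return {
            "criterion": self.name,
            "eta_hat_total": float(self.eta_hat_total),
            "bias_total": float(self.bias_total),
            "value": float(self.value),
            "mc_se": float(self.mc_se),
            "n_obs": int(self.n_obs),
            "dim": int(self.dim),
        }
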