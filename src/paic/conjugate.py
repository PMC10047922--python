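"""Conjugate normal-mean model with every quantity in closed form.

Data y_1..y_n ~ iid N(mu_T, sigma2_T) are analysed with the (possibly
misspecified) working model N(mu, sigma2_A), sigma2_A fixed, and a normal
prior mu ~ N(mu_0, tau2_0).  The posterior is N(mu_hat, sigma2_hat) with

    mu_hat     = (mu_0/tau2_0 + sum_i y_i/sigma2_A) / (1/tau2_0 + n/sigma2_A)
    sigma2_hat = 1 / (1/tau2_0 + n/sigma2_A)

so the posterior-averaged discrepancy eta, its in-sample estimator
eta_hat, all five bias estimators (PAIC, BPIC, WAIC2, penalized-loss popt,
leave-one-out CV) and the true expected bias b_mu = sigma2_T *
sigma2_hat / sigma2_A^2... are available analytically.  This module is the
exact oracle for the generic engine in :mod:`paic.criteria` and drives the
replication study of bias-estimator convergence.

An improper flat prior is represented by ``tau2_0 = inf``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import BayesianModel, PosteriorDraws

LOG2PI = math.log(2.0 * math.pi)

__all__ = [
    "NormalSetting",
    "NormalPosterior",
    "BiasEstimates",
    "StudyConfig",
    "posterior_params",
    "eta",
    "eta_hat",
    "bias_estimates",
    "true_bias",
    "make_model",
    "sample_exact_draws",
    "run_bias_study",
    "plot_bias_study",
]


@dataclass
class NormalSetting:
    """True, working-model and prior parameters for the normal case.

    ``tau2_0 = inf`` declares the improper flat prior on mu.
    """

    n: int
    mu_T: float = 0.0
    sigma2_T: float = 1.0
    sigma2_A: float = 1.0
    mu_0: float = 0.0
    tau2_0: float = 1e4

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("sigma2_T", "sigma2_A", "tau2_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def flat_prior(self) -> bool:
        return math.isinf(self.tau2_0)


@dataclass
class NormalPosterior:
    mu_hat: float
    sigma2_hat: float


@dataclass
class BiasEstimates:
    """The five per-observation bias estimators of the normal case."""

    paic: float
    bpic: float
    waic2: float
    popt: float
    cv: float


def posterior_params(setting: NormalSetting, y: np.ndarray) -> NormalPosterior:
    """Precision-weighted posterior mean and variance."""
    y = np.asarray(y, dtype=float)
    if y.size != setting.n:
        raise ValueError("length of y must equal setting.n")
    prec0 = 0.0 if setting.flat_prior else 1.0 / setting.tau2_0
    prec = prec0 + setting.n / setting.sigma2_A
    mu_hat = (prec0 * setting.mu_0 + y.sum() / setting.sigma2_A) / prec
    return NormalPosterior(mu_hat=float(mu_hat), sigma2_hat=float(1.0 / prec))


def eta(setting: NormalSetting, post: NormalPosterior) -> float:
    """Expected out-of-sample log density under the true N(mu_T, sigma2_T)."""
    s = setting
    return float(
        -0.5 * math.log(2.0 * math.pi * s.sigma2_A)
        - (s.sigma2_T + (s.mu_T - post.mu_hat) ** 2 + post.sigma2_hat)
        / (2.0 * s.sigma2_A)
    )


def eta_hat(
    setting: NormalSetting, y: np.ndarray, post: Optional[NormalPosterior] = None
) -> float:
    """In-sample posterior-mean log density (1/n) sum_i E log g(y_i|mu)."""
    y = np.asarray(y, dtype=float)
    post = post or posterior_params(setting, y)
    rss = float(np.sum((y - post.mu_hat) ** 2))
    return float(
        -0.5 * math.log(2.0 * math.pi * setting.sigma2_A)
        - (rss / setting.n + post.sigma2_hat) / (2.0 * setting.sigma2_A)
    )


def _loo_means(setting: NormalSetting, y: np.ndarray) -> np.ndarray:
    """Leave-one-out posterior means mu_hat_{-i}."""
    s = setting
    prec0 = 0.0 if s.flat_prior else 1.0 / s.tau2_0
    prec_m1 = prec0 + (s.n - 1) / s.sigma2_A
    return (prec0 * s.mu_0 + (y.sum() - y) / s.sigma2_A) / prec_m1


def sigma2_hat_loo(setting: NormalSetting) -> float:
    """Posterior variance after dropping one observation."""
    s = setting
    prec0 = 0.0 if s.flat_prior else 1.0 / s.tau2_0
    return 1.0 / (prec0 + (s.n - 1) / s.sigma2_A)


def bias_estimates(
    setting: NormalSetting,
    y: np.ndarray,
    post: Optional[NormalPosterior] = None,
    form: str = "derived",
) -> BiasEstimates:
    """All five closed-form bias estimators, per-observation scale.

    ``form="derived"`` (default) uses the algebraically consistent
    renderings: WAIC2 carries the 1/n making it equal to
    (1/n) sum_i Var_{mu|y} log g(y_i|mu); CV retains the Gaussian
    normalising constant in the subtracted term so the constants cancel;
    popt is sigma2_hat_{-1}/sigma2_A, the unique reading that converges to
    the true bias exactly when sigma2_A = sigma2_T (its printed display is
    not evaluable as typeset, so the switch returns the same value for it).
    ``form="printed"`` reproduces the face-value typeset displays for
    comparison (WAIC2 without the 1/n; CV without the constant).
    """
    if setting.n < 2:
        raise ValueError("bias estimators need n >= 2")
    if form not in ("derived", "printed"):
        raise ValueError("form must be 'derived' or 'printed'")
    s = setting
    y = np.asarray(y, dtype=float)
    post = post or posterior_params(s, y)
    n, sa2 = s.n, s.sigma2_A
    d = y - post.mu_hat
    rss = float(np.sum(d * d))
    prior_pull = 0.0 if s.flat_prior else (s.mu_0 - post.mu_hat) / (n * s.tau2_0)
    score_sq = float(np.sum((prior_pull + d / sa2) ** 2))

    b_paic = post.sigma2_hat * score_sq / (n - 1)
    b_bpic = post.sigma2_hat * score_sq / n
    b_waic2 = post.sigma2_hat / (n * sa2**2) * (n * post.sigma2_hat / 2.0 + rss)
    b_popt = sigma2_hat_loo(s) / sa2
    mu_loo = _loo_means(s, y)
    rss_loo = float(np.sum((y - mu_loo) ** 2))
    b_cv = (rss_loo - rss) / (2.0 * n * sa2)
    if form == "printed":
        b_waic2 *= n
        b_cv -= 0.5 * math.log(2.0 * math.pi * sa2)
    return BiasEstimates(
        paic=float(b_paic),
        bpic=float(b_bpic),
        waic2=float(b_waic2),
        popt=float(b_popt),
        cv=float(b_cv),
    )


def true_bias(setting: NormalSetting) -> float:
    """E_y(eta_hat - eta) = sigma2_T * sigma2_hat / sigma2_A^2 (exact)."""
    s = setting
    prec0 = 0.0 if s.flat_prior else 1.0 / s.tau2_0
    sigma2_hat = 1.0 / (prec0 + s.n / s.sigma2_A)
    return float(s.sigma2_T * sigma2_hat / s.sigma2_A**2)


# ---------------------------------------------------------------------------
# exact posterior backend + model contract for the generic engine


class ConjugateMoments:
    """Closed-form posterior moments used by the exact criteria backend."""

    def __init__(self, setting: NormalSetting, y: np.ndarray):
        self.setting = setting
        self.y = np.asarray(y, dtype=float)
        self.post = posterior_params(setting, self.y)

    def mode(self) -> np.ndarray:
        return np.array([self.post.mu_hat])

    def expected_log_density(self, i: int) -> float:
        s, p = self.setting, self.post
        return (
            -0.5 * math.log(2.0 * math.pi * s.sigma2_A)
            - ((self.y[i] - p.mu_hat) ** 2 + p.sigma2_hat) / (2.0 * s.sigma2_A)
        )

    def var_log_density(self, i: int) -> float:
        # Var of a quadratic in a Gaussian: Var{(d-z)^2/2s} with z~N(0,v)
        s, p = self.setting, self.post
        d2 = (self.y[i] - p.mu_hat) ** 2
        return (d2 * p.sigma2_hat + p.sigma2_hat**2 / 2.0) / s.sigma2_A**2

    def expected_log_prior(self) -> float:
        s, p = self.setting, self.post
        if s.flat_prior:
            raise ValueError("flat prior has no proper log prior")
        return (
            -0.5 * math.log(2.0 * math.pi * s.tau2_0)
            - ((p.mu_hat - s.mu_0) ** 2 + p.sigma2_hat) / (2.0 * s.tau2_0)
        )

    def loo_expected_log_density(self, i: int) -> float:
        s = self.setting
        mu_loo = _loo_means(s, self.y)[i]
        v_loo = sigma2_hat_loo(s)
        return (
            -0.5 * math.log(2.0 * math.pi * s.sigma2_A)
            - ((self.y[i] - mu_loo) ** 2 + v_loo) / (2.0 * s.sigma2_A)
        )

    def log_pointwise_predictive(self, i: int) -> float:
        s, p = self.setting, self.post
        v = s.sigma2_A + p.sigma2_hat
        return -0.5 * math.log(2.0 * math.pi * v) - (
            self.y[i] - p.mu_hat
        ) ** 2 / (2.0 * v)


def make_model(
    setting: NormalSetting, y: np.ndarray, exact: bool = True
) -> BayesianModel:
    """Build the :class:`BayesianModel` contract for the normal case.

    Analytic derivative contracts are always attached; ``exact=True`` also
    attaches the closed-form posterior backend (:class:`ConjugateMoments`).
    """
    s = setting
    y = np.asarray(y, dtype=float)
    sa2 = s.sigma2_A
    flat = s.flat_prior

    def log_density(i, th):
        return -0.5 * math.log(2.0 * math.pi * sa2) - (y[i] - th[0]) ** 2 / (
            2.0 * sa2
        )

    def log_density_matrix(draws):
        mu = draws[:, 0][:, None]
        return -0.5 * math.log(2.0 * math.pi * sa2) - (y[None, :] - mu) ** 2 / (
            2.0 * sa2
        )

    if flat:
        log_prior = lambda th: 0.0
        prior_score = lambda th: np.zeros(1)
        prior_hessian = lambda th: np.zeros((1, 1))
        log_prior_vector = lambda draws: np.zeros(draws.shape[0])
    else:

        def log_prior(th):
            return -0.5 * math.log(2.0 * math.pi * s.tau2_0) - (
                th[0] - s.mu_0
            ) ** 2 / (2.0 * s.tau2_0)

        prior_score = lambda th: np.array([-(th[0] - s.mu_0) / s.tau2_0])
        prior_hessian = lambda th: np.array([[-1.0 / s.tau2_0]])

        def log_prior_vector(draws):
            return -0.5 * math.log(2.0 * math.pi * s.tau2_0) - (
                draws[:, 0] - s.mu_0
            ) ** 2 / (2.0 * s.tau2_0)

    return BayesianModel(
        n_obs=s.n,
        dim=1,
        log_density=log_density,
        log_prior=log_prior,
        prior_proper=not flat,
        score=lambda i, th: np.array([(y[i] - th[0]) / sa2]),
        hessian=lambda i, th: np.array([[-1.0 / sa2]]),
        prior_score=prior_score,
        prior_hessian=prior_hessian,
        exact_moments=ConjugateMoments(s, y) if exact else None,
        log_density_matrix=log_density_matrix,
        log_prior_vector=log_prior_vector,
        param_names=("mu",),
    )


def sample_exact_draws(
    setting: NormalSetting,
    y: np.ndarray,
    size: int,
    rng: np.random.Generator,
    chains: int = 1,
) -> PosteriorDraws:
    """iid draws from the exact normal posterior (for tests and the CLI)."""
    post = posterior_params(setting, np.asarray(y, dtype=float))
    draws = rng.normal(post.mu_hat, math.sqrt(post.sigma2_hat), size=(size, 1))
    chain_id = np.repeat(np.arange(chains), int(np.ceil(size / chains)))[:size]
    return PosteriorDraws(draws=draws, chain_id=chain_id)


# ---------------------------------------------------------------------------
# replication study of the bias estimators

PRIOR_SCENARIOS = ("1e4", "1e4/n", "0.25")


def _scenario_tau2(scenario: str, n: int) -> float:
    if scenario == "1e4":
        return 1e4
    if scenario == "1e4/n":
        return 1e4 / n
    if scenario == "0.25":
        return 0.25
    raise ValueError(f"unknown prior scenario {scenario!r}")


@dataclass
class StudyConfig:
    """Replication-study grid for the normal-case bias estimators."""

    n_grid: Sequence[int] = (10, 25, 50, 100, 200)
    prior_scenarios: Sequence[str] = PRIOR_SCENARIOS
    sigma2_A_grid: Sequence[float] = (1.0, 2.25, 0.25)
    replications: int = 10000
    seed: int = 0
    mu_T: float = 0.0
    sigma2_T: float = 1.0
    mu_0: float = 0.0

    def __post_init__(self):
        if not self.n_grid or not self.prior_scenarios or not self.sigma2_A_grid:
            raise ValueError("grids must be non-empty")
        if self.replications < 100:
            raise ValueError("replications must be >= 100")


_ESTIMATORS = ("paic", "bpic", "waic2", "popt", "cv")


def _simulate_estimates(
    setting: NormalSetting, reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorised draws of the five estimators (and realised gap) over reps."""
    s = setting
    n, sa2 = s.n, s.sigma2_A
    prec0 = 0.0 if s.flat_prior else 1.0 / s.tau2_0
    prec = prec0 + n / sa2
    sigma2_hat = 1.0 / prec
    out: dict[str, list[np.ndarray]] = {k: [] for k in (*_ESTIMATORS, "gap")}
    chunk = max(1, int(2e7) // n)  # bound peak memory for large grids
    left = reps
    while left > 0:
        r = min(chunk, left)
        Y = rng.normal(s.mu_T, math.sqrt(s.sigma2_T), size=(r, n))
        mu_hat = (prec0 * s.mu_0 + Y.sum(axis=1) / sa2) / prec
        D = Y - mu_hat[:, None]
        rss = np.einsum("ij,ij->i", D, D)
        pull = (
            np.zeros(r)
            if s.flat_prior
            else (s.mu_0 - mu_hat) / (n * s.tau2_0)
        )
        score_sq = np.einsum(
            "ij,ij->i", pull[:, None] + D / sa2, pull[:, None] + D / sa2
        )
        prec_m1 = prec0 + (n - 1) / sa2
        MU_LOO = (prec0 * s.mu_0 + (Y.sum(axis=1)[:, None] - Y) / sa2) / prec_m1
        E = Y - MU_LOO
        rss_loo = np.einsum("ij,ij->i", E, E)
        out["paic"].append(sigma2_hat * score_sq / (n - 1))
        out["bpic"].append(sigma2_hat * score_sq / n)
        out["waic2"].append(
            sigma2_hat / (n * sa2**2) * (n * sigma2_hat / 2.0 + rss)
        )
        out["popt"].append(np.full(r, (1.0 / prec_m1) / sa2))
        out["cv"].append((rss_loo - rss) / (2.0 * n * sa2))
        # realised overfit gap eta_hat - eta
        out["gap"].append(
            (s.sigma2_T + (s.mu_T - mu_hat) ** 2 - rss / n) / (2.0 * sa2)
        )
        left -= r
    return {k: np.concatenate(v) for k, v in out.items()}


def run_bias_study(config: StudyConfig) -> pd.DataFrame:
    """Mean scaled bias n*E[b-hat] per grid cell, with Monte-Carlo SEs.

    One row per (prior scenario, sigma2_A, n, estimator); the row with
    ``estimator="true"`` carries the analytic target n*b_mu.  Deterministic
    given the seed: each cell uses an independent substream spawned from
    (seed, cell index), so enlarging one grid axis never reshuffles the
    replications of existing cells.
    """
    rows = []
    cell = 0
    for scenario in config.prior_scenarios:
        for sa2 in config.sigma2_A_grid:
            for n in config.n_grid:
                setting = NormalSetting(
                    n=n,
                    mu_T=config.mu_T,
                    sigma2_T=config.sigma2_T,
                    sigma2_A=sa2,
                    mu_0=config.mu_0,
                    tau2_0=_scenario_tau2(scenario, n),
                )
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(cell,))
                )
                sims = _simulate_estimates(setting, config.replications, rng)
                base = {
                    "prior_scenario": scenario,
                    "sigma2_A": sa2,
                    "n": n,
                    "replications": config.replications,
                    "seed": config.seed,
                }
                for est in _ESTIMATORS:
                    x = sims[est]
                    rows.append(
                        {
                            **base,
                            "estimator": est,
                            "mean_scaled_bias": n * float(x.mean()),
                            "mc_se": n
                            * float(x.std(ddof=1) / math.sqrt(x.size)),
                        }
                    )
                rows.append(
                    {
                        **base,
                        "estimator": "true",
                        "mean_scaled_bias": n * true_bias(setting),
                        "mc_se": 0.0,
                    }
                )
                cell += 1
    cols = [
        "prior_scenario",
        "sigma2_A",
        "n",
        "estimator",
        "mean_scaled_bias",
        "mc_se",
        "replications",
        "seed",
    ]
    return pd.DataFrame(rows)[cols]


def plot_bias_study(df: pd.DataFrame, path=None):
    """3x3 panel plot of mean scaled bias vs n for each study cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = df["prior_scenario"].unique()
    sa2s = df["sigma2_A"].unique()
    fig, axes = plt.subplots(
        len(scenarios), len(sa2s), figsize=(4 * len(sa2s), 3 * len(scenarios)),
        squeeze=False,
    )
    for r, sc in enumerate(scenarios):
        for c, sa2 in enumerate(sa2s):
            ax = axes[r][c]
            cell = df[(df.prior_scenario == sc) & (df.sigma2_A == sa2)]
            for est, grp in cell.groupby("estimator"):
                grp = grp.sort_values("n")
                style = "-k" if est == "true" else "o--"
                ax.plot(grp["n"], grp["mean_scaled_bias"], style, label=est,
                        markersize=3, linewidth=1)
            ax.set_title(f"tau2_0={sc}, sigma2_A={sa2}", fontsize=8)
            ax.set_xlabel("n")
            ax.set_ylabel("n * mean bias")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
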