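import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats
from scipy.special import comb, expit

from paic.hierlogit import (
    LogitConfig,
    LogitDataset,
    _gibbs_mu,
    _gibbs_tau2,
    estimate_true_eta,
    generate_dataset,
    model_spec,
    run_experiment,
    sample_posterior,
    summarize_errors,
    trial_model_spec,
)
from paic.model import PosteriorDraws
from paic.numdiff import numeric_score_and_hessian


@pytest.fixture(scope="module")
def config():
    return LogitConfig(seed=0)


@pytest.fixture(scope="module")
def dataset(config):
    return generate_dataset(config, np.random.default_rng(42))


# ---------------------------------------------------------------------------
# data generation


def test_generate_dataset_deterministic_and_in_support(config):
    d1 = generate_dataset(config, np.random.default_rng(5))
    d2 = generate_dataset(config, np.random.default_rng(5))
    np.testing.assert_array_equal(d1.y, d2.y)
    np.testing.assert_array_equal(d1.beta_T, d2.beta_T)
    assert np.all((d1.y >= 0) & (d1.y <= d1.n))


def test_zero_between_group_variance_collapses_logits():
    cfg = LogitConfig(tau_T=0.0, mu_T=0.8, seed=0)
    d = generate_dataset(cfg, np.random.default_rng(1))
    np.testing.assert_allclose(d.beta_T, 0.8)


def test_extreme_flag_detects_boundary_counts():
    d = LogitDataset(beta_T=np.zeros(3), y=[0, 3, 5], n=[10, 10, 5])
    assert d.extreme
    d2 = LogitDataset(beta_T=np.zeros(3), y=[1, 3, 4], n=[10, 10, 5])
    assert not d2.extreme


# ---------------------------------------------------------------------------
# model contract


def test_log_density_matches_binomial_pmf(config, dataset):
    model = model_spec(dataset, config)
    th = np.zeros(17)
    th[16] = 1.0
    i = 0
    # beta_i = 0 means success probability 1/2
    expected = math.log(comb(dataset.n[i], dataset.y[i], exact=True)) - (
        dataset.n[i] * math.log(2.0)
    )
    assert model.log_density(i, th) == pytest.approx(expected, rel=1e-12)
    assert model.log_density(i, th) == pytest.approx(
        stats.binom.logpmf(dataset.y[i], dataset.n[i], 0.5), rel=1e-12
    )


def test_analytic_derivatives_match_finite_differences(config, dataset):
    model = model_spec(dataset, config)
    rng = np.random.default_rng(3)
    N = dataset.N
    for _ in range(10):
        th = np.concatenate(
            [rng.normal(0, 1, N), [rng.normal()], [rng.uniform(0.5, 3.0)]]
        )
        i = int(rng.integers(N))

        def f(t):
            return model.log_density(i, t) + model.log_prior(t) / N

        g_num, H_num = numeric_score_and_hessian(f, th)
        g_ana = model.score(i, th) + model.prior_score(th) / N
        H_ana = model.hessian(i, th) + model.prior_hessian(th) / N
        np.testing.assert_allclose(g_num, g_ana, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(H_num, H_ana, rtol=1e-5, atol=1e-5)


def test_tau2_prior_density_integrates_to_one(config):
    a, b = config.tau2_invgamma_ab

    def dens(t):
        return math.exp(
            a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(t) - b / t
        )

    val, err = integrate.quad(dens, 0.0, np.inf, limit=400)
    assert val == pytest.approx(1.0, abs=max(1e-6, 10 * err))
    # and it matches scipy's inverse-gamma with the same shape/scale
    assert dens(2.5) == pytest.approx(
        stats.invgamma.pdf(2.5, a, scale=b), rel=1e-10
    )


def test_trial_decomposition_matches_group_likelihood(config, dataset):
    group = model_spec(dataset, config)
    trial = trial_model_spec(dataset, config)
    assert trial.n_obs == int(dataset.n.sum())
    rng = np.random.default_rng(8)
    th = np.concatenate([rng.normal(size=15), [0.1], [1.3]])
    log_comb = sum(
        math.log(comb(int(n), int(y), exact=True))
        for n, y in zip(dataset.n, dataset.y)
    )
    total_group = group.loglik_vector(th).sum()
    total_trial = trial.loglik_vector(th).sum()
    assert total_trial == pytest.approx(total_group - log_comb, rel=1e-12)
    # per-group sums of trial scores equal the group score (likelihood part)
    s_group = sum(group.score(i, th) for i in range(15))
    s_trial = sum(trial.score(t, th) for t in range(trial.n_obs))
    np.testing.assert_allclose(s_trial, s_group, atol=1e-10)


# ---------------------------------------------------------------------------
# sampler


def test_gibbs_mu_conditional_moments(config):
    rng = np.random.default_rng(10)
    beta = np.tile(np.linspace(-1.0, 2.0, config.N), (20000, 1))
    tau2 = np.full(20000, 1.5)
    draws = _gibbs_mu(beta, tau2, config.prior_mu_mean, config.prior_mu_sd, rng)
    prec = 1 / config.prior_mu_sd**2 + config.N / 1.5
    mean = (beta[0].sum() / 1.5) / prec
    se = math.sqrt(1 / prec) / math.sqrt(draws.size)
    assert abs(draws.mean() - mean) < 3 * se
    assert draws.var(ddof=1) == pytest.approx(1 / prec, rel=0.05)


def test_gibbs_tau2_conditional_mean(config):
    rng = np.random.default_rng(11)
    a0, b0 = config.tau2_invgamma_ab
    beta = np.tile(np.linspace(-1.0, 1.0, config.N), (20000, 1))
    mu = np.zeros(20000)
    draws = _gibbs_tau2(beta, mu, a0, b0, rng)
    shape = a0 + config.N / 2
    rate = b0 + np.sum(beta[0] ** 2) / 2
    mean = rate / (shape - 1)
    sd = mean / math.sqrt(shape - 2)
    assert abs(draws.mean() - mean) < 3 * sd / math.sqrt(draws.size)


def test_sampler_converges_on_seeded_dataset(config, dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = sample_posterior(dataset, config, np.random.default_rng(2))
    assert np.nanmax(draws.diagnostics["rhat"]) < 1.05
    assert draws.n_chains == config.chains
    acc = draws.diagnostics["accept_rate"]
    assert np.all((acc > 0.2) & (acc < 0.7))
    assert np.all(draws.draws[:, -1] > 0)  # tau2 in its domain


# ---------------------------------------------------------------------------
# true out-of-sample term


def test_exact_enumeration_with_degenerate_draws(config, dataset):
    # all draws at the true logits: eta_i = sum_z pmf * log pmf
    th = np.concatenate([dataset.beta_T, [0.0], [1.0]])
    draws = PosteriorDraws(draws=np.tile(th, (4, 1)))
    est = estimate_true_eta(draws, dataset)
    oracle = 0.0
    for i in range(dataset.N):
        z = np.arange(dataset.n[i] + 1)
        pmf = stats.binom.pmf(z, dataset.n[i], expit(dataset.beta_T[i]))
        logpmf = stats.binom.logpmf(z, dataset.n[i], expit(dataset.beta_T[i]))
        oracle += float(pmf @ logpmf)
    oracle /= dataset.N
    assert est.mc_se == 0.0
    assert est.eta_true == pytest.approx(oracle, abs=1e-10)


def test_mc_outcome_draws_converge_to_enumeration(config, dataset):
    rng = np.random.default_rng(30)
    th = np.concatenate([dataset.beta_T, [0.0], [1.0]])
    draws = PosteriorDraws(
        draws=np.tile(th, (6, 1)) + 0.01 * rng.standard_normal((6, 17))
    )
    exact = estimate_true_eta(draws, dataset, method="exact")
    mc = estimate_true_eta(draws, dataset, method="mc", J=20000, rng=rng)
    assert mc.mc_se > 0
    assert abs(mc.eta_true - exact.eta_true) < 3 * mc.mc_se


# ---------------------------------------------------------------------------
# error summaries and the experiment


def test_summarize_errors_arithmetic():
    df = np.rec.fromarrays(
        [[0, 1, 0, 1], ["A", "A", "B", "B"], [1.0, -1.0, 0.0, 0.0]],
        names=["replication", "criterion", "error"],
    )
    import pandas as pd

    out = summarize_errors(pd.DataFrame.from_records(df))
    assert out.loc["A", "mean_error"] == pytest.approx(0.0)
    assert out.loc["A", "sd_error"] == pytest.approx(math.sqrt(2.0))
    assert out.loc["A", "mean_abs_error"] == pytest.approx(1.0)
    assert out.loc["A", "mean_sq_error"] == pytest.approx(1.0)
    assert (out.loc["B"][["mean_error", "mean_abs_error", "mean_sq_error"]] == 0).all()


@given(st.lists(st.floats(-5, 5), min_size=2, max_size=40))
def test_mean_absolute_error_dominates_mean_error(errors):
    import pandas as pd

    df = pd.DataFrame(
        {
            "replication": range(len(errors)),
            "criterion": "PAIC",
            "error": errors,
        }
    )
    out = summarize_errors(df)
    assert (
        out.loc["PAIC", "mean_abs_error"]
        >= abs(out.loc["PAIC", "mean_error"]) - 1e-12
    )


def test_experiment_is_deterministic_and_consistent():
    cfg = LogitConfig(replications=3, seed=77)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = run_experiment(cfg)
        r2 = run_experiment(cfg)
    assert r1.errors.equals(r2.errors)
    assert r1.n_failed == 0
    # error + bias_hat reconstructs the realised gap for every criterion
    df = r1.errors
    gap = df.eta_hat - df.eta_true
    np.testing.assert_allclose(df.error + df.bias_hat, gap, atol=1e-12)
    # substituting the realised truth as the bias gives zero error
    assert np.allclose(gap - gap, 0.0)


def test_prior_robustness_between_tau2_hyperpriors():
    """Swapping Inv-chi2(0.1,10) for Inv-Gamma(0.001,0.001) moves each
    criterion's mean actual error by less than 2 Monte-Carlo SE."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = run_experiment(LogitConfig(replications=60, seed=5))
        alt = run_experiment(
            LogitConfig(replications=60, seed=5, tau2_prior="inv_gamma")
        )
    for crit in ("PAIC", "BPIC", "WAIC2", "CV"):
        m1, s1 = base.summary.loc[crit, ["mean_error", "sd_error"]]
        m2, s2 = alt.summary.loc[crit, ["mean_error", "sd_error"]]
        se = math.sqrt(s1**2 / 60 + s2**2 / 60)
        assert abs(m1 - m2) < 2 * se, crit


def test_extreme_observations_hurt_bpic_more_than_paic():
    """Replications with boundary counts: the plug-in log likelihood at the
    mode deviates sharply and BPIC's correction cannot recover it, so its
    absolute error is stochastically larger than PAIC's (sign test)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_experiment(LogitConfig(replications=60, tau_T=2.0, seed=11))
    ext = res.errors[res.errors.extreme_flag]
    piv = ext.pivot_table(index="replication", columns="criterion", values="error")
    assert len(piv) >= 20
    k = int((piv.BPIC.abs() > piv.PAIC.abs()).sum())
    p = stats.binomtest(k, len(piv), alternative="greater").pvalue
    assert p < 0.05
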