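import math
import warnings

import numpy as np
import pytest

from paic import (
    BayesianModel,
    ImproperPriorError,
    ModelCriteria,
    PosteriorDraws,
    bpic,
    cv_loo,
    expected_log_density_per_obs,
    paic,
    waic,
)
from paic import conjugate as cj

HALF_LOG_2PI = 0.5 * math.log(2 * math.pi)
MICRO_Y = np.array([-1.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# expected log density


def test_degenerate_draws_reduce_to_plugin_value():
    s = cj.NormalSetting(n=3, tau2_0=1.0)
    model = cj.make_model(s, MICRO_Y, exact=False)
    theta_star = 0.3
    draws = PosteriorDraws(draws=np.full((6, 1), theta_star))
    per_obs, _ = expected_log_density_per_obs(model, draws)
    expected = [model.log_density(i, np.array([theta_star])) for i in range(3)]
    np.testing.assert_allclose(per_obs, expected, rtol=1e-12)


def test_monte_carlo_agrees_with_exact_moments(micro_setting, micro_draws):
    exact = cj.make_model(micro_setting, MICRO_Y, exact=True)
    mc = cj.make_model(micro_setting, MICRO_Y, exact=False)
    vec_exact, se_exact = expected_log_density_per_obs(exact, micro_draws)
    vec_mc, se_mc = expected_log_density_per_obs(mc, micro_draws)
    assert se_exact == 0.0
    assert se_mc > 0.0
    assert abs(vec_mc.sum() - vec_exact.sum()) < 3 * se_mc


def test_additive_constant_shifts_every_entry_exactly():
    s = cj.NormalSetting(n=3, tau2_0=1.0)
    base = cj.make_model(s, MICRO_Y, exact=False)
    c = 1.7
    shifted = BayesianModel(
        n_obs=3,
        dim=1,
        log_density=lambda i, th: base.log_density(i, th) + c,
        log_prior=base.log_prior,
    )
    draws = PosteriorDraws(draws=np.linspace(-1, 1, 40)[:, None])
    v0, _ = expected_log_density_per_obs(base, draws)
    v1, _ = expected_log_density_per_obs(shifted, draws)
    np.testing.assert_allclose(v1 - v0, c, rtol=1e-12)


# ---------------------------------------------------------------------------
# PAIC


def test_paic_micro_example(micro_model, micro_draws):
    res = paic(micro_model, micro_draws)
    eta_hat = -HALF_LOG_2PI - (2.0 / 3.0 + 0.25) / 2.0
    assert res.eta_hat_total == pytest.approx(3 * eta_hat, abs=1e-10)
    assert res.eta_hat_total == pytest.approx(-4.13182, abs=1e-5)
    assert res.bias_total == pytest.approx(0.75, abs=1e-9)
    assert res.value == pytest.approx(-6 * eta_hat + 1.5, abs=1e-9)
    assert res.value == pytest.approx(9.76364, abs=1e-4)


def test_paic_flat_prior_micro_example():
    s = cj.NormalSetting(n=3, tau2_0=float("inf"))
    model = cj.make_model(s, MICRO_Y)
    draws = PosteriorDraws(draws=np.array([[0.0], [0.1]]))
    res = paic(model, draws)
    eta_total = 3 * (-HALF_LOG_2PI) - (2.0 + 1.0) / 2.0
    assert res.eta_hat_total == pytest.approx(eta_total, abs=1e-10)
    assert res.bias_total == pytest.approx(1.0, abs=1e-9)
    assert res.value == pytest.approx(-2 * eta_total + 2.0, abs=1e-9)


def test_identical_models_give_identical_paic(micro_setting, micro_draws):
    a = paic(cj.make_model(micro_setting, MICRO_Y), micro_draws)
    b = paic(cj.make_model(micro_setting, MICRO_Y), micro_draws)
    assert a.value - b.value == 0.0


@pytest.mark.parametrize("name", ["paic", "bpic", "waic1", "waic2", "cv"])
def test_value_reconstructs_from_eta_and_bias(name, micro_model, micro_draws):
    fit = ModelCriteria(micro_model, micro_draws).fit(criteria=(name,))
    res = fit[name]
    assert res.value == pytest.approx(
        -2.0 * res.eta_hat_total + 2.0 * res.bias_total, abs=1e-12
    )


# ---------------------------------------------------------------------------
# BPIC


def test_bpic_micro_bias_matches_closed_form(micro_model, micro_draws):
    res = bpic(micro_model, micro_draws)
    assert res.bias == pytest.approx(1.0 / 6.0, abs=1e-9)
    assert res.value == pytest.approx(
        -2 * (res.eta_hat_total - res.bias_total), abs=1e-12
    )


def test_bpic_refuses_improper_prior():
    s = cj.NormalSetting(n=3, tau2_0=float("inf"))
    model = cj.make_model(s, MICRO_Y)
    draws = PosteriorDraws(draws=np.array([[0.0], [0.1]]))
    with pytest.raises(ImproperPriorError, match="degenerate"):
        bpic(model, draws)


def test_expected_log_prior_gaussian_identity(micro_setting, micro_draws):
    # E_{mu|y} log N(mu; 0, 1) under posterior N(0, 0.25)
    em = cj.ConjugateMoments(micro_setting, MICRO_Y)
    closed = -HALF_LOG_2PI - 0.5 * 0.25
    assert em.expected_log_prior() == pytest.approx(closed, abs=1e-12)
    model = cj.make_model(micro_setting, MICRO_Y, exact=False)
    lp = model.logprior_per_draw(micro_draws.draws)
    se = lp.std(ddof=1) / math.sqrt(lp.size)
    assert abs(lp.mean() - closed) < 3 * se


# ---------------------------------------------------------------------------
# WAIC


def test_waic2_functional_variance_micro(micro_model, micro_draws):
    res = waic(micro_model, micro_draws, variant=2)
    assert res.bias_total == pytest.approx(0.59375, abs=1e-12)
    assert res.bias == pytest.approx(0.19791667, abs=1e-7)


def test_waic2_monte_carlo_approaches_exact(micro_setting, micro_draws):
    mc_model = cj.make_model(micro_setting, MICRO_Y, exact=False)
    res = waic(mc_model, micro_draws, variant=2)
    # functional variance of ~2000 draws: loose stochastic agreement
    assert res.bias_total == pytest.approx(0.59375, rel=0.15)


def test_waic2_degenerate_draws_zero_bias_with_warning():
    s = cj.NormalSetting(n=3, tau2_0=1.0)
    model = cj.make_model(s, MICRO_Y, exact=False)
    draws = PosteriorDraws(draws=np.full((5, 1), 0.2))
    with pytest.warns(RuntimeWarning, match="degenerate"):
        res = waic(model, draws, variant=2)
    assert res.bias_total == 0.0


def test_waic2_bias_never_negative():
    rng = np.random.default_rng(5)
    for _ in range(20):
        s = cj.NormalSetting(
            n=int(rng.integers(2, 30)), tau2_0=float(10 ** rng.uniform(-1, 3))
        )
        y = rng.normal(size=s.n)
        model = cj.make_model(s, y, exact=False)
        draws = PosteriorDraws(draws=rng.normal(size=(60, 1)))
        assert waic(model, draws, variant=2).bias_total >= 0.0


def test_waic1_plugin_discrepancy_form(micro_model, micro_draws):
    res = waic(micro_model, micro_draws, variant=1)
    em = micro_model.exact_moments
    lppd = sum(em.log_pointwise_predictive(i) for i in range(3))
    p1 = 2.0 * (lppd - res.eta_hat_total)
    assert res.value == pytest.approx(-2.0 * (lppd - p1), abs=1e-10)
    assert res.bias_total >= 0.0  # Jensen


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_refit_exact_loo_micro(micro_model, micro_draws):
    res = cv_loo(micro_model, micro_draws, method="refit")
    # hand oracle: mu_loo = (1/3, 0, -1/3), sigma2_loo = 1/3
    mu_loo = np.array([1.0 / 3.0, 0.0, -1.0 / 3.0])
    loo = -HALF_LOG_2PI - ((MICRO_Y - mu_loo) ** 2 + 1.0 / 3.0) / 2.0
    assert res.bias == pytest.approx(
        (res.eta_hat_total - loo.sum()) / 3.0, abs=1e-12
    )
    assert res.bias == pytest.approx(0.30092593, abs=1e-8)


def test_cv_importance_mean_cap_agrees_with_refit(micro_setting):
    rng = np.random.default_rng(17)
    draws = cj.sample_exact_draws(micro_setting, MICRO_Y, 20000, rng)
    model = cj.make_model(micro_setting, MICRO_Y)
    refit = cv_loo(model, draws, method="refit")
    imp = cv_loo(model, draws, method="importance", truncation="mean")
    # batch-means SE of the IS estimate of the LOO total
    L = model.loglik_matrix(draws.draws)
    se = 0.0
    for i in range(3):
        w = np.exp(-L[:, i] + L[:, i].min())
        est = (w * L[:, i]).reshape(20, -1).sum(1) / w.reshape(20, -1).sum(1)
        se += est.var(ddof=1) / 20
    se = math.sqrt(se)
    assert abs(imp.bias_total - refit.bias_total) < 3 * max(se, 1e-3)


def test_cv_quantile_cap_shrinks_correction_toward_zero(micro_setting):
    rng = np.random.default_rng(19)
    draws = cj.sample_exact_draws(micro_setting, MICRO_Y, 4000, rng)
    model = cj.make_model(micro_setting, MICRO_Y)
    quant = cv_loo(model, draws, method="importance", truncation="quantile")
    mean = cv_loo(model, draws, method="importance", truncation="mean")
    assert 0.0 <= quant.bias_total <= mean.bias_total


def test_cv_single_observation_is_error():
    model = BayesianModel(
        n_obs=1,
        dim=1,
        log_density=lambda i, th: float(-th[0] ** 2),
        log_prior=lambda th: 0.0,
    )
    draws = PosteriorDraws(draws=np.array([[0.0], [0.2]]))
    with pytest.raises(ValueError, match="held-out"):
        cv_loo(model, draws)


def test_cv_low_ess_warns_about_influential_observation():
    L = np.zeros((100, 2))
    L[0, 0] = -60.0  # one draw carries essentially all LOO weight for obs 0
    model = BayesianModel(
        n_obs=2,
        dim=1,
        log_density=lambda i, th: 0.0,
        log_prior=lambda th: 0.0,
        log_density_matrix=lambda d: L[: d.shape[0]],
    )
    draws = PosteriorDraws(draws=np.zeros((100, 1)))
    with pytest.warns(RuntimeWarning, match="observation 0"):
        cv_loo(model, draws, method="importance", truncation="mean")


# ---------------------------------------------------------------------------
# front end


def test_fit_default_criteria_skip_bpic_for_improper_prior():
    s = cj.NormalSetting(n=3, tau2_0=float("inf"))
    model = cj.make_model(s, MICRO_Y)
    draws = PosteriorDraws(draws=np.array([[0.0], [0.1], [0.2]]))
    fit = ModelCriteria(model, draws).fit()
    assert set(fit.results) == {"paic", "waic2", "cv"}
    assert "PAIC" in fit.summary()


def test_fit_matches_standalone_functions(micro_model, micro_draws):
    fit = ModelCriteria(micro_model, micro_draws).fit(
        criteria=("paic", "bpic", "waic2")
    )
    assert fit["paic"].value == pytest.approx(
        paic(micro_model, micro_draws).value, abs=1e-12
    )
    assert fit["bpic"].value == pytest.approx(
        bpic(micro_model, micro_draws).value, abs=1e-12
    )
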