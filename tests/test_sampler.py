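"""Posterior sampler correctness: prior recovery, oracle agreement, determinism."""

import numpy as np
import pytest

from ctdose import (
    BayesianToxicityModel,
    PosteriorDraws,
    SamplerSettings,
    TrialData,
    TruthSpec,
    posterior_mtd_quantile,
    prior_bounds,
    sample_posterior,
)

from grid_oracle import grid_posterior


def test_empty_data_samples_the_prior(acc_config):
    """With no observations the chain explores the constrained prior:
    nu has unit median and every MTD draw stays inside the dose range."""
    draws = sample_posterior(None, acc_config, SamplerSettings(n_iterations=9000, seed=4))
    assert np.median(draws.nu) == pytest.approx(1.0, abs=0.02)
    assert np.all(draws.xi > acc_config.x_min)
    assert np.all(draws.xi < acc_config.x_max)
    # support constraints hold draw-by-draw
    lo, hi = prior_bounds(draws.sigma, draws.nu, acc_config)
    assert np.all(draws.beta > lo) and np.all(draws.beta < hi)
    assert np.all(draws.sigma < acc_config.sigma_max)


def test_posterior_draws_never_violate_support(acc_config, quick_settings):
    rng = np.random.default_rng(0)
    x = rng.uniform(6, 70, 12)
    y = rng.normal(0.06 * (x - 5), 0.1)
    draws = sample_posterior(TrialData.from_arrays(x, y), acc_config, quick_settings)
    lo, hi = prior_bounds(draws.sigma, draws.nu, acc_config)
    assert np.all(draws.beta > lo) and np.all(draws.beta < hi)
    assert np.all((draws.xi > acc_config.x_min) & (draws.xi < acc_config.x_max))


def test_seed_determinism(acc_config):
    data = TrialData.from_arrays([6.0, 30.0], [0.1, 1.5])
    s = SamplerSettings(n_iterations=2000, n_burnin=500, seed=123)
    d1 = sample_posterior(data, acc_config, s)
    d2 = sample_posterior(data, acc_config, s)
    assert np.array_equal(d1.beta, d2.beta)
    assert np.array_equal(d1.nu, d2.nu)
    assert np.array_equal(d1.sigma, d2.sigma)
    d3 = sample_posterior(data, acc_config, SamplerSettings(2000, 500, seed=124))
    assert not np.array_equal(d1.beta, d3.beta)


def _mcse_mean(x: np.ndarray) -> float:
    import arviz as az

    ess = max(float(az.ess(np.asarray(x))), 10.0)
    return float(np.std(x) / np.sqrt(ess))


@pytest.mark.parametrize(
    "x,y",
    [
        ([6.0], [0.08]),
        ([6.0, 30.0], [0.05, 1.55]),
    ],
)
def test_posterior_matches_grid_oracle(acc_config, x, y):
    """Marginal posterior means agree with dense 3-D grid integration."""
    oracle = grid_posterior(np.array(x), np.array(y), acc_config,
                            n_sigma=160, n_nu=160, n_beta=240)
    draws = sample_posterior(
        TrialData.from_arrays(x, y), acc_config,
        SamplerSettings(n_iterations=30000, n_burnin=2000, seed=9),
    )
    for name in ("beta", "nu", "sigma", "xi"):
        arr = getattr(draws, name)
        se = _mcse_mean(arr)
        assert arr.mean() == pytest.approx(oracle["mean"](name), abs=max(3 * se, 1e-4)), name


def test_posterior_quantiles_match_grid_oracle(acc_config):
    x, y = [6.0, 30.0], [0.05, 1.55]
    oracle = grid_posterior(np.array(x), np.array(y), acc_config,
                            n_sigma=160, n_nu=160, n_beta=240)
    draws = sample_posterior(
        TrialData.from_arrays(x, y), acc_config,
        SamplerSettings(n_iterations=30000, n_burnin=2000, seed=10),
    )
    import arviz as az

    for name in ("xi", "sigma"):
        arr = np.asarray(getattr(draws, name))
        for p in (0.1, 0.5, 0.9):
            ess = max(float(az.ess(arr, method="quantile", prob=p)), 10.0)
            # SE of an empirical quantile: sqrt(p(1-p)/ess) / f(q), with the
            # density f(q) approximated as 0.1 / (Q(p+.05) - Q(p-.05))
            q = np.quantile(arr, p)
            bw = np.quantile(arr, min(p + 0.05, 1.0)) - np.quantile(arr, max(p - 0.05, 0.0))
            se = max(np.sqrt(p * (1 - p) / ess) * bw / 0.1, 1e-3)
            assert q == pytest.approx(oracle["quantile"](name, p), abs=3 * se), (name, p)


def test_mtd_quantile_conventions():
    point = PosteriorDraws(*(np.full(100, 1.0) for _ in range(3)), xi=np.full(100, 42.0))
    for alpha in (0.01, 0.5, 0.99):
        assert posterior_mtd_quantile(point, alpha) == 42.0
    spaced = np.round(np.linspace(30.1, 40.0, 100), 1)
    draws = PosteriorDraws(np.ones(100), np.ones(100), np.ones(100), xi=spaced)
    # inverted-CDF (type 1): ceil(100 * 0.10) = 10th order statistic
    assert posterior_mtd_quantile(draws, 0.10) == pytest.approx(31.0)
    qs = [posterior_mtd_quantile(draws, a) for a in np.linspace(0.05, 0.95, 10)]
    assert np.all(np.diff(qs) >= 0)
    with pytest.raises(ValueError):
        posterior_mtd_quantile(draws, 1.5)


def test_parameter_recovery_and_interval_coverage(acc_config):
    """With many patients the posterior concentrates near the true MTD, and
    the 90% credible interval covers it in most synthetic replicates."""
    truth = TruthSpec(xi0=50.0, nu0=1.0, sigma0=0.1)
    b0 = truth.beta0(acc_config)
    covered = 0
    n_sets = 20
    for rep in range(n_sets):
        rng = np.random.default_rng(1000 + rep)
        x = rng.uniform(6.0, 79.0, 200)
        y = rng.normal(b0 * (x - 5.0), 0.1)
        draws = sample_posterior(
            TrialData.from_arrays(x, y), acc_config,
            SamplerSettings(n_iterations=2000, n_burnin=500, seed=rep),
        )
        lo, hi = np.quantile(draws.xi, [0.05, 0.95])
        covered += lo <= truth.xi0 <= hi
    assert covered >= 0.8 * n_sets


def test_estimator_interface(acc_config, quick_settings):
    est = BayesianToxicityModel(acc_config, n_iterations=1200, n_burnin=300, random_state=5)
    assert est.get_params()["n_iterations"] == 1200
    rng = np.random.default_rng(2)
    x = rng.uniform(6, 70, 10)
    y = rng.normal(0.06 * (x - 5), 0.1)
    est.fit(x.reshape(-1, 1), y)
    assert est.n_obs_ == 10
    assert est.mtd_draws_.shape == est.draws_.beta.shape
    pred = est.predict([5.0, 40.0])
    assert pred[0] == pytest.approx(0.0, abs=1e-12)
    assert pred[1] > 0
    assert acc_config.x_min < est.mtd_quantile() < acc_config.x_max
    with pytest.raises(AttributeError):
        BayesianToxicityModel(acc_config).predict([10.0])
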