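"""Closed-form MTD, prior bounds, and the model densities."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr, ndtri

from ctdose import (
    DesignConfig,
    ModelParams,
    TruthSpec,
    dlt_probability,
    log_likelihood,
    log_prior,
    mtd,
    mtd_from_params,
    prior_bounds,
    sample_prior,
)
from ctdose.dose_rule import TrialData


def test_prior_bounds_hand_computed(std_config):
    # (3 - 0.1 * 2.3263479) / 75 and 3/75 + 0.1 * 2.3263479
    lower, upper = prior_bounds(0.1, 1.0, std_config)
    assert lower == pytest.approx(0.036898203, abs=1e-7)
    assert upper == pytest.approx(0.272634787, abs=1e-7)
    assert 0 < lower < upper


def test_prior_bounds_width_is_positive_and_collapses_as_sigma_vanishes(std_config):
    lower, upper = prior_bounds(1e-12, 1.0, std_config)
    assert upper - lower == pytest.approx(0.0, abs=1e-10)
    assert lower == pytest.approx(3.0 / 75.0, rel=1e-6)
    for sigma in (0.01, 0.3, 1.0):
        for nu in (0.3, 1.0, 2.5):
            lo, hi = prior_bounds(sigma, nu, std_config)
            width = sigma * std_config.z_gamma * (1 + std_config.dose_span**-nu)
            assert hi - lo == pytest.approx(width, rel=1e-9)


def test_prior_bounds_rejects_out_of_support(std_config):
    with pytest.raises(ValueError):
        prior_bounds(std_config.sigma_max * 1.01, 1.0, std_config)
    with pytest.raises(ValueError):
        prior_bounds(0.1, -1.0, std_config)


def test_mtd_inverts_truth_slope(std_config):
    truth = TruthSpec(xi0=50.0, nu0=1.0, sigma0=0.1)
    params = truth.params(std_config)
    xi = mtd_from_params(params, std_config)
    assert xi == pytest.approx(50.0, abs=1e-9)
    # the defining identity: Pr[Y(xi) < eta] = gamma
    mean = params.beta * (xi - std_config.x_min) ** params.nu
    assert ndtr((std_config.eta - mean) / params.sigma) == pytest.approx(
        std_config.gamma, abs=1e-12
    )


def test_mtd_at_lower_slope_bound_is_range_supremum(std_config):
    sigma = 0.2
    beta = (std_config.eta - sigma * std_config.z_gamma) / std_config.dose_span
    assert mtd(beta, 1.0, sigma, std_config) == pytest.approx(std_config.x_max)


def test_mtd_small_sigma_limit(std_config):
    beta = 0.05
    xi = mtd(beta, 2.0, 1e-14, std_config)
    assert xi == pytest.approx(std_config.x_min + (std_config.eta / beta) ** 0.5, rel=1e-9)


def test_mtd_undefined_outside_constraints(std_config):
    with pytest.raises(ValueError):
        mtd(0.05, 1.0, std_config.sigma_max + 0.1, std_config)
    with pytest.raises(ValueError):
        mtd(-0.1, 1.0, 0.1, std_config)
    with pytest.raises(ValueError):
        mtd(0.1, 0.0, 0.1, std_config)


def test_mtd_strictly_decreasing_in_beta_sigma_gamma(std_config):
    rng = np.random.default_rng(7)
    for _ in range(200):
        sigma = rng.uniform(0.01, 0.9 * std_config.sigma_max)
        nu = float(np.exp(rng.normal(0, 0.4)))
        lo, hi = prior_bounds(sigma, nu, std_config)
        beta = rng.uniform(lo, hi)
        base = mtd(beta, nu, sigma, std_config)
        assert mtd(beta * 1.05, nu, sigma, std_config) < base
        if sigma * 1.05 < std_config.sigma_max:
            assert mtd(beta, nu, sigma * 1.05, std_config) < base
        steeper = DesignConfig(**{**std_config.to_dict(), "gamma": 0.995})
        if sigma < steeper.sigma_max:
            assert mtd(beta, nu, sigma, steeper) < base


def test_dlt_probability_monotone_in_dose(std_config):
    rng = np.random.default_rng(3)
    x = np.linspace(std_config.x_min, std_config.x_max - 1e-9, 50)
    for _ in range(50):
        sigma = rng.uniform(0.01, 0.9 * std_config.sigma_max)
        nu = float(np.exp(rng.normal(0, 0.4)))
        lo, hi = prior_bounds(sigma, nu, std_config)
        params = ModelParams(rng.uniform(lo, hi), nu, sigma)
        p = dlt_probability(x, params, std_config)
        assert np.all(np.diff(p) >= -1e-15)


def test_prior_draws_map_into_dose_range(std_config):
    """Every triple in the prior support yields an MTD inside (x_min, x_max)."""
    rng = np.random.default_rng(11)
    beta, nu, sigma = sample_prior(std_config, 10_000, rng)
    xi = mtd(beta, nu, sigma, std_config)
    assert np.all(xi > std_config.x_min)
    assert np.all(xi < std_config.x_max)


def test_log_prior_flat_in_beta_and_off_support(std_config):
    sigma, nu = 0.2, 0.8
    lo, hi = prior_bounds(sigma, nu, std_config)
    lp1 = log_prior(ModelParams(lo + 0.2 * (hi - lo), nu, sigma), std_config)
    lp2 = log_prior(ModelParams(lo + 0.9 * (hi - lo), nu, sigma), std_config)
    assert lp1 == pytest.approx(lp2, rel=1e-12)
    assert log_prior(ModelParams(lo * 0.99, nu, sigma), std_config) == -math.inf
    assert log_prior(ModelParams(hi * 1.01, nu, sigma), std_config) == -math.inf
    assert (
        log_prior(ModelParams(0.1, nu, std_config.sigma_max * 1.01), std_config)
        == -math.inf
    )


def test_log_prior_integrates_to_one(std_config):
    """Midpoint cubature of exp(log_prior) over the 3-D support."""
    cfg = std_config
    ns, nn, nb = 120, 80, 8
    s_edges = np.linspace(0, cfg.sigma_max, ns + 1)
    sig = 0.5 * (s_edges[:-1] + s_edges[1:])
    ds = cfg.sigma_max / ns
    t_edges = np.linspace(-6 * cfg.delta, 6 * cfg.delta, nn + 1)
    t = 0.5 * (t_edges[:-1] + t_edges[1:])
    nus = np.exp(t)
    total = 0.0
    for s in sig:
        for k, nu in enumerate(nus):
            dnu = math.exp(t_edges[k + 1]) - math.exp(t_edges[k])
            lo, hi = prior_bounds(s, nu, cfg)
            betas = lo + (np.arange(nb) + 0.5) * (hi - lo) / nb
            db = (hi - lo) / nb
            dens = sum(
                math.exp(log_prior(ModelParams(b, nu, s), cfg)) for b in betas
            )
            total += dens * db * dnu * ds
    assert total == pytest.approx(1.0, abs=1e-2)


def test_log_likelihood_empty_and_single_record(std_config):
    assert log_likelihood(ModelParams(0.1, 1.0, 0.2), None, std_config) == 0.0
    data = TrialData.from_arrays([std_config.x_min], [0.0])
    for beta, nu in [(0.05, 1.0), (0.2, 2.3)]:
        ll = log_likelihood(ModelParams(beta, nu, 0.3), data, std_config)
        assert ll == pytest.approx(-math.log(0.3 * math.sqrt(2 * math.pi)), rel=1e-12)


def test_log_likelihood_matches_per_record_sum(std_config):
    params = ModelParams(0.04, 1.2, 0.25)
    x = np.array([6.0, 20.0, 55.0])
    y = np.array([0.1, 0.9, 2.4])
    expected = 0.0
    for xi_, yi in zip(x, y):
        m = params.beta * (xi_ - std_config.x_min) ** params.nu
        expected += (
            -0.5 * math.log(2 * math.pi)
            - math.log(params.sigma)
            - (yi - m) ** 2 / (2 * params.sigma**2)
        )
    got = log_likelihood(params, TrialData.from_arrays(x, y), std_config)
    assert got == pytest.approx(expected, abs=1e-12)


def test_log_likelihood_rejects_dose_below_range(std_config):
    data = TrialData.from_arrays([4.0], [0.1])
    with pytest.raises(ValueError):
        log_likelihood(ModelParams(0.1, 1.0, 0.2), data, std_config)


@given(st.floats(0.51, 0.99), st.floats(0.6, 40.0), st.floats(0.2, 3.0))
def test_truth_spec_roundtrip(gamma, xi_offset, nu0):
    """Deriving the slope from a true MTD and inverting recovers the MTD."""
    config = DesignConfig(
        eta=3.0, gamma=gamma, x_min=5.0, x_max=80.0, delta=0.1, alpha=0.01,
        initial_dose=6.0, n_patients=5,
    )
    truth = TruthSpec(xi0=5.0 + xi_offset, nu0=nu0, sigma0=0.1)
    xi = mtd_from_params(truth.params(config), config)
    assert xi == pytest.approx(truth.xi0, rel=1e-9)


def test_config_validation_rejects_bad_fields():
    ok = dict(eta=3.0, gamma=0.9, x_min=5.0, x_max=80.0, delta=0.1, alpha=0.01,
              initial_dose=6.0, n_patients=10)
    DesignConfig(**ok)
    for bad in (
        {"gamma": 0.4}, {"gamma": 1.0}, {"alpha": 0.0}, {"eta": -1.0},
        {"x_min": 90.0}, {"initial_dose": 4.0}, {"cohort_size": 0},
        {"dose_grid": (1.0, 50.0)}, {"grid_snap": "floor"},
    ):
        with pytest.raises(ValueError):
            DesignConfig(**{**ok, **bad})
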