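"""Brute-force posterior oracle by dense 3-D grid integration.

Independent of the MCMC path: evaluates ``exp(log_likelihood + log_prior)``
on a dense (sigma, nu, beta) grid and forms posterior means and quantiles
by normalised weighted sums.  Feasible only for a handful of observations,
which is exactly where it is used as a reference.
"""

from __future__ import annotations

import numpy as np

from ctdose import DesignConfig
from ctdose.model import mtd


def grid_posterior(
    x: np.ndarray,
    y: np.ndarray,
    config: DesignConfig,
    n_sigma: int = 160,
    n_nu: int = 160,
    n_beta: int = 400,
    nu_halfwidth: float = 5.0,
):
    """Posterior summaries of (beta, nu, sigma, xi) by grid integration.

    Returns a dict with weighted means and a ``quantile(name, p)`` callable.
    sigma is gridded over its truncated support, ``log nu`` over
    ``+- nu_halfwidth * delta`` (the prior is Gaussian there), and beta over
    its conditional support ``(l, u)`` for every (sigma, nu) pair, with the
    cell volume as the integration weight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xs = x - config.x_min

    # midpoint grids avoid the support boundaries; sigma is gridded on the
    # log scale because with n <= 2 exactly-fittable observations the
    # likelihood concentrates sharply as sigma -> 0
    s_edges = np.exp(
        np.linspace(np.log(config.sigma_max) - 12.0, np.log(config.sigma_max), n_sigma + 1)
    )
    sigma = 0.5 * (s_edges[:-1] + s_edges[1:])
    ds = np.diff(s_edges)

    t_edges = np.linspace(
        -nu_halfwidth * config.delta, nu_halfwidth * config.delta, n_nu + 1
    )
    t = 0.5 * (t_edges[:-1] + t_edges[1:])
    nu = np.exp(t)
    dt = np.diff(t_edges)

    S, NU = np.meshgrid(sigma, nu, indexing="ij")  # (ns, nn)
    span_nu = config.dose_span ** NU
    lower = (config.eta - S * config.z_gamma) / span_nu
    upper = config.eta / span_nu + S * config.z_gamma
    width = upper - lower

    frac = (np.arange(n_beta) + 0.5) / n_beta
    BETA = lower[..., None] + width[..., None] * frac  # (ns, nn, nb)

    # log prior: uniform beta (1/width) * trunc half-Cauchy sigma * lognormal nu,
    # with the nu integral taken on the log scale (drops the 1/nu Jacobian)
    log_prior = (
        -np.log(width)[..., None]
        - np.log1p(S * S)[..., None]
        - np.log(np.arctan(config.sigma_max))
        - (np.log(NU) ** 2 / (2.0 * config.delta**2))[..., None]
        - np.log(config.delta * np.sqrt(2.0 * np.pi))
    )

    if n:
        W = xs[None, None, :] ** NU[..., None]  # (ns, nn, n)
        swy = (W * y).sum(axis=-1)
        sww = (W * W).sum(axis=-1)
        syy = float(y @ y)
        ss = syy - 2.0 * BETA * swy[..., None] + BETA**2 * sww[..., None]
        log_lik = (
            -n * np.log(S)[..., None]
            - ss / (2.0 * S**2)[..., None]
            - 0.5 * n * np.log(2.0 * np.pi)
        )
    else:
        log_lik = 0.0

    log_w = log_prior + log_lik
    log_vol = (
        np.log(ds)[:, None, None]
        + np.log(dt)[None, :, None]
        + np.log(width[..., None] / n_beta)
    )
    log_w = log_w + log_vol
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= w.sum()

    xi = mtd(BETA, NU[..., None] * np.ones_like(BETA), S[..., None] * np.ones_like(BETA), config)
    values = {
        "beta": BETA,
        "nu": NU[..., None] * np.ones_like(BETA),
        "sigma": S[..., None] * np.ones_like(BETA),
        "xi": xi,
    }

    flat_w = w.ravel()
    order_cache: dict = {}

    def mean(name: str) -> float:
        return float((values[name] * w).sum())

    def quantile(name: str, p: float) -> float:
        if name not in order_cache:
            v = values[name].ravel()
            idx = np.argsort(v)
            order_cache[name] = (v[idx], np.cumsum(flat_w[idx]))
        v_sorted, cum = order_cache[name]
        return float(v_sorted[np.searchsorted(cum, p)])

    return {"mean": mean, "quantile": quantile, "weights": w, "values": values}
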