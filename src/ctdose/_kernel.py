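"""JIT-compiled slice-within-Gibbs kernel for the three-parameter posterior.

The state is parameterised as ``(b, nu, sigma)`` with
``b = (beta - l(sigma, nu)) / (u(sigma, nu) - l(sigma, nu))`` in (0, 1).
Because the conditional prior of the slope is uniform on ``(l, u)``, the
prior of ``b`` is exactly uniform on (0, 1) and independent of
``(nu, sigma)`` — the 1/(u-l) density cancels the Jacobian of the map.
Updating ``nu`` or ``sigma`` with ``b`` held fixed therefore carries the
slope along with its moving support, which follows the narrow (beta, nu)
posterior ridge instead of getting pinned by it.

Each coordinate is refreshed by a univariate slice update (Neal 2003):
shrinkage on the bounded supports of ``b`` and ``sigma``, stepping-out plus
shrinkage on ``log nu`` (where the prior is Gaussian).  Conditional density
evaluations for ``b`` and ``sigma`` reuse the sufficient statistics
``S_wy = sum w_i y_i`` and ``S_ww = sum w_i^2`` with
``w_i = (x_i - x_min)^nu``, so only ``nu`` updates touch the data.  The
kernel is numba-compiled because an adaptive trial runs one chain per dose
decision and replicated operating-characteristic studies need thousands of
chains.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chain"]

_NEG_INF = -np.inf


@njit(cache=True)
def _beta_of(b, nu, sigma, eta, zgam, span):
    span_nu = span**nu
    lower = (eta - sigma * zgam) / span_nu
    upper = eta / span_nu + sigma * zgam
    return lower + b * (upper - lower)


@njit(cache=True)
def _logpost_suff(b, nu, sigma, n, syy, swy, sww, eta, zgam, sigma_max, delta, span):
    """Log posterior in (b, nu, sigma) using sufficient statistics at ``nu``."""
    if b <= 0.0 or b >= 1.0 or sigma <= 0.0 or sigma >= sigma_max or nu <= 0.0:
        return _NEG_INF
    lnu = np.log(nu)
    lp = -np.log1p(sigma * sigma) - lnu - lnu * lnu / (2.0 * delta * delta)
    if n == 0:
        return lp
    beta = _beta_of(b, nu, sigma, eta, zgam, span)
    ss = syy - 2.0 * beta * swy + beta * beta * sww
    return lp - n * np.log(sigma) - ss / (2.0 * sigma * sigma)


@njit(cache=True)
def _logpost_nu(b, nu, sigma, xs, y, eta, zgam, sigma_max, delta, span):
    """Log posterior with the weights recomputed at a candidate ``nu`` (O(n))."""
    if b <= 0.0 or b >= 1.0 or sigma <= 0.0 or sigma >= sigma_max or nu <= 0.0:
        return _NEG_INF
    lnu = np.log(nu)
    lp = -np.log1p(sigma * sigma) - lnu - lnu * lnu / (2.0 * delta * delta)
    n = xs.size
    if n == 0:
        return lp
    beta = _beta_of(b, nu, sigma, eta, zgam, span)
    ss = 0.0
    for i in range(n):
        d = y[i] - beta * xs[i] ** nu
        ss += d * d
    return lp - n * np.log(sigma) - ss / (2.0 * sigma * sigma)


@njit(cache=True)
def _slice_b(b0, nu, sigma, logp0, n, syy, swy, sww, eta, zgam, sigma_max, delta, span):
    logy = logp0 + np.log(np.random.random())
    left = 0.0
    right = 1.0
    for _ in range(200):
        b1 = left + np.random.random() * (right - left)
        lp = _logpost_suff(b1, nu, sigma, n, syy, swy, sww,
                           eta, zgam, sigma_max, delta, span)
        if lp > logy:
            return b1, lp
        if b1 < b0:
            left = b1
        else:
            right = b1
    return b0, logp0


@njit(cache=True)
def _slice_sigma(sigma0, b, nu, logp0, n, syy, swy, sww, eta, zgam, sigma_max, delta, span):
    logy = logp0 + np.log(np.random.random())
    left = 0.0
    right = sigma_max
    for _ in range(200):
        s1 = left + np.random.random() * (right - left)
        lp = _logpost_suff(b, nu, s1, n, syy, swy, sww,
                           eta, zgam, sigma_max, delta, span)
        if lp > logy:
            return s1, lp
        if s1 < sigma0:
            left = s1
        else:
            right = s1
    return sigma0, logp0


@njit(cache=True)
def _slice_log_nu(nu0, b, sigma, logp0, xs, y, eta, zgam, sigma_max, delta, span,
                  width, max_step):
    """Slice update of ``t = log nu`` with stepping-out; Jacobian term ``+t``."""
    t0 = np.log(nu0)
    logy = logp0 + t0 + np.log(np.random.random())
    u = np.random.random()
    left = t0 - width * u
    right = left + width
    j = int(np.floor(max_step * np.random.random()))
    k = max_step - 1 - j
    while j > 0:
        lp = _logpost_nu(b, np.exp(left), sigma, xs, y,
                         eta, zgam, sigma_max, delta, span)
        if lp + left <= logy:
            break
        left -= width
        j -= 1
    while k > 0:
        lp = _logpost_nu(b, np.exp(right), sigma, xs, y,
                         eta, zgam, sigma_max, delta, span)
        if lp + right <= logy:
            break
        right += width
        k -= 1
    for _ in range(200):
        t1 = left + np.random.random() * (right - left)
        lp = _logpost_nu(b, np.exp(t1), sigma, xs, y,
                         eta, zgam, sigma_max, delta, span)
        if lp + t1 > logy:
            return np.exp(t1), lp
        if t1 < t0:
            left = t1
        else:
            right = t1
    return nu0, logp0


@njit(cache=True)
def run_chain(x, y, x_min, span, eta, zgam, sigma_max, delta,
              n_iterations, n_burnin, thin, seed,
              beta_init, nu_init, sigma_init):
    """One slice-within-Gibbs chain; returns kept (beta, nu, sigma) draws."""
    np.random.seed(seed)
    n = x.size
    xs = x - x_min

    nu = nu_init
    sigma = sigma_init
    span_nu = span**nu
    lower = (eta - sigma * zgam) / span_nu
    upper = eta / span_nu + sigma * zgam
    b = (beta_init - lower) / (upper - lower)
    if b <= 0.0 or b >= 1.0:
        b = 0.5

    syy = 0.0
    swy = 0.0
    sww = 0.0
    for i in range(n):
        w = xs[i] ** nu
        syy += y[i] * y[i]
        swy += w * y[i]
        sww += w * w

    n_keep = (n_iterations - n_burnin + thin - 1) // thin
    out = np.empty((n_keep, 3))
    kept = 0

    lp = _logpost_suff(b, nu, sigma, n, syy, swy, sww, eta, zgam, sigma_max, delta, span)
    for it in range(n_iterations):
        sigma, lp = _slice_sigma(sigma, b, nu, lp, n, syy, swy, sww,
                                 eta, zgam, sigma_max, delta, span)
        nu_new, lp_nu = _slice_log_nu(nu, b, sigma, lp, xs, y,
                                      eta, zgam, sigma_max, delta, span, 1.0, 30)
        if nu_new != nu:
            nu = nu_new
            lp = lp_nu
            swy = 0.0
            sww = 0.0
            for i in range(n):
                w = xs[i] ** nu
                swy += w * y[i]
                sww += w * w
        b, lp = _slice_b(b, nu, sigma, lp, n, syy, swy, sww,
                         eta, zgam, sigma_max, delta, span)
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            out[kept, 0] = _beta_of(b, nu, sigma, eta, zgam, span)
            out[kept, 1] = nu
            out[kept, 2] = sigma
            kept += 1
    return out
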