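"""Elementwise log-densities with analytic gradients.

Each helper returns the elementwise log-pdf together with the partial
derivatives the hierarchical models need (with respect to the variate and,
where the models sample them, the distribution's own parameters). Callers
sum over elements themselves. Constant terms are kept so that log-posterior
values are comparable across parameterizations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, digamma, expit, gammaln, log_ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def norm_logpdf(x, mu, sigma):
    """Normal log-pdf and d/dx, d/dmu, d/dsigma."""
    t = (x - mu) / sigma
    lp = -0.5 * t * t - np.log(sigma) - _LOG_SQRT_2PI
    dx = -t / sigma
    dmu = t / sigma
    dsigma = (t * t - 1.0) / sigma
    return lp, dx, dmu, dsigma


def _log_phi(t):
    return -0.5 * t * t - _LOG_SQRT_2PI


def _log_norm_interval(a, b):
    """log(Phi(b) - Phi(a)) for standard-normal bounds a < b, stable in
    either tail (computed from whichever tail is smaller)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # reflect so that the interval sits in the left tail where log_ndtr is sharp
    flip = (a + b) > 0
    a_, b_ = np.where(flip, -b, a), np.where(flip, -a, b)
    la = log_ndtr(a_)
    lb = log_ndtr(b_)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lb + np.log1p(-np.exp(np.minimum(la - lb, 0.0)))
    # a == b (zero-width) underflows to -inf, which is the correct limit
    return out


def truncnorm_lower_logpdf(x, mu, sigma, lower=0.0):
    """Lower-truncated normal log-pdf and d/dx, d/dmu, d/dsigma.

    Fast path for the common one-sided [lower, inf) case; avoids the
    interval bookkeeping of :func:`truncnorm_logpdf`.
    """
    t = (x - mu) / sigma
    lp = -0.5 * t * t - np.log(sigma) - _LOG_SQRT_2PI
    dx = -t / sigma
    dmu = t / sigma
    dsigma = (t * t - 1.0) / sigma
    a = (lower - mu) / sigma
    log_z = log_ndtr(-a)
    ratio_a = np.exp(_log_phi(a) - log_z)
    lp = lp - log_z
    dmu = dmu - ratio_a / sigma
    dsigma = dsigma - ratio_a * a / sigma
    return lp, dx, dmu, dsigma


def truncnorm_logpdf(x, mu, sigma, lower=-np.inf, upper=np.inf):
    """Truncated-normal log-pdf and d/dx, d/dmu, d/dsigma.

    The normalizer Z = Phi((upper-mu)/sigma) - Phi((lower-mu)/sigma) depends
    on mu and sigma, so its gradient terms matter when the bounds are finite
    and mu/sigma are themselves sampled (hierarchical truncation).
    """
    lp, dx, dmu, dsigma = norm_logpdf(x, mu, sigma)
    shape = np.broadcast_shapes(np.shape(lp), np.shape(lower), np.shape(upper))
    lo = np.broadcast_to(np.asarray(lower, dtype=float), shape)
    hi = np.broadcast_to(np.asarray(upper, dtype=float), shape)
    with np.errstate(invalid="ignore"):
        a = np.where(np.isfinite(lo), (lo - mu) / sigma, -np.inf)
        b = np.where(np.isfinite(hi), (hi - mu) / sigma, np.inf)
    log_z = _log_norm_interval(a, b)
    # phi(t)/Z ratios computed in log space so extreme tails stay finite
    ratio_a = np.where(
        np.isfinite(a), np.exp(np.where(np.isfinite(a), _log_phi(a), -np.inf) - log_z), 0.0
    )
    ratio_b = np.where(
        np.isfinite(b), np.exp(np.where(np.isfinite(b), _log_phi(b), -np.inf) - log_z), 0.0
    )
    lp = lp - log_z
    dmu = dmu + (ratio_b - ratio_a) / sigma
    dsigma = dsigma + (
        ratio_b * np.where(np.isfinite(b), b, 0.0)
        - ratio_a * np.where(np.isfinite(a), a, 0.0)
    ) / sigma
    return lp, dx, dmu, dsigma


def gamma_logpdf(x, shape, rate):
    """Gamma (shape/rate) log-pdf and d/dx."""
    lp = shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    dx = (shape - 1.0) / x - rate
    return lp, dx


def beta_logpdf(x, a, b):
    """Beta log-pdf and d/dx, d/da, d/db (shape gradients use digamma)."""
    lp = (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)
    dx = (a - 1.0) / x - (b - 1.0) / (1.0 - x)
    dab = digamma(a + b)
    da = np.log(x) - digamma(a) + dab
    db = np.log1p(-x) - digamma(b) + dab
    return lp, dx, da, db


def studentt_logpdf(y, mu, sigma, nu):
    """Student-t log-pdf and d/dmu, d/dsigma, d/dnu."""
    t = (y - mu) / sigma
    u = 1.0 + t * t / nu
    lp = (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log(u)
    )
    dmu = (nu + 1.0) * t / (sigma * nu * u)
    dsigma = -1.0 / sigma + (nu + 1.0) * t * t / (sigma * nu * u)
    dnu = (
        0.5 * digamma((nu + 1.0) / 2.0)
        - 0.5 * digamma(nu / 2.0)
        - 0.5 / nu
        - 0.5 * np.log(u)
        + (nu + 1.0) * t * t / (2.0 * nu * nu * u)
    )
    return lp, dmu, dsigma, dnu


def log_sigmoid(x):
    """log(1/(1+exp(-x))), stable for large |x|."""
    return -np.logaddexp(0.0, -x)


def sigmoid(x):
    """Logistic function (scipy's C implementation)."""
    return expit(np.asarray(x, dtype=float))
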