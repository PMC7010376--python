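"""Shared numerics: stable log-pmf/pdf helpers on 1-based arrays."""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, logit, xlog1py, xlogy

__all__ = ["expit", "logit", "binom_logpmf", "norm_logpdf", "as_1based"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def binom_logpmf(k, n, p):
    """Elementwise log binomial pmf including the binomial coefficient.

    Out-of-support k (k < 0 or k > n) gives -inf, as do boundary rates
    incompatible with the data (p = 0 with k > 0, p = 1 with k < n); boundary
    rates compatible with the data give the exact point-mass value 0.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + xlogy(k, p)
            + xlog1py(n - k, -p)
        )
    support = (k >= 0) & (k <= n) & (p >= 0) & (p <= 1)
    return np.where(support, out, -np.inf)


try:  # fast summed version for the sampler's hot loop (identical math)
    import math

    from numba import njit as _njit

    @_njit(cache=False)
    def binom_logpmf_sum(k, n, p):
        total = 0.0
        for i in range(k.shape[0]):
            ki, ni, pi = k[i], n[i], p[i]
            if ki < 0.0 or ki > ni or pi < 0.0 or pi > 1.0:
                return -np.inf
            v = (
                math.lgamma(ni + 1.0)
                - math.lgamma(ki + 1.0)
                - math.lgamma(ni - ki + 1.0)
            )
            if ki > 0.0:
                if pi == 0.0:
                    return -np.inf
                v += ki * math.log(pi)
            if ni - ki > 0.0:
                if pi == 1.0:
                    return -np.inf
                v += (ni - ki) * math.log1p(-pi)
            total += v
        return total

except Exception:  # pragma: no cover

    def binom_logpmf_sum(k, n, p):
        return float(binom_logpmf(k, n, p).sum())


def norm_logpdf(x, mu, sigma):
    """Elementwise normal log-density; sigma <= 0 gives -inf."""
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sigma
        out = -_LOG_SQRT_2PI - np.log(sigma) - 0.5 * z * z
    return np.where(sigma > 0, out, -np.inf)


def as_1based(values, T: int, first: int = 1, last: int | None = None) -> np.ndarray:
    """Return a 1-based array of length T+1 whose valid entries cover
    occasions first..last (last defaults to T).  Accepts either an already
    1-based length-(T+1) array or a plain array of length last-first+1."""
    if last is None:
        last = T
    v = np.asarray(values, dtype=float)
    if v.shape == (T + 1,):
        return v
    if v.shape == (last - first + 1,):
        out = np.full(T + 1, np.nan)
        out[first : last + 1] = v
        return out
    raise ValueError(
        f"expected length {T + 1} (1-based) or {last - first + 1}, got {v.shape}"
    )
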