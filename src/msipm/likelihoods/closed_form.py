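"""Binomial likelihoods for breeding success and (murre) non-breeding.

Both datasets are series of independent annual binomial trials: C(t) chicks
fledged out of E(t) monitored pairs with productivity rho(t), and xi_b(t)
breeders out of xi_m(t) monitored murres with breeding probability B(t).
Log-likelihoods include the binomial coefficients, so they are true log pmfs;
years with zero monitored pairs contribute 0.
"""

from __future__ import annotations

import numpy as np

from ..data import BreedingSuccessSeries, NonBreedingSeries
from ..util import as_1based, binom_logpmf

__all__ = ["bs_loglik", "nb_loglik", "binomial_series_loglik"]


def binomial_series_loglik(k: np.ndarray, n: np.ndarray, rate) -> float:
    """Sum over years of log bin-pmf(k(t); n(t), rate(t)); 1-based arrays."""
    T = len(k) - 1
    r = as_1based(rate, T)
    active = n[1:] > 0
    if not active.any():
        return 0.0
    ll = binom_logpmf(k[1:][active], n[1:][active], r[1:][active])
    return float(ll.sum())


def bs_loglik(data: BreedingSuccessSeries, rho) -> float:
    """Breeding-success log-likelihood: sum_t log bin(C(t); E(t), rho(t)).

    ``rho`` may be a 1-based length-(T+1) array or a plain length-T array.
    Incompatible boundary rates (rho=0 with C>0, rho=1 with C<E) give -inf.
    """
    return binomial_series_loglik(data.C, data.E, rho)


def nb_loglik(data: NonBreedingSeries, B) -> float:
    """Non-breeding log-likelihood: sum_t log bin(xi_b(t); xi_m(t), B(t))."""
    return binomial_series_loglik(data.xi_b, data.xi_m, B)
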