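"""Binomial state-space population model and the count observation model.

System process (per species, females only): new recruits R(t) are the
survivors of the cohort fledged d years earlier,

  R(t) ~ bin(N_a(t-d), tau(t-d) * s_a(t-1)),

with tau = rho * phi_c / 2 for the species without juvenile data (phi_c is
the combined fledging-to-prerecruitment survival-and-fidelity parameter), or
the fully age-structured

  tau_M(t-6) = B(t-6) * rho(t-6) * (1/2) * s1(t-6) * s2 * s35^3 * F5 * F6

for the murre-like species.  Surviving adults S(t) ~ bin(N_a(t-1), s_a(t-1))
and N_a(t) = R(t) + S(t).  Counts are observed with untruncated normal error
x(t) ~ N(N_a(t), sigma_x^2) for t > d; the first d years' counts instead set
informative normal initialization priors on N_a(1..d) with the same SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CountSeries, ValidationError
from .util import as_1based, binom_logpmf, norm_logpdf

__all__ = [
    "LatentPopulation",
    "rp_system_loglik",
    "murre_system_loglik",
    "system_loglik_from_tau",
    "observation_loglik",
    "init_prior_logpdf",
    "init_means_from_counts",
]


@dataclass
class LatentPopulation:
    """Integer latent abundances, 1-based arrays of length T+1.

    ``N[t]`` adult breeding females for t = 1..T; ``R[t]`` and ``S[t]`` the
    recruit/survivor split, defined for t = d+1..T (zero before).
    """

    N: np.ndarray
    R: np.ndarray
    S: np.ndarray
    d: int

    @property
    def T(self) -> int:
        return len(self.N) - 1

    def validate(self) -> None:
        T, d = self.T, self.d
        if (self.N[1:] < 0).any() or (self.R < 0).any() or (self.S < 0).any():
            raise ValidationError("latent abundances must be nonnegative")
        if not np.array_equal(self.N[d + 1 :], (self.R + self.S)[d + 1 :]):
            raise ValidationError("N(t) must equal R(t) + S(t) for t > d")


def system_loglik_from_tau(latent: LatentPopulation, tau, s_a, d: int) -> float:
    """Shared binomial system-process likelihood: for t = d+1..T,
    R(t) ~ bin(N(t-d), tau(t-d)*s_a(t-1)) and S(t) ~ bin(N(t-1), s_a(t-1))."""
    T = latent.T
    tau = as_1based(tau, T)
    s_a = as_1based(s_a, T, first=1, last=T - 1)
    t = np.arange(d + 1, T + 1)
    rate_R = tau[t - d] * s_a[t - 1]
    ll = binom_logpmf(latent.R[t], latent.N[t - d], rate_R)
    ll = ll + binom_logpmf(latent.S[t], latent.N[t - 1], s_a[t - 1])
    return float(ll.sum())


def rp_system_loglik(latent: LatentPopulation, rho, s_a, phi_c: float, d: int) -> float:
    """System-process likelihood with the combined-juvenile-survival recruit
    rate tau = rho * phi_c / 2 (razorbill/puffin structural variant)."""
    T = latent.T
    tau = as_1based(rho, T) * phi_c / 2.0
    return system_loglik_from_tau(latent, tau, s_a, d)


def murre_system_loglik(
    latent: LatentPopulation, B, rho, s1, s2, s35, F5, F6, s_a
) -> float:
    """System-process likelihood with the age-structured recruit rate
    tau(t-6) = B*rho*(1/2)*s1*s2*s35^3*F5*F6 evaluated at t-6 (d = 6)."""
    T = latent.T
    tau = (
        as_1based(B, T)
        * as_1based(rho, T)
        * 0.5
        * as_1based(s1, T, first=1, last=T - 1)
        * s2
        * s35**3
        * F5
        * F6
    )
    return system_loglik_from_tau(latent, tau, s_a, d=6)


def observation_loglik(
    x: CountSeries, latent: LatentPopulation, sigma_x: float, d: int
) -> float:
    """Normal observation log-density of the non-missing counts at t > d."""
    if sigma_x <= 0:
        return -np.inf
    T = latent.T
    t = x.observed_years()
    t = t[t > d]
    if t.size == 0:
        return 0.0
    return float(norm_logpdf(x.x[t], latent.N[t], sigma_x).sum())


def init_means_from_counts(x: CountSeries, d: int) -> np.ndarray:
    """Initialization-prior means for N_a(1..d): the observed counts, with
    missing years filled by linear interpolation between the nearest counted
    years (1-based array of length d+1)."""
    obs = x.observed_years()
    if obs.size == 0:
        raise ValidationError("cannot build initialization priors: no counts at all")
    means = np.interp(np.arange(0, d + 1, dtype=float), obs, x.x[obs])
    means[0] = np.nan
    return means


def init_prior_logpdf(latent: LatentPopulation, init_means, sigma_x: float) -> float:
    """Informative normal priors N(init_mean(t), sigma_x^2) on N_a(1..d)."""
    if sigma_x <= 0:
        return -np.inf
    d = latent.d
    means = np.asarray(init_means, dtype=float)
    if means.shape == (d,):
        means = np.concatenate([[np.nan], means])
    return float(norm_logpdf(latent.N[1 : d + 1], means[1 : d + 1], sigma_x).sum())
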