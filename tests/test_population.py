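import math

import numpy as np
import pytest

from msipm.config import StudyConfig
from msipm.data import CountSeries
from msipm.population import (
    LatentPopulation,
    init_means_from_counts,
    init_prior_logpdf,
    murre_system_loglik,
    observation_loglik,
    rp_system_loglik,
)


def binom_logpmf_oracle(k, n, p):
    """math.comb-based binomial log pmf, independent of scipy."""
    if not (0 <= k <= n):
        return -np.inf
    c = math.comb(int(n), int(k))
    if p == 0.0:
        return math.log(c) if k == 0 else -np.inf
    if p == 1.0:
        return math.log(c) if k == n else -np.inf
    return math.log(c) + k * math.log(p) + (n - k) * math.log(1 - p)


def toy_latent(T, d, rng, N0=200):
    N = np.zeros(T + 1)
    R = np.zeros(T + 1)
    S = np.zeros(T + 1)
    N[1 : d + 1] = N0 + rng.integers(-10, 10, d)
    for t in range(d + 1, T + 1):
        S[t] = rng.integers(int(0.7 * N[t - 1]), int(0.95 * N[t - 1]))
        R[t] = rng.integers(0, max(1, int(0.2 * N[t - d])))
        N[t] = R[t] + S[t]
    return LatentPopulation(N, R, S, d)


class TestSystemProcess:
    def test_recruit_rate_composition(self, rng):
        """The recruit success probability is exactly rho(t-d)*phi_c*s_a(t-1)/2."""
        T, d = 8, 5
        lat = toy_latent(T, d, rng)
        rho = np.concatenate([[np.nan], np.full(T, 0.6)])
        s_a = np.concatenate([[np.nan], np.full(T - 1, 0.9), [np.nan]])
        phi_c = 0.5
        ll = rp_system_loglik(lat, rho, s_a, phi_c, d)
        rate = 0.6 * phi_c * 0.9 / 2.0
        want = sum(
            binom_logpmf_oracle(lat.R[t], lat.N[t - d], rate)
            + binom_logpmf_oracle(lat.S[t], lat.N[t - 1], 0.9)
            for t in range(d + 1, T + 1)
        )
        assert ll == pytest.approx(want, abs=1e-9)

    def test_toy_trajectory_matches_pmf_oracle(self, rng):
        T, d = 8, 5
        lat = toy_latent(T, d, rng)
        rho1 = np.concatenate([[np.nan], rng.uniform(0.4, 0.8, T)])
        sa1 = np.concatenate([[np.nan], rng.uniform(0.8, 0.95, T - 1), [np.nan]])
        phi_c = 0.45
        ll = rp_system_loglik(lat, rho1, sa1, phi_c, d)
        want = 0.0
        for t in range(d + 1, T + 1):
            rate = rho1[t - d] * phi_c * sa1[t - 1] / 2.0
            want += binom_logpmf_oracle(lat.R[t], lat.N[t - d], rate)
            want += binom_logpmf_oracle(lat.S[t], lat.N[t - 1], sa1[t - 1])
        assert ll == pytest.approx(want, abs=1e-9)

    def test_impossible_survivors_score_minus_inf(self, rng):
        T, d = 8, 5
        lat = toy_latent(T, d, rng)
        lat.S[6] = lat.N[5] + 1
        lat.N[6] = lat.R[6] + lat.S[6]
        rho1 = np.concatenate([[np.nan], np.full(T, 0.6)])
        sa1 = np.concatenate([[np.nan], np.full(T - 1, 0.9), [np.nan]])
        assert rp_system_loglik(lat, rho1, sa1, 0.5, d) == -np.inf

    def test_murre_variant_reduces_to_combined_form(self, rng):
        """With B=1, s2=s35=F5=F6=1 and s1 constant = phi_c, the murre recruit
        rate equals the combined-survival form at d=6."""
        T, d = 10, 6
        lat = toy_latent(T, d, rng)
        rho1 = np.concatenate([[np.nan], rng.uniform(0.4, 0.8, T)])
        sa1 = np.concatenate([[np.nan], rng.uniform(0.8, 0.95, T - 1), [np.nan]])
        phi_c = 0.37
        B = np.concatenate([[np.nan], np.ones(T)])
        s1 = np.concatenate([[np.nan], np.full(T - 1, phi_c), [np.nan]])
        v1 = murre_system_loglik(lat, B, rho1, s1, 1.0, 1.0, 1.0, 1.0, sa1)
        v2 = rp_system_loglik(lat, rho1, sa1, phi_c, d)
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_s35_enters_cubed(self, rng):
        T, d = 10, 6
        lat = toy_latent(T, d, rng)
        rho1 = np.concatenate([[np.nan], np.full(T, 0.6)])
        sa1 = np.concatenate([[np.nan], np.full(T - 1, 0.9), [np.nan]])
        B = np.concatenate([[np.nan], np.full(T, 0.9)])
        s1 = np.concatenate([[np.nan], np.full(T - 1, 0.5), [np.nan]])
        s35, eps = 0.9, 1e-6
        base_rate = 0.9 * 0.6 * 0.5 * 0.7 * s35**3 * 0.9 * 0.85 * 0.5
        up_rate = base_rate * ((s35 + eps) / s35) ** 3
        # first-order: d log(rate) = 3 eps / s35
        assert np.log(up_rate / base_rate) == pytest.approx(3 * eps / s35, rel=1e-4)
        v0 = murre_system_loglik(lat, B, rho1, s1, 0.7, s35, 0.9, 0.85, sa1)
        v1 = murre_system_loglik(lat, B, rho1, s1, 0.7, s35 + eps, 0.9, 0.85, sa1)
        # numerical derivative of the recruit term wrt log s35 equals
        # 3 * (sum R - sum (N-R) rate/(1-rate)) -- just check sensitivity sign/scale
        num = (v1 - v0) / eps
        t = np.arange(d + 1, T + 1)
        rate = base_rate * 0.9
        anal = sum(
            3 / s35 * (lat.R[t_] - (lat.N[t_ - d] - lat.R[t_]) * rate / (1 - rate))
            for t_ in t
        )
        assert num == pytest.approx(anal, rel=1e-3)


class TestObservationModel:
    def test_zero_residuals(self, rng):
        T, d = 8, 2
        lat = toy_latent(T, d, rng)
        x = CountSeries.from_values(lat.N[1:], T)
        ll = observation_loglik(x, lat, 1.0, d)
        assert ll == pytest.approx(-(T - d) * np.log(np.sqrt(2 * np.pi)), abs=1e-10)

    def test_single_observation_closed_form(self, rng):
        T, d = 8, 2
        lat = toy_latent(T, d, rng)
        vals = np.full(T, np.nan)
        vals[4] = lat.N[5] + 2.0
        x = CountSeries.from_values(vals, T)
        ll = observation_loglik(x, lat, 2.0, d)
        assert ll == pytest.approx(-np.log(2 * np.sqrt(2 * np.pi)) - 0.5, abs=1e-12)

    def test_sparse_counts_contribute_only_after_initialization(self):
        """With the full 26-year design, the puffin likelihood sees exactly
        the five counts after the 7-year initialization window."""
        cfg = StudyConfig.full_study()
        puffin = cfg.species_by_code("P")
        vals = np.full(cfg.T, np.nan)
        for t in puffin.count_years:
            vals[t - 1] = 1000.0
        x = CountSeries.from_values(vals, cfg.T)
        tobs = x.observed_years()
        assert list(tobs[tobs > puffin.d]) == [9, 15, 20, 25, 26]
        lat = LatentPopulation(
            np.full(cfg.T + 1, 1000.0), np.zeros(cfg.T + 1), np.zeros(cfg.T + 1), puffin.d
        )
        ll = observation_loglik(x, lat, 3.0, puffin.d)
        assert ll == pytest.approx(5 * (-np.log(3 * np.sqrt(2 * np.pi))), abs=1e-10)


class TestInitialization:
    def test_full_counts_give_observed_means(self, rng):
        T, d = 8, 3
        vals = rng.uniform(100, 200, T)
        x = CountSeries.from_values(vals, T)
        means = init_means_from_counts(x, d)
        assert np.allclose(means[1:], vals[:d])

    def test_sparse_anchors_interpolate_linearly(self):
        """Anchors at occasions 1 and 6 (and 9): intermediate init years are
        linear interpolations; the year after the second anchor interpolates
        toward the next count."""
        T, d = 12, 7
        vals = np.full(T, np.nan)
        vals[0], vals[5], vals[8] = 1000.0, 2000.0, 3200.0
        x = CountSeries.from_values(vals, T)
        means = init_means_from_counts(x, d)
        assert means[3] == pytest.approx(1000 + 2 * (2000 - 1000) / 5)
        assert means[7] == pytest.approx(2000 + (3200 - 2000) / 3)

    def test_single_year_window_reduces_to_one_normal_term(self, rng):
        T, d = 6, 1
        lat = toy_latent(T, d, rng)
        ll = init_prior_logpdf(lat, np.array([lat.N[1] + 1.0]), 1.0)
        assert ll == pytest.approx(-np.log(np.sqrt(2 * np.pi)) - 0.5, abs=1e-12)


class TestGenerativeConsistency:
    def test_mean_trajectory_matches_mean_recursion(self, rng):
        """Iterating expectations reproduces the Monte-Carlo mean of the
        binomial system process."""
        T, d, N0 = 12, 3, 400
        rho, phi_c, s_a = 0.6, 0.5, 0.9
        rate = rho * phi_c * s_a / 2.0
        nsim = 3000
        N = np.full((nsim, T + 1), 0.0)
        N[:, 1 : d + 1] = N0
        for t in range(d + 1, T + 1):
            R = rng.binomial(N[:, t - d].astype(int), rate)
            S = rng.binomial(N[:, t - 1].astype(int), s_a)
            N[:, t] = R + S
        EN = np.full(T + 1, float(N0))
        for t in range(d + 1, T + 1):
            EN[t] = EN[t - d] * rate + EN[t - 1] * s_a
        mc = N[:, T].mean()
        se = N[:, T].std(ddof=1) / np.sqrt(nsim)
        assert abs(mc - EN[T]) < 3 * se
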