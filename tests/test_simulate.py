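import numpy as np

from msipm.data import build_mrr_sufficient_stats
from msipm.likelihoods.mrr import mrr_loglik
from msipm.simulate import (
    default_scenario,
    simulate_bundle,
    simulate_latents,
    simulate_marked_individuals,
    simulate_observations,
)
from msipm.util import expit, logit


def frozen_scenario(T=10):
    """All between-year variability switched off."""
    sc = default_scenario(T)
    sc.sigma_delta_rho = sc.sigma_delta_phi = 0.0
    sc.sigma_eps_rho = {S: 0.0 for S in "RPM"}
    sc.sigma_eps_phi = {S: 0.0 for S in "RPM"}
    sc.B_sd_logit = 0.0
    sc.s1_sd_logit = 0.0
    return sc


class TestLatents:
    def test_zero_variance_gives_constant_rates(self):
        sc = frozen_scenario()
        truth = simulate_latents(sc, np.random.default_rng(1))
        for S in "RPM":
            assert np.allclose(truth.rates[f"rho_{S}"][1:], expit(sc.beta_rho[S]))
            assert np.allclose(
                truth.rates[f"s_a_{S}"][1 : sc.study.T], expit(sc.beta_phi[S])
            )

    def test_fixed_seed_reproducible(self):
        sc = default_scenario(T=10)
        t1 = simulate_latents(sc, np.random.default_rng(77))
        t2 = simulate_latents(sc, np.random.default_rng(77))
        for S in "RPM":
            assert np.array_equal(t1.latents[S].N, t2.latents[S].N)

    def test_mean_trajectory_matches_deterministic_recursion(self):
        """At frozen rates the Monte-Carlo mean trajectory agrees with the
        iterated-expectation recursion within Monte-Carlo error."""
        sc = frozen_scenario(T=10)
        nsim = 400
        S, d = "R", 5
        ends = np.empty(nsim)
        for i in range(nsim):
            truth = simulate_latents(sc, np.random.default_rng(1000 + i))
            ends[i] = truth.latents[S].N[sc.study.T]
        rho = expit(sc.beta_rho[S])
        sa = expit(sc.beta_phi[S])
        rate = rho * sc.phi_c[S] * sa / 2.0
        EN = np.zeros(sc.study.T + 1)
        EN[1 : d + 1] = np.round(sc.N0[S] * (1 + sc.init_growth) ** np.arange(d))
        for t in range(d + 1, sc.study.T + 1):
            EN[t] = EN[t - d] * rate + EN[t - 1] * sa
        se = ends.std(ddof=1) / np.sqrt(nsim)
        assert abs(ends.mean() - EN[sc.study.T]) < 3 * se


class TestObservations:
    def test_zero_observation_noise_reproduces_latents(self):
        sc = frozen_scenario()
        sc.sigma_x = {S: 0.0 for S in "RPM"}
        rng = np.random.default_rng(3)
        truth = simulate_latents(sc, rng)
        obs = simulate_observations(truth, sc, rng)
        x = obs["R"]["counts"].x
        assert np.allclose(x[1:], truth.latents["R"].N[1:])

    def test_sparse_species_mask_has_seven_counts(self):
        sc = default_scenario()  # T = 15 default
        rng = np.random.default_rng(4)
        truth = simulate_latents(sc, rng)
        obs = simulate_observations(truth, sc, rng)
        assert obs["P"]["counts"].observed_years().size == 7

    def test_breeding_success_frequencies_match_rates(self):
        sc = frozen_scenario()
        rng = np.random.default_rng(5)
        truth = simulate_latents(sc, rng)
        rho = truth.rates["rho_M"][1]
        E = sc.E["M"]
        nrep = 400
        phat = np.array(
            [
                simulate_observations(truth, sc, np.random.default_rng(10_000 + i))[
                    "M"
                ]["breeding"].C[1]
                / E
                for i in range(nrep)
            ]
        )
        se = np.sqrt(rho * (1 - rho) / (E * nrep))
        assert abs(phat.mean() - rho) < 4 * se


class TestMarkedIndividuals:
    def test_no_unobservable_alive_states_when_fidelity_perfect(self):
        sc = frozen_scenario()
        sc.F5 = sc.F6 = sc.psi = 1.0
        rng = np.random.default_rng(6)
        truth = simulate_latents(sc, rng)
        _, chicks = simulate_marked_individuals(truth, sc, rng)
        assert all(f["state0"] is None for f in truth.fates["chicks"])

    def test_empirical_first_year_survival(self):
        sc = frozen_scenario(T=10)
        sc.chicks_banded = {"A": 1500, "B": 0}
        rng = np.random.default_rng(7)
        truth = simulate_latents(sc, rng)
        _, chicks = simulate_marked_individuals(truth, sc, rng)
        fates = truth.fates["chicks"]
        assert len(fates) == len(chicks)
        for t0 in (1, 4):
            idx = [i for i, r in enumerate(chicks) if r.t0 == t0]
            died = sum(1 for i in idx if fates[i]["death"] == t0)
            surv = 1 - died / len(idx)
            s1 = truth.rates["s1"][t0]
            se = np.sqrt(s1 * (1 - s1) / len(idx))
            assert abs(surv - s1) < 4 * se

    def test_truth_beats_perturbed_parameters_on_simulated_mrr(self):
        """The chick MRR likelihood prefers the generating parameters to a
        uniformly logit-shifted alternative in nearly all replicates."""
        sc = frozen_scenario(T=10)
        sc.chicks_banded = {"A": 300, "B": 0}
        wins = 0
        nrep = 15
        for i in range(nrep):
            rng = np.random.default_rng(20_000 + i)
            truth = simulate_latents(sc, rng)
            _, chicks = simulate_marked_individuals(truth, sc, rng)
            stats = build_mrr_sufficient_stats(chicks, sc.study)

            def make(perturb):
                T = sc.study.T
                p = {}
                for area in sc.study.areas:
                    p[area] = {}
                    for cls, val in sc.chick_p[area].items():
                        lo, hi = sc.study.window(area, cls)
                        arr = np.full(T + 1, np.nan)
                        arr[lo : hi + 1] = expit(logit(val) + perturb)
                        p[area][cls] = arr
                from msipm.likelihoods.mrr import MRRStructuralParams

                return MRRStructuralParams(
                    s1=np.concatenate([truth.rates["s1"][:T], [np.nan]])
                    if perturb == 0
                    else np.concatenate(
                        [expit(logit(truth.rates["s1"][:T]) + perturb), [np.nan]]
                    ),
                    s2=expit(logit(sc.s2) + perturb),
                    s35=expit(logit(sc.s35) + perturb),
                    s_a=expit(logit(truth.rates["s_a_M"]) + perturb),
                    F5=expit(logit(sc.F5) + perturb),
                    F6=expit(logit(sc.F6) + perturb),
                    psi=expit(logit(sc.psi) + perturb),
                    alpha0=sc.alpha0 + perturb,
                    alpha1=sc.alpha1,
                    p=p,
                )

            llt = mrr_loglik(stats["A"], stats["B"], make(0.0), sc.study)
            llp = mrr_loglik(stats["A"], stats["B"], make(0.2), sc.study)
            wins += llt > llp
        assert wins >= int(0.9 * nrep)


class TestEndToEnd:
    def test_bundle_validates_and_cohorts_reconcile(self):
        sc = default_scenario(T=12)
        bundle, truth = simulate_bundle(sc, seed=31)
        bundle.validate()
        recs = bundle["M"].chick_records
        for area, st in bundle["M"].mrr_stats.items():
            assert st.total_birds() == sum(1 for r in recs if r.area == area)
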