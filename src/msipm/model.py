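"""Joint posterior assembly for the multi-species IPM.

A :class:`JointModel` binds a validated :class:`~msipm.data.DatasetBundle` to
a parameter layout and a list of log-likelihood/log-density *components*:

  BS_S      breeding-success binomial likelihood, per species
  NB        non-breeding binomial likelihood (murre-like species)
  CJS_S     adult mark-resight likelihood, per species
  MRR_A/B   chick mark-resight-recovery likelihood, per banding area
  SYS_S     binomial system process of the latent population
  OBS_S     normal count observation model (t > d)
  INIT_S    informative initialization priors on N_a(1..d)
  RE_*      mean-zero normal densities of the year random effects

The joint log posterior is the sum of all components plus the proper priors
of the top-level parameters.  Each parameter block records which components
depend on it, which is what makes single-site Metropolis updates affordable.

The parameter state is a plain ``dict[str, np.ndarray]`` (every block a 1-D
array, scalars length-1); all probability-scale parameters live on their
natural scale except the adult resight baselines, stored as logits
(``lpstar_S``) to carry their normal prior.

Species with no counts at all get no latent block and no population
components (there is nothing to anchor a state-space model to); their
demographic parameters are then informed by the remaining datasets only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RESIGHT_CLASSES, StudyConfig
from .data import DatasetBundle
from .likelihoods.cjs import cjs_loglik_core, prepare_histories
from .likelihoods.closed_form import binomial_series_loglik
from .likelihoods.mrr import (
    MRRStructuralParams,
    compute_mrr_tables,
    mrr_loglik_prepared,
    prepare_mrr_stats,
    standardized_years,
)
from .population import LatentPopulation, init_means_from_counts
from .priors import PriorSpec, default_priors
from .util import binom_logpmf_sum, expit, logit, norm_logpdf

__all__ = ["Block", "Component", "JointModel", "joint_logposterior", "ParameterState"]

#: A full point in parameter space: block name -> 1-D array.
ParameterState = dict


@dataclass
class Block:
    name: str
    size: int
    group: str  # prior group key
    labels: list[int]  # occasion (or age) labels per element; [0] for scalars
    integer: bool = False
    comp_ids: list[int] = field(default_factory=list)


@dataclass
class Component:
    name: str
    fn: object  # state -> float


class JointModel:
    def __init__(
        self,
        bundle: DatasetBundle,
        priors: PriorSpec | None = None,
        config: StudyConfig | None = None,
    ):
        self.bundle = bundle
        self.config = config or bundle.config
        bundle.validate()
        if priors is None:
            priors = default_priors(
                {s.code: s.sigma_x_upper for s in self.config.species}
            )
        self.priors = priors
        self.blocks: dict[str, Block] = {}
        self.components: list[Component] = []
        self._build()

    # ------------------------------------------------------------------
    def _add_block(self, name, size, group, labels=None, integer=False):
        self.blocks[name] = Block(
            name, size, group, labels if labels is not None else [0] * size, integer
        )

    def _add_component(self, name, fn, dep_blocks):
        cid = len(self.components)
        self.components.append(Component(name, fn))
        for b in dep_blocks:
            if b in self.blocks:
                self.blocks[b].comp_ids.append(cid)

    # -- rate assembly on the current state -----------------------------
    def rate_series(self, state, kind: str, S: str) -> np.ndarray:
        """1-based logistic rate series for ``kind`` in {"rho", "phi"}."""
        L = self.config.T if kind == "rho" else self.config.T - 1
        out = np.empty(L + 1)
        out[0] = np.nan
        out[1:] = expit(
            state[f"beta_{kind}_{S}"][0] + state[f"delta_{kind}"] + state[f"eps_{kind}_{S}"]
        )
        return out

    def _pad1(self, vec, first=1):
        out = np.zeros(self.config.T + 1)
        out[first : first + len(vec)] = vec
        return out

    def latent(self, state, S: str) -> LatentPopulation:
        T = self.config.T
        d = self.config.species_by_code(S).d
        N = np.zeros(T + 1)
        R = np.zeros(T + 1)
        Su = np.zeros(T + 1)
        N[1 : d + 1] = state[f"Ninit_{S}"]
        R[d + 1 :] = state[f"R_{S}"]
        Su[d + 1 :] = state[f"Ssur_{S}"]
        N[d + 1 :] = R[d + 1 :] + Su[d + 1 :]
        return LatentPopulation(N, R, Su, d)

    def mrr_tables(self, state, area: str):
        """Expanded MRR probability tables at ``state`` for one banding area.

        A fused fast path equivalent to ``assemble_age_year_params`` followed
        by ``compute_mrr_tables`` (asserted equal in the test suite)."""
        cfg = self.config
        A, T = cfg.A, cfg.T
        sM = cfg.mrr_species.code
        ts = slice(1, T)
        phi = np.zeros((A + 1, T + 1))
        phi[1, ts] = state["s1"]
        phi[2, ts] = state["s2"][0]
        phi[3:6, ts] = state["s35"][0]
        sa_sub = expit(
            state[f"beta_phi_{sM}"][0] + state["delta_phi"] + state[f"eps_phi_{sM}"]
        )
        phi[6:, ts] = sa_sub[None, :]
        F = np.zeros((A + 1, T + 1))
        F[1:5, ts] = 1.0
        F[5, ts] = state["F5"][0]
        F[6, ts] = state["F6"][0]
        F[7:, ts] = state["psi"][0]
        lam = np.zeros((A + 1, T + 1))
        lam[1:, ts] = expit(
            state["alpha0"][0] + state["alpha1"][0] * standardized_years(T)[ts]
        )[None, :]
        p = np.zeros((A + 1, T + 1))
        for name, alo, ahi, lo, hi in self._p_templates[area]:
            p[alo : ahi + 1, lo : hi + 1] = state[name][None, :]
        return compute_mrr_tables(phi, F, p, lam, A, T)

    def mrr_structural(self, state) -> MRRStructuralParams:
        cfg = self.config
        T = cfg.T
        sM = cfg.mrr_species.code
        p = {}
        for area in cfg.areas:
            p[area] = {}
            for cls in RESIGHT_CLASSES:
                lo, hi = cfg.window(area, cls)
                arr = np.full(T + 1, np.nan)
                arr[lo : hi + 1] = state[f"pw_{area}_{cls}"]
                p[area][cls] = arr
        return MRRStructuralParams(
            s1=self._pad1(state["s1"]),
            s2=state["s2"][0],
            s35=state["s35"][0],
            s_a=self.rate_series(state, "phi", sM),
            F5=state["F5"][0],
            F6=state["F6"][0],
            psi=state["psi"][0],
            alpha0=state["alpha0"][0],
            alpha1=state["alpha1"][0],
            p=p,
        )

    # ------------------------------------------------------------------
    def _build(self):
        cfg = self.config
        T = cfg.T
        bundle = self.bundle

        # ---- parameter blocks ----
        self._add_block("delta_rho", T, "effect", list(range(1, T + 1)))
        self._add_block("delta_phi", T - 1, "effect", list(range(1, T)))
        self._add_block("sigma_delta_rho", 1, "re_sd")
        self._add_block("sigma_delta_phi", 1, "re_sd")
        self.has_latents: dict[str, bool] = {}
        for sp in cfg.species:
            S = sp.code
            self._add_block(f"beta_rho_{S}", 1, "intercept")
            self._add_block(f"beta_phi_{S}", 1, "intercept")
            self._add_block(f"eps_rho_{S}", T, "effect", list(range(1, T + 1)))
            self._add_block(f"eps_phi_{S}", T - 1, "effect", list(range(1, T)))
            self._add_block(f"sigma_eps_rho_{S}", 1, "re_sd")
            self._add_block(f"sigma_eps_phi_{S}", 1, "re_sd")
            self._add_block(f"lpstar_{S}", T - 1, "logit_pstar", list(range(2, T + 1)))
            self._add_block(f"a_{S}", 1, "intercept")
            if not sp.murre_like:
                self._add_block(f"phi_c_{S}", 1, "prob")
            has_lat = bundle[S].counts.observed_years().size > 0
            self.has_latents[S] = has_lat
            if has_lat:
                d = sp.d
                self._add_block(f"sigma_x_{S}", 1, "sigma_x")
                self._add_block(f"Ninit_{S}", d, "latent", list(range(1, d + 1)), integer=True)
                self._add_block(f"R_{S}", T - d, "latent", list(range(d + 1, T + 1)), integer=True)
                self._add_block(f"Ssur_{S}", T - d, "latent", list(range(d + 1, T + 1)), integer=True)
        murre = cfg.mrr_species
        if murre is not None:
            if murre.d != 6:
                raise ValueError("the age-structured recruit rate assumes d = 6")
            self._add_block("B", T, "prob", list(range(1, T + 1)))
            self._add_block("s1", T - 1, "prob", list(range(1, T)))
            for nm in ("s2", "s35", "F5", "F6", "psi"):
                self._add_block(nm, 1, "prob")
            self._add_block("alpha0", 1, "intercept")
            self._add_block("alpha1", 1, "intercept")
            self._p_templates: dict[str, list] = {}
            for area in cfg.areas:
                self._p_templates[area] = []
                for cls, (alo, ahi) in RESIGHT_CLASSES.items():
                    lo, hi = cfg.window(area, cls)
                    self._add_block(
                        f"pw_{area}_{cls}", hi - lo + 1, "prob", list(range(lo, hi + 1))
                    )
                    self._p_templates[area].append(
                        (f"pw_{area}_{cls}", alo, cfg.A if ahi is None else ahi, lo, hi)
                    )

        # ---- components ----
        rho_deps_all, phi_deps_all = [], []

        _lsq2pi = 0.5 * np.log(2.0 * np.pi)

        def re_comp(vec_name, sd_name):
            def fn(state, v=vec_name, s=sd_name):
                sd = state[s][0]
                vec = state[v]
                if sd <= 0:
                    return -np.inf if np.any(vec != 0) else 0.0
                return float(
                    -0.5 * (vec @ vec) / (sd * sd) - vec.size * (np.log(sd) + _lsq2pi)
                )

            return fn

        self._add_component("RE_delta_rho", re_comp("delta_rho", "sigma_delta_rho"),
                            ["delta_rho", "sigma_delta_rho"])
        self._add_component("RE_delta_phi", re_comp("delta_phi", "sigma_delta_phi"),
                            ["delta_phi", "sigma_delta_phi"])
        for sp in cfg.species:
            S = sp.code
            self._add_component(f"RE_eps_rho_{S}", re_comp(f"eps_rho_{S}", f"sigma_eps_rho_{S}"),
                                [f"eps_rho_{S}", f"sigma_eps_rho_{S}"])
            self._add_component(f"RE_eps_phi_{S}", re_comp(f"eps_phi_{S}", f"sigma_eps_phi_{S}"),
                                [f"eps_phi_{S}", f"sigma_eps_phi_{S}"])

        for sp in cfg.species:
            S = sp.code
            sd = bundle[S]
            rho_deps = [f"beta_rho_{S}", f"eps_rho_{S}", "delta_rho"]
            phi_deps = [f"beta_phi_{S}", f"eps_phi_{S}", "delta_phi"]
            # breeding success
            if (sd.breeding.E[1:] > 0).any():
                E1, C1 = sd.breeding.E, sd.breeding.C

                def bs_fn(state, S=S, E1=E1, C1=C1):
                    return binomial_series_loglik(C1, E1, self.rate_series(state, "rho", S))

                self._add_component(f"BS_{S}", bs_fn, rho_deps)
            # adult CJS
            if sd.adults:
                fa, la, seen = prepare_histories(sd.adults, T)

                def cjs_fn(state, S=S, fa=fa, la=la, seen=seen):
                    s1b = self._pad1_rate(self.rate_series(state, "phi", S))
                    ps1b = self._pad1(expit(state[f"lpstar_{S}"]), first=2)
                    return cjs_loglik_core(fa, la, seen, s1b, ps1b, state[f"a_{S}"][0])

                self._add_component(f"CJS_{S}", cjs_fn, phi_deps + [f"lpstar_{S}", f"a_{S}"])
            # population state space
            if self.has_latents[S]:
                d = sp.d
                x = sd.counts
                init_means = init_means_from_counts(x, d)
                tobs = x.observed_years()
                tobs = tobs[tobs > d]
                xobs = x.x[tobs]

                murre_like = sp.murre_like
                if murre_like:
                    sys_deps = (
                        rho_deps + phi_deps
                        + ["B", "s1", "s2", "s35", "F5", "F6",
                           f"Ninit_{S}", f"R_{S}", f"Ssur_{S}"]
                    )
                else:
                    sys_deps = (
                        rho_deps + phi_deps
                        + [f"phi_c_{S}", f"Ninit_{S}", f"R_{S}", f"Ssur_{S}"]
                    )

                def sys_fn(state, S=S, d=d, murre_like=murre_like, T=T):
                    # R(t) ~ bin(N(t-d), tau(t-d)*s_a(t-1)),
                    # S(t) ~ bin(N(t-1), s_a(t-1)),  t = d+1..T
                    R = state[f"R_{S}"]
                    Su = state[f"Ssur_{S}"]
                    N = np.empty(T + 1)
                    N[1 : d + 1] = state[f"Ninit_{S}"]
                    N[d + 1 :] = R + Su
                    nlag = T - d
                    rho_sub = expit(
                        state[f"beta_rho_{S}"][0]
                        + state["delta_rho"][:nlag]
                        + state[f"eps_rho_{S}"][:nlag]
                    )
                    sa_sub = expit(
                        state[f"beta_phi_{S}"][0]
                        + state["delta_phi"][d - 1 : T - 1]
                        + state[f"eps_phi_{S}"][d - 1 : T - 1]
                    )
                    if murre_like:
                        tau_sub = (
                            state["B"][:nlag] * rho_sub * 0.5 * state["s1"][:nlag]
                            * state["s2"][0] * state["s35"][0] ** 3
                            * state["F5"][0] * state["F6"][0]
                        )
                    else:
                        tau_sub = rho_sub * state[f"phi_c_{S}"][0] / 2.0
                    ll = binom_logpmf_sum(R, N[1 : nlag + 1], tau_sub * sa_sub)
                    if ll == -np.inf:
                        return ll
                    return ll + binom_logpmf_sum(Su, N[d:T], sa_sub)

                self._add_component(f"SYS_{S}", sys_fn, sys_deps)

                def obs_fn(state, S=S, d=d, tobs=tobs, xobs=xobs):
                    sx = state[f"sigma_x_{S}"][0]
                    if sx <= 0:
                        return -np.inf
                    if tobs.size == 0:
                        return 0.0
                    Nt = (state[f"R_{S}"] + state[f"Ssur_{S}"])[tobs - d - 1]
                    return float(norm_logpdf(xobs, Nt, sx).sum())

                self._add_component(
                    f"OBS_{S}", obs_fn, [f"sigma_x_{S}", f"R_{S}", f"Ssur_{S}"]
                )

                def init_fn(state, S=S, d=d, init_means=init_means):
                    sx = state[f"sigma_x_{S}"][0]
                    if sx <= 0:
                        return -np.inf
                    return float(
                        norm_logpdf(state[f"Ninit_{S}"], init_means[1:], sx).sum()
                    )

                self._add_component(f"INIT_{S}", init_fn, [f"sigma_x_{S}", f"Ninit_{S}"])
            rho_deps_all += rho_deps
            phi_deps_all += phi_deps

        if murre is not None:
            M = murre.code
            sd = bundle[M]
            if sd.nonbreeding is not None and (sd.nonbreeding.xi_m[1:] > 0).any():
                nb = sd.nonbreeding

                def nb_fn(state, nb=nb):
                    return binomial_series_loglik(nb.xi_b, nb.xi_m, self._pad1(state["B"]))

                self._add_component("NB", nb_fn, ["B"])
            if sd.mrr_stats:
                phi_deps_M = [f"beta_phi_{M}", f"eps_phi_{M}", "delta_phi"]
                shared = ["s1", "s2", "s35", "F5", "F6", "psi", "alpha0", "alpha1"]
                for area in cfg.areas:
                    stats = sd.mrr_stats.get(area)
                    if stats is None or stats.total_birds() == 0:
                        continue
                    prep = prepare_mrr_stats(stats)
                    p_deps = [f"pw_{area}_{cls}" for cls in RESIGHT_CLASSES]

                    def mrr_fn(state, area=area, prep=prep):
                        return mrr_loglik_prepared(prep, self.mrr_tables(state, area))

                    self._add_component(
                        f"MRR_{area}", mrr_fn, phi_deps_M + shared + p_deps
                    )

    def _pad1_rate(self, rate_1based):
        """1-based rate series of length L+1 -> length T+1 (zero pad tail)."""
        T = self.config.T
        if len(rate_1based) == T + 1:
            return rate_1based
        out = np.zeros(T + 1)
        out[1 : len(rate_1based)] = rate_1based[1:]
        return out

    # ------------------------------------------------------------------
    def prior_for(self, name: str):
        return self.priors.for_param(name, self.blocks[name].group)

    def component_values(self, state) -> dict[str, float]:
        return {c.name: float(c.fn(state)) for c in self.components}

    def prior_logpdf(self, state) -> float:
        total = 0.0
        for name, block in self.blocks.items():
            pr = self.prior_for(name)
            if not pr.proper:
                continue
            for v in state[name]:
                total += pr.logpdf(float(v))
                if total == -np.inf:
                    return total
        return total

    def logpost(self, state) -> float:
        total = self.prior_logpdf(state)
        if total == -np.inf:
            return total
        for c in self.components:
            total += c.fn(state)
            if total == -np.inf:
                return total
        return float(total)

    # ------------------------------------------------------------------
    def init_state(self, rng: np.random.Generator, jitter: float = 1.0) -> ParameterState:
        """Crude data-informed starting point with chain-specific jitter:
        empirical proportions for binomial rates, interpolated counts for the
        latent abundances, prior-scale draws elsewhere."""
        cfg = self.config
        T = cfg.T
        state: ParameterState = {}
        j = jitter

        def jn(mu, sd):
            return mu + j * sd * rng.normal()

        state["delta_rho"] = 0.05 * j * rng.normal(size=T)
        state["delta_phi"] = 0.05 * j * rng.normal(size=T - 1)
        state["sigma_delta_rho"] = np.array([rng.uniform(0.15, 0.8)])
        state["sigma_delta_phi"] = np.array([rng.uniform(0.15, 0.8)])
        for sp in cfg.species:
            S = sp.code
            sd = self.bundle[S]
            Esum, Csum = sd.breeding.E[1:].sum(), sd.breeding.C[1:].sum()
            phat = (Csum + 1.0) / (Esum + 2.0) if Esum > 0 else 0.6
            state[f"beta_rho_{S}"] = np.array([jn(logit(np.clip(phat, 0.05, 0.95)), 0.3)])
            state[f"beta_phi_{S}"] = np.array([jn(logit(0.9), 0.3)])
            state[f"eps_rho_{S}"] = 0.05 * j * rng.normal(size=T)
            state[f"eps_phi_{S}"] = 0.05 * j * rng.normal(size=T - 1)
            state[f"sigma_eps_rho_{S}"] = np.array([rng.uniform(0.15, 0.8)])
            state[f"sigma_eps_phi_{S}"] = np.array([rng.uniform(0.15, 0.8)])
            state[f"lpstar_{S}"] = logit(0.6) + 0.3 * j * rng.normal(size=T - 1)
            state[f"a_{S}"] = np.array([jn(1.0, 0.3)])
            if not sp.murre_like:
                state[f"phi_c_{S}"] = np.array([rng.uniform(0.35, 0.75)])
            if self.has_latents[S]:
                self._init_latents(state, sp, rng)
        murre = cfg.mrr_species
        if murre is not None:
            nbd = self.bundle[murre.code].nonbreeding
            if nbd is not None and (nbd.xi_m[1:] > 0).any():
                bhat = (nbd.xi_b[1:].sum() + 1.0) / (nbd.xi_m[1:].sum() + 2.0)
            else:
                bhat = 0.9
            state["B"] = np.clip(bhat + 0.02 * j * rng.normal(size=T), 0.05, 0.99)
            state["s1"] = rng.uniform(0.3, 0.7, size=T - 1)
            state["s2"] = np.array([rng.uniform(0.55, 0.85)])
            state["s35"] = np.array([rng.uniform(0.75, 0.95)])
            state["F5"] = np.array([rng.uniform(0.7, 0.95)])
            state["F6"] = np.array([rng.uniform(0.7, 0.95)])
            state["psi"] = np.array([rng.uniform(0.7, 0.95)])
            state["alpha0"] = np.array([jn(-2.0, 0.5)])
            state["alpha1"] = np.array([jn(0.0, 0.3)])
            for area in cfg.areas:
                hi_p = 0.4 if area == "A" else 0.2
                for cls in RESIGHT_CLASSES:
                    n = self.blocks[f"pw_{area}_{cls}"].size
                    state[f"pw_{area}_{cls}"] = rng.uniform(0.05, hi_p, size=n)
        return state

    def _init_latents(self, state, sp, rng):
        cfg, T, d, S = self.config, self.config.T, sp.d, sp.code
        x = self.bundle[S].counts
        obs = x.observed_years()
        xfull = np.interp(np.arange(1, T + 1, dtype=float), obs, x.x[obs])
        xfull = np.maximum(np.round(xfull * np.exp(0.02 * rng.normal(size=T))), 1)
        N = np.concatenate([[0.0], xfull])
        R = np.zeros(T + 1)
        Su = np.zeros(T + 1)
        for t in range(d + 1, T + 1):
            Su[t] = min(N[t], N[t - 1], round(N[t] * rng.uniform(0.85, 0.95)))
            R[t] = N[t] - Su[t]
            if R[t] > N[t - d]:
                R[t] = N[t - d]
                Su[t] = min(N[t] - R[t], N[t - 1])
                N[t] = R[t] + Su[t]
        state[f"Ninit_{S}"] = N[1 : d + 1].copy()
        state[f"R_{S}"] = R[d + 1 :].copy()
        state[f"Ssur_{S}"] = Su[d + 1 :].copy()
        mean_x = float(np.nanmean(x.x[obs])) if obs.size else 100.0
        state[f"sigma_x_{S}"] = np.array(
            [max(2.0, 0.05 * mean_x) * np.exp(0.3 * rng.normal())]
        )

    def check_finite(self, state) -> None:
        """Raise with the offending component's name if the state is outside
        the posterior support."""
        lp = self.prior_logpdf(state)
        if not np.isfinite(lp):
            for name in self.blocks:
                pr = self.prior_for(name)
                if pr.proper and any(
                    not np.isfinite(pr.logpdf(float(v))) for v in state[name]
                ):
                    raise RuntimeError(f"initial state outside prior support: {name}")
        for c in self.components:
            if not np.isfinite(c.fn(state)):
                raise RuntimeError(f"initial state has -inf component: {c.name}")


def joint_logposterior(
    state: ParameterState,
    bundle: DatasetBundle,
    priors: PriorSpec | None = None,
    config: StudyConfig | None = None,
) -> float:
    """Joint log posterior density (up to the multinomial-coefficient
    constants of the MRR component) at ``state``."""
    return JointModel(bundle, priors, config).logpost(state)
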