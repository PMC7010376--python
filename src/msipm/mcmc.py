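"""MCMC fitting of the joint posterior, convergence diagnostics, summaries.

The sampler mixes adaptive Metropolis updates with exact Gibbs steps over
the blocks of a :class:`~msipm.model.JointModel`:

* continuous parameters take Gaussian random-walk proposals, per-site step
  sizes adapted during warmup toward acceptance 0.44; bounded parameters
  occasionally take an independence proposal from their proper prior (prior
  and proposal ratios cancel exactly);
* latent abundances take integer random-walk steps, plus block moves:
  whole-trajectory shifts, initialization-window shifts, and
  recruit/survivor exchanges at fixed N(t);
* the synchrony layer is resampled by exact Gibbs along its
  likelihood-flat directions (delta/eps exchange at fixed per-species sums,
  intercept recentering with truncated-normal conditionals) and the
  random-effect and observation SDs are drawn from their exact
  truncated-gamma conditionals (normal likelihoods, uniform SD priors);
* amplitude moves rescale each (SD, effect-vector) pair jointly, and a
  reversible joint move walks the (phi_c, initialization level) ridge of
  the combined-juvenile-survival species.

Only the components that depend on the touched block are re-evaluated, so a
full sweep costs a few dozen likelihood evaluations rather than thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .data import DatasetBundle
from .model import JointModel
from .priors import PriorSpec
from .synchrony import synchrony_index

__all__ = ["PosteriorResult", "run_mcmc", "gelman_rubin", "summarize_posterior"]


# ----------------------------------------------------------------------
@dataclass
class PosteriorResult:
    """Posterior draws with named blocks, plus enough metadata to summarize."""

    draws: dict[str, np.ndarray]  # name -> (n_chains, n_kept, block_size)
    labels: dict[str, list[int]]
    groups: dict[str, str]
    config: StudyConfig
    latent_species: list[str]
    seed: int
    n_iter: int
    warmup: int
    thin: int
    logpost: np.ndarray  # (n_chains, n_kept)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.logpost.shape[0]

    # -- scalar access ---------------------------------------------------
    def scalar_names(self) -> list[str]:
        out = []
        for name, arr in self.draws.items():
            if arr.shape[2] == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{lab}]" for lab in self.labels[name])
        return out

    def scalar_draws(self, label: str) -> np.ndarray:
        """(n_chains, n_kept) draws for one scalar parameter label."""
        if "[" in label:
            name, idx = label[:-1].split("[")
            col = self.labels[name].index(int(idx))
        else:
            name, col = label, 0
        return self.draws[name][:, :, col]

    # -- derived quantities ----------------------------------------------
    def derived_draws(self) -> dict[str, np.ndarray]:
        """Per-draw deterministic quantities: synchrony indices and the
        adult-abundance trajectories."""
        out: dict[str, np.ndarray] = {}
        for kind in ("phi", "rho"):
            sd = self.draws.get(f"sigma_delta_{kind}")
            if sd is None:
                continue
            for sp in self.config.species:
                S = sp.code
                se = self.draws.get(f"sigma_eps_{kind}_{S}")
                if se is not None:
                    out[f"I_{kind}_{S}"] = synchrony_index(sd[:, :, 0], se[:, :, 0])
        for S in self.latent_species:
            d = self.config.species_by_code(S).d
            Ninit = self.draws[f"Ninit_{S}"]
            Ntail = self.draws[f"R_{S}"] + self.draws[f"Ssur_{S}"]
            for t in range(1, self.config.T + 1):
                col = Ninit[:, :, t - 1] if t <= d else Ntail[:, :, t - d - 1]
                out[f"N_{S}[{t}]"] = col
        return out

    def rhat(self, label: str) -> float:
        return gelman_rubin(self.scalar_draws(label))

    def worst_rhat(self) -> tuple[str, float]:
        worst = ("", -np.inf)
        for name in self.scalar_names():
            r = self.rhat(name)
            if np.isfinite(r) and r > worst[1]:
                worst = (name, r)
        return worst


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from >=2 chains of equal length
    (array (n_chains, n_draws)).  Constant identical chains give 1.0."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    n = x.shape[1]
    if n < 2:
        raise ValueError("chains too short")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


# ----------------------------------------------------------------------
def _run_chain(model: JointModel, rng, n_iter, warmup, thin, indep_prob):
    # initialization: crude estimates + jitter, retried until in support
    state = None
    err: Optional[Exception] = None
    for _ in range(30):
        cand = model.init_state(rng)
        try:
            model.check_finite(cand)
        except RuntimeError as e:
            err = e
            continue
        state = cand
        break
    if state is None:
        raise RuntimeError(f"failed to initialize chain: {err}")

    comp_fns = [c.fn for c in model.components]
    comp_vals = np.array([fn(state) for fn in comp_fns])
    blocks = list(model.blocks.values())

    # site table; resight-window blocks move as one vector proposal
    sites = []
    for b in blocks:
        pr = model.prior_for(b.name)
        if b.name.startswith("pw_") and b.size > 1:
            sites.append((b.name, None, pr, b.comp_ids, False))
        else:
            for i in range(b.size):
                sites.append((b.name, i, pr, b.comp_ids, b.integer))
    scales = np.empty(len(sites))
    targets = np.empty(len(sites))
    for k, (name, i, pr, _, integer) in enumerate(sites):
        targets[k] = 0.25 if i is None else 0.44
        if i is None:
            scales[k] = 0.1
        elif integer:
            scales[k] = max(2.0, 0.05 * abs(float(state[name][i])))
        elif model.blocks[name].group in ("sigma_x",):
            scales[k] = max(1.0, 0.2 * abs(float(state[name][i])))
        else:
            scales[k] = 0.3
    log_scales = np.log(scales)

    prior_total = model.prior_logpdf(state)
    n_accept = np.zeros(len(sites))
    n_prop = np.zeros(len(sites))

    # Exact Gibbs updates along the likelihood-flat directions of the
    # synchrony layer.  The likelihood depends on the effects only through
    # the per-species sums beta_S + delta(t) + eps_S(t); conditional on those
    # sums and the SDs, the decomposition is Gaussian and can be resampled in
    # closed form (intercept priors are uniform, so only truncation at their
    # bounds enters).
    codes = [S.code for S in model.config.species]
    comp_idx = {c.name: i for i, c in enumerate(model.components)}

    def _update_comps(cids):
        for cid in cids:
            comp_vals[cid] = comp_fns[cid](state)

    def _trunc_normal(mu, sd, lo, hi):
        for _ in range(100):
            x = mu + sd * rng.normal()
            if lo <= x <= hi:
                return x
        return min(max(mu, lo), hi)

    def _sample_sd(ss, n, hi):
        """Exact draw of sigma from p(sigma) ~ sigma^-n exp(-ss/(2 sigma^2))
        on (0, hi): with v = sigma^-2, v ~ Gamma((n-1)/2, rate=ss/2)
        truncated to v >= hi^-2, sampled by inverse CDF."""
        from scipy.stats import gamma as gamma_dist

        if ss <= 0.0 or n < 2:
            return None
        shape, scale = (n - 1) / 2.0, 2.0 / ss
        lo_v = hi**-2
        Flo = gamma_dist.cdf(lo_v, shape, scale=scale)
        if Flo >= 1.0 - 1e-14:
            return None  # essentially no mass inside the prior bound
        u = Flo + rng.random() * (1.0 - Flo)
        v = gamma_dist.ppf(u, shape, scale=scale)
        if not np.isfinite(v) or v <= 0:
            return None
        return float(1.0 / np.sqrt(v))

    def gibbs_synchrony(kind):
        sd_d = float(state[f"sigma_delta_{kind}"][0])
        sds_e = {S: float(state[f"sigma_eps_{kind}_{S}"][0]) for S in codes}
        cids = [comp_idx[f"RE_delta_{kind}"]] + [
            comp_idx[f"RE_eps_{kind}_{S}"] for S in codes
        ]
        if sd_d > 0 and all(v > 0 for v in sds_e.values()):
            # per-year delta/eps exchange at fixed sums
            delta = state[f"delta_{kind}"]
            eta = {S: delta + state[f"eps_{kind}_{S}"] for S in codes}
            prec = 1.0 / sd_d**2 + sum(1.0 / sds_e[S] ** 2 for S in codes)
            mean = sum(eta[S] / sds_e[S] ** 2 for S in codes) / prec
            new_delta = mean + rng.normal(size=delta.size) / np.sqrt(prec)
            state[f"delta_{kind}"] = new_delta
            for S in codes:
                state[f"eps_{kind}_{S}"] = eta[S] - new_delta
        # beta_S vs eps_S mean, at fixed sums (uniform prior -> truncation)
        for S in codes:
            sd_e = sds_e[S]
            if sd_e <= 0:
                continue
            pr = model.prior_for(f"beta_{kind}_{S}")
            beta = float(state[f"beta_{kind}_{S}"][0])
            zeta = beta + state[f"eps_{kind}_{S}"]
            n = zeta.size
            new_beta = _trunc_normal(zeta.mean(), sd_e / np.sqrt(n), pr.lo, pr.hi)
            state[f"beta_{kind}_{S}"][0] = new_beta
            state[f"eps_{kind}_{S}"] = zeta - new_beta
        # common shift between all intercepts and delta
        if sd_d > 0:
            delta = state[f"delta_{kind}"]
            lo = max(
                model.prior_for(f"beta_{kind}_{S}").lo - float(state[f"beta_{kind}_{S}"][0])
                for S in codes
            )
            hi = min(
                model.prior_for(f"beta_{kind}_{S}").hi - float(state[f"beta_{kind}_{S}"][0])
                for S in codes
            )
            c = _trunc_normal(delta.mean(), sd_d / np.sqrt(delta.size), lo, hi)
            for S in codes:
                state[f"beta_{kind}_{S}"][0] += c
            state[f"delta_{kind}"] = delta - c
        # exact conditional draws of the random-effect SDs
        pairs = [(f"delta_{kind}", f"sigma_delta_{kind}")] + [
            (f"eps_{kind}_{S}", f"sigma_eps_{kind}_{S}") for S in codes
        ]
        for vec_name, sd_name in pairs:
            vec = state[vec_name]
            pr = model.prior_for(sd_name)
            new_sd = _sample_sd(float(vec @ vec), vec.size, pr.hi)
            if new_sd is not None:
                state[sd_name][0] = new_sd
        _update_comps(cids)

    from .population import init_means_from_counts

    _sigma_x_data = {}
    for S, has in model.has_latents.items():
        if has:
            sp = model.config.species_by_code(S)
            sd = model.bundle[S]
            tobs = sd.counts.observed_years()
            tobs = tobs[tobs > sp.d]
            _sigma_x_data[S] = (
                tobs,
                sd.counts.x[tobs],
                init_means_from_counts(sd.counts, sp.d)[1:],
            )

    def gibbs_sigma_x():
        """Exact conditional draws of the count-observation SDs (shared by
        the observation likelihood and the initialization priors)."""
        for S, (tobs, xobs, init_means) in _sigma_x_data.items():
            lat_N = np.concatenate(
                [state[f"Ninit_{S}"], state[f"R_{S}"] + state[f"Ssur_{S}"]]
            )
            resid = [state[f"Ninit_{S}"] - init_means]
            if tobs.size:
                resid.append(xobs - lat_N[tobs - 1])
            resid = np.concatenate(resid)
            pr = model.prior_for(f"sigma_x_{S}")
            new_sd = _sample_sd(float(resid @ resid), resid.size, pr.hi)
            if new_sd is not None:
                state[f"sigma_x_{S}"][0] = new_sd
                _update_comps(
                    [comp_idx[f"OBS_{S}"], comp_idx[f"INIT_{S}"]]
                )
    shift_moves = []
    swap_moves = []  # R(t) <-> S(t) exchanges leave N(t) and the counts fixed
    for S, has in model.has_latents.items():
        if has:
            cids = [
                i
                for i, c in enumerate(model.components)
                if c.name in (f"SYS_{S}", f"OBS_{S}", f"INIT_{S}")
            ]
            shift_moves.append((S, cids))
            init_cids = [
                i
                for i, c in enumerate(model.components)
                if c.name in (f"SYS_{S}", f"INIT_{S}")
            ]
            shift_moves.append((S + "#init", init_cids))
            sys_cid = [
                i for i, c in enumerate(model.components) if c.name == f"SYS_{S}"
            ]
            for idx in range(state[f"R_{S}"].size):
                swap_moves.append((S, idx, sys_cid))
    # amplitude ("scale") moves: (sigma, effects) -> (u*sigma, u*effects),
    # the slow direction of the hierarchical random-effect funnels
    scale_moves = []
    for kind in ("rho", "phi"):
        vecs = [("delta_" + kind, "sigma_delta_" + kind)] + [
            (f"eps_{kind}_{S.code}", f"sigma_eps_{kind}_{S.code}")
            for S in model.config.species
        ]
        for vec_name, sd_name in vecs:
            cids = sorted(
                set(model.blocks[vec_name].comp_ids) | set(model.blocks[sd_name].comp_ids)
            )
            scale_moves.append((vec_name, sd_name, cids))
    scale_scales = np.full(len(scale_moves), 0.2)

    # joint (phi_c, initialization level) ridge moves for the species whose
    # combined juvenile survival is only anchored through the counts
    ridge_moves = []
    for sp in model.config.species:
        S = sp.code
        if not sp.murre_like and model.has_latents.get(S) and f"phi_c_{S}" in model.blocks:
            cids = [
                i
                for i, c in enumerate(model.components)
                if c.name in (f"SYS_{S}", f"INIT_{S}")
            ]
            ridge_moves.append((S, cids))
    ridge_scales = np.full(len(ridge_moves), 0.1)

    shift_scales = np.array(
        [
            max(2.0, 0.02 * float(state[f"Ninit_{S.split('#')[0]}"][0]))
            for S, _ in shift_moves
        ]
    )
    swap_scales = np.array(
        [max(2.0, 0.05 * float(state[f"R_{S}"][idx])) for S, idx, _ in swap_moves]
    )
    # "hump" moves: raise N(t) over a segment [t1, t2) at fixed endpoints by
    # adding k recruits at t1 and converting k recruits to survivors at t2;
    # lets the trajectory flex between sparse counts
    hump_moves = []
    for S, has in model.has_latents.items():
        if has and state[f"R_{S}"].size >= 2:
            cids = [
                i
                for i, c in enumerate(model.components)
                if c.name in (f"SYS_{S}", f"OBS_{S}")
            ]
            hump_moves.append((S, state[f"R_{S}"].size, cids))
    hump_scales = np.array(
        [max(2.0, 0.03 * float(state[f"R_{S}"].mean())) for S, _, _ in hump_moves]
    )

    kept = max(0, (n_iter - warmup)) // max(thin, 1)
    store = {b.name: np.empty((kept, b.size)) for b in blocks}
    lp_store = np.empty(kept)
    k_out = 0

    exp, log_ = np.exp, np.log
    for it in range(n_iter):
        adapt = it < warmup
        gamma = 2.0 / (it + 10.0) ** 0.6
        for k, (name, i, pr, comp_ids, integer) in enumerate(sites):
            if i is None:  # vector random-walk over a whole window block
                old = state[name].copy()
                xp_vec = old + scales[k] * rng.normal(size=old.size)
                dprior = 0.0
                for ov, nv_ in zip(old, xp_vec):
                    lp_new = pr.logpdf(float(nv_))
                    if lp_new == -np.inf:
                        dprior = -np.inf
                        break
                    dprior += lp_new - pr.logpdf(float(ov))
                n_prop[k] += 1
                if dprior == -np.inf:
                    if adapt:
                        log_scales[k] -= gamma * targets[k]
                        scales[k] = exp(log_scales[k])
                    continue
                state[name] = xp_vec
                dcomp = dprior
                new_vals = []
                ok = True
                for cid in comp_ids:
                    nv = comp_fns[cid](state)
                    new_vals.append(nv)
                    dcomp += nv - comp_vals[cid]
                    if nv == -np.inf:
                        ok = False
                        break
                loga = dcomp if ok else -np.inf
                if loga >= 0.0 or (loga > -np.inf and rng.random() < exp(loga)):
                    for cid, nv in zip(comp_ids, new_vals):
                        comp_vals[cid] = nv
                    prior_total += dprior
                    n_accept[k] += 1
                else:
                    state[name] = old
                if adapt:
                    alpha = min(1.0, exp(loga)) if loga < 0 else 1.0
                    log_scales[k] += gamma * (alpha - targets[k])
                    scales[k] = exp(log_scales[k])
                continue
            x = float(state[name][i])
            indep = (not integer) and pr.proper and rng.random() < indep_prob
            if indep:
                xp = pr.sample(rng)
                dprior = 0.0
            elif integer:
                step = int(round(rng.normal(0.0, scales[k])))
                if step == 0:
                    step = 1 if rng.random() < 0.5 else -1
                xp = x + step
                dprior = 0.0
            else:
                xp = x + scales[k] * rng.normal()
                lp_new = pr.logpdf(xp)
                if lp_new == -np.inf:
                    n_prop[k] += 1
                    if adapt:
                        log_scales[k] -= gamma * 0.44
                        scales[k] = exp(log_scales[k])
                    continue
                dprior = lp_new - pr.logpdf(x)
            state[name][i] = xp
            dcomp = dprior
            new_vals = []
            ok = True
            for cid in comp_ids:
                nv = comp_fns[cid](state)
                new_vals.append(nv)
                dcomp += nv - comp_vals[cid]
                if nv == -np.inf:
                    ok = False
                    break
            loga = dcomp if ok else -np.inf
            n_prop[k] += 1
            if loga >= 0.0 or (loga > -np.inf and rng.random() < exp(loga)):
                for cid, nv in zip(comp_ids, new_vals):
                    comp_vals[cid] = nv
                prior_total += dprior
                n_accept[k] += 1
            else:
                state[name][i] = x
            if adapt and not indep:
                alpha = min(1.0, exp(loga)) if loga < 0 else 1.0
                log_scales[k] += gamma * (alpha - 0.44)
                scales[k] = exp(log_scales[k])
                if integer:
                    scales[k] = max(scales[k], 0.5)

        # exact conditional resampling of the synchrony decomposition; the
        # prior total changes with the intercepts (uniform, so only by 0 or
        # truncation never leaves support) -> recompute their contribution
        for kind in ("rho", "phi"):
            gibbs_synchrony(kind)
        gibbs_sigma_x()

        # block integer shifts of the latent populations: the whole
        # trajectory (Ninit and survivors together), or the initialization
        # window alone (the direction confounded with juvenile survival)
        for mk, (tag, cids) in enumerate(shift_moves):
            S, init_only = (tag.split("#")[0], "#" in tag)
            step = int(round(rng.normal(0.0, shift_scales[mk])))
            if step == 0:
                step = 1 if rng.random() < 0.5 else -1
            state[f"Ninit_{S}"] += step
            if not init_only:
                state[f"Ssur_{S}"] += step
            new_vals = [comp_fns[cid](state) for cid in cids]
            loga = sum(new_vals) - sum(comp_vals[cid] for cid in cids)
            if np.isfinite(loga) and (loga >= 0.0 or rng.random() < exp(min(loga, 0.0))):
                for cid, nv in zip(cids, new_vals):
                    comp_vals[cid] = nv
                alpha = 1.0 if loga >= 0 else exp(loga)
            else:
                state[f"Ninit_{S}"] -= step
                if not init_only:
                    state[f"Ssur_{S}"] -= step
                alpha = exp(min(loga, 0.0)) if np.isfinite(loga) else 0.0
            if adapt:
                shift_scales[mk] = max(1.0, shift_scales[mk] * exp(gamma * (alpha - 0.44)))

        # amplitude scaling of each random-effect block with its SD
        for mk, (vec_name, sd_name, cids) in enumerate(scale_moves):
            z = scale_scales[mk] * rng.normal()
            u = exp(z)
            pr_sd = model.prior_for(sd_name)
            old_sd = float(state[sd_name][0])
            lp_new = pr_sd.logpdf(old_sd * u)
            if lp_new == -np.inf:
                alpha = 0.0
            else:
                dprior = lp_new - pr_sd.logpdf(old_sd)
                old_vec = state[vec_name].copy()
                state[sd_name][0] = old_sd * u
                state[vec_name] = old_vec * u
                new_vals = [comp_fns[cid](state) for cid in cids]
                n_el = old_vec.size + 1
                loga = (
                    dprior
                    + sum(new_vals)
                    - sum(comp_vals[cid] for cid in cids)
                    + n_el * z  # Jacobian of the scaling map
                )
                if np.isfinite(loga) and (
                    loga >= 0.0 or rng.random() < exp(min(loga, 0.0))
                ):
                    for cid, nv in zip(cids, new_vals):
                        comp_vals[cid] = nv
                    prior_total += dprior
                    alpha = 1.0 if loga >= 0 else exp(loga)
                else:
                    state[sd_name][0] = old_sd
                    state[vec_name] = old_vec
                    alpha = exp(min(loga, 0.0)) if np.isfinite(loga) else 0.0
            if adapt:
                scale_scales[mk] *= exp(gamma * (alpha - 0.44))

        # joint phi_c / initialization-level ridge moves
        for mk, (S, cids) in enumerate(ridge_moves):
            z = ridge_scales[mk] * rng.normal()
            u = exp(z)
            name_pc = f"phi_c_{S}"
            pr_pc = model.prior_for(name_pc)
            old_pc = float(state[name_pc][0])
            new_pc = old_pc * u
            lp_new = pr_pc.logpdf(new_pc)
            if lp_new == -np.inf:
                alpha = 0.0
            else:
                old_init = state[f"Ninit_{S}"].copy()
                # compensating integer proposal around Ninit/u, unit window
                mu = old_init / u
                new_init = np.round(mu) + rng.integers(-1, 2, size=old_init.size)
                # reversibility: the return move must be able to propose old_init
                mu_rev = new_init * u
                if np.max(np.abs(old_init - np.round(mu_rev))) > 1:
                    alpha = 0.0
                else:
                    dprior = lp_new - pr_pc.logpdf(old_pc)
                    state[name_pc][0] = new_pc
                    state[f"Ninit_{S}"] = new_init.astype(float)
                    new_vals = [comp_fns[cid](state) for cid in cids]
                    loga = (
                        dprior
                        + sum(new_vals)
                        - sum(comp_vals[cid] for cid in cids)
                        + z  # Jacobian of the log-scale walk on phi_c
                    )
                    if np.isfinite(loga) and (
                        loga >= 0.0 or rng.random() < exp(min(loga, 0.0))
                    ):
                        for cid, nv in zip(cids, new_vals):
                            comp_vals[cid] = nv
                        prior_total += dprior
                        alpha = 1.0 if loga >= 0 else exp(loga)
                    else:
                        state[name_pc][0] = old_pc
                        state[f"Ninit_{S}"] = old_init
                        alpha = exp(min(loga, 0.0)) if np.isfinite(loga) else 0.0
            if adapt:
                ridge_scales[mk] *= exp(gamma * (alpha - 0.234))

        # recruit/survivor exchanges at fixed N(t)
        for mk, (S, idx, cids) in enumerate(swap_moves):
            step = int(round(rng.normal(0.0, swap_scales[mk])))
            if step == 0:
                step = 1 if rng.random() < 0.5 else -1
            state[f"R_{S}"][idx] += step
            state[f"Ssur_{S}"][idx] -= step
            new_vals = [comp_fns[cid](state) for cid in cids]
            loga = sum(new_vals) - sum(comp_vals[cid] for cid in cids)
            if np.isfinite(loga) and (loga >= 0.0 or rng.random() < exp(min(loga, 0.0))):
                for cid, nv in zip(cids, new_vals):
                    comp_vals[cid] = nv
                alpha = 1.0 if loga >= 0 else exp(loga)
            else:
                state[f"R_{S}"][idx] -= step
                state[f"Ssur_{S}"][idx] += step
                alpha = exp(min(loga, 0.0)) if np.isfinite(loga) else 0.0
            if adapt:
                swap_scales[mk] = max(1.0, swap_scales[mk] * exp(gamma * (alpha - 0.44)))

        # latent segment ("hump") moves
        for mk, (S, n_lat, cids) in enumerate(hump_moves):
            for _ in range(n_lat):
                i1 = int(rng.integers(0, n_lat - 1))
                i2 = int(rng.integers(i1 + 1, n_lat))
                step = int(round(rng.normal(0.0, hump_scales[mk])))
                if step == 0:
                    step = 1 if rng.random() < 0.5 else -1
                R = state[f"R_{S}"]
                Su = state[f"Ssur_{S}"]
                R[i1] += step
                Su[i1 + 1 : i2] += step  # N(t) rises on [i1, i2), fixed after
                new_vals = [comp_fns[cid](state) for cid in cids]
                loga = sum(new_vals) - sum(comp_vals[cid] for cid in cids)
                if np.isfinite(loga) and (
                    loga >= 0.0 or rng.random() < exp(min(loga, 0.0))
                ):
                    for cid, nv in zip(cids, new_vals):
                        comp_vals[cid] = nv
                    alpha = 1.0 if loga >= 0 else exp(loga)
                else:
                    R[i1] -= step
                    Su[i1 + 1 : i2] -= step
                    alpha = exp(min(loga, 0.0)) if np.isfinite(loga) else 0.0
                if adapt:
                    hump_scales[mk] = max(
                        1.0, hump_scales[mk] * exp(gamma * (alpha - 0.3))
                    )

        if it >= warmup and (it - warmup) % thin == 0 and k_out < kept:
            for name in store:
                store[name][k_out] = state[name]
            lp_store[k_out] = prior_total + comp_vals.sum()
            k_out += 1

    acc = {}
    for k, (name, *_rest) in enumerate(sites):
        acc.setdefault(name, []).append(
            n_accept[k] / n_prop[k] if n_prop[k] else np.nan
        )
    acc = {name: float(np.mean(v)) for name, v in acc.items()}
    return store, lp_store[:k_out], acc


def run_mcmc(
    bundle: DatasetBundle,
    priors: PriorSpec | None = None,
    config: StudyConfig | None = None,
    n_chains: int = 2,
    n_iter: int = 4000,
    seed: int = 0,
    warmup: int | None = None,
    thin: int = 1,
    indep_prob: float = 0.05,
) -> PosteriorResult:
    """Fit the joint model by MCMC.

    ``n_iter`` counts total sweeps per chain; the first ``warmup`` (default
    half) adapt the proposal scales and are discarded; the rest are kept
    every ``thin`` sweeps.  Runs are reproducible given ``seed``.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    model = JointModel(bundle, priors, config)
    if warmup is None:
        warmup = n_iter // 2
    stores, lps, accs = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng([int(seed), c])
        store, lp, acc = _run_chain(model, rng, n_iter, warmup, thin, indep_prob)
        stores.append(store)
        lps.append(lp)
        accs.append(acc)
    draws = {
        name: np.stack([s[name] for s in stores]) for name in stores[0]
    }
    acceptance = {
        name: float(np.mean([a[name] for a in accs])) for name in accs[0]
    }
    return PosteriorResult(
        draws=draws,
        labels={b.name: b.labels for b in model.blocks.values()},
        groups={b.name: b.group for b in model.blocks.values()},
        config=model.config,
        latent_species=[S for S, has in model.has_latents.items() if has],
        seed=int(seed),
        n_iter=n_iter,
        warmup=warmup,
        thin=thin,
        logpost=np.stack(lps),
        acceptance=acceptance,
    )


def summarize_posterior(result: PosteriorResult) -> pd.DataFrame:
    """Median and symmetric 95% credible interval (linear-interpolation
    quantiles) for every parameter and derived quantity, with R-hat.

    Synchrony indices are summarized draw-wise (the primary quantity); the
    plug-in index of the posterior-median SDs is emitted alongside for
    comparison (rows suffixed ``_plugin``, no interval)."""
    rows = []

    def add(name, chains):
        flat = chains.reshape(-1)
        med, lo, hi = np.quantile(flat, [0.5, 0.025, 0.975])
        rh = gelman_rubin(chains) if chains.shape[0] >= 2 else np.nan
        rows.append((name, med, lo, hi, rh))

    for name in result.scalar_names():
        add(name, result.scalar_draws(name))
    derived = result.derived_draws()
    for name, chains in derived.items():
        add(name, chains)
    for kind in ("phi", "rho"):
        sd_name = f"sigma_delta_{kind}"
        if sd_name in result.draws:
            sd_med = np.median(result.draws[sd_name][:, :, 0])
            for sp in result.config.species:
                se = result.draws.get(f"sigma_eps_{kind}_{sp.code}")
                if se is not None:
                    plug = synchrony_index(sd_med, np.median(se[:, :, 0]))
                    rows.append((f"I_{kind}_{sp.code}_plugin", plug, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["parameter", "median", "q2.5", "q97.5", "rhat"]
    ).set_index("parameter")
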