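"""Synthetic-community generator: the exact generative dual of the fitted model.

Every stage of the package is testable without field data by simulating a
complete community dataset whose statistical structure matches the model:
logit-scale shared + species year effects on productivity and adult survival,
binomial breeding success / non-breeding monitoring, binomial population
dynamics observed with normal count error (counts rounded and floored at 0),
adult mark-resight histories with one-year trap dependence, and murre chick
MRR histories with age-structured survival, absorbing pre-recruitment
emigration (F5, F6), band loss / invisible recruitment after recruitment age
(1 - psi per year), area-specific age-class resighting (none in the first two
bookkeeping ages) and a logit-linear declining dead-recovery reporting rate.

The default scenario is a desk-scale version of the 26-year three-species
study: T = 15 occasions and roughly one quarter of the field sample sizes,
with intercepts and structural parameters at field-realistic values and the
synchrony variance components set at sigma_delta = 0.4, sigma_eps = 0.2
(synchrony index I = 0.8 for every species and both rates).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import StudyConfig, resight_class_of_age
from .data import (
    AdultEncounterHistory,
    BreedingSuccessSeries,
    ChickEncounterRecord,
    CountSeries,
    DatasetBundle,
    NonBreedingSeries,
    SpeciesData,
    build_mrr_sufficient_stats,
)
from .likelihoods.mrr import standardized_years
from .population import LatentPopulation
from .util import expit, logit

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "default_scenario",
    "full_scale_scenario",
    "simulate_latents",
    "simulate_observations",
    "simulate_marked_individuals",
    "simulate_bundle",
    "empty_bundle",
    "monitored_parameters",
]


@dataclass
class ScenarioConfig:
    """Generating parameter values and monitoring/marking effort."""

    study: StudyConfig
    beta_rho: dict[str, float]
    beta_phi: dict[str, float]
    pstar: dict[str, float]
    trap_a: dict[str, float]
    phi_c: dict[str, float]
    sigma_x: dict[str, float]
    N0: dict[str, float]
    E: dict[str, int]
    adults_marked: dict[str, int]
    sigma_delta_rho: float = 0.4
    sigma_delta_phi: float = 0.4
    sigma_eps_rho: dict[str, float] = field(default_factory=dict)
    sigma_eps_phi: dict[str, float] = field(default_factory=dict)
    init_growth: float = 0.02
    # murre-like extras
    xi_m: int = 0
    B_mean: float = 0.92
    B_sd_logit: float = 0.4
    s1_mean_logit: float = 0.0
    s1_sd_logit: float = 1.2
    s2: float = 0.763
    s35: float = 0.898
    F5: float = 0.865
    F6: float = 0.834
    psi: float = 0.850
    alpha0: float = -3.084
    alpha1: float = -0.687
    chick_p: dict[str, dict[str, float]] = field(default_factory=dict)
    chicks_banded: dict[str, int] = field(default_factory=dict)

    def sigma_eps(self, kind: str, S: str) -> float:
        d = self.sigma_eps_rho if kind == "rho" else self.sigma_eps_phi
        return d.get(S, 0.2)


def default_scenario(T: int = 15) -> ScenarioConfig:
    """Desk-scale default: quarter-scale efforts, field-realistic rates,
    synchrony generated at I = 0.8."""
    study = StudyConfig.reduced(T)
    return ScenarioConfig(
        study=study,
        beta_rho={"R": 0.689, "P": 0.890, "M": 1.002},
        beta_phi={"R": 2.319, "P": 2.436, "M": 2.789},
        pstar={"R": 0.75, "P": 0.75, "M": 0.75},
        trap_a={"R": 1.826, "P": 1.928, "M": 3.240},
        phi_c={"R": 0.501, "P": 0.761},
        sigma_x={"R": 90.0, "P": 1388.0, "M": 376.0},
        N0={"R": 375.0, "P": 2850.0, "M": 3250.0},
        E={"R": 34, "P": 40, "M": 207},
        adults_marked={"R": 3, "P": 10, "M": 15},
        xi_m=78,
        chick_p={
            "A": {"p2": 0.25, "p3": 0.45, "p45": 0.60, "pa": 0.75},
            "B": {"p2": 0.10, "p3": 0.20, "p45": 0.30, "pa": 0.50},
        },
        chicks_banded={"A": 40, "B": 20},
    )


def full_scale_scenario() -> ScenarioConfig:
    """Field-scale shape: the 26-occasion design with full sample sizes."""
    sc = default_scenario()
    sc.study = StudyConfig.full_study()
    sc.sigma_x = {"R": 358.0, "P": 5551.0, "M": 1503.0}
    sc.N0 = {"R": 1500.0, "P": 11390.0, "M": 13000.0}
    sc.E = {"R": 135, "P": 159, "M": 828}
    sc.adults_marked = {"R": 6, "P": 22, "M": 32}
    sc.xi_m = 310
    sc.chicks_banded = {"A": 200, "B": 97}
    return sc


@dataclass
class TruthRecord:
    """The generating truth: a model-compatible parameter state, the expanded
    rate series, the latent populations, and per-individual fates."""

    params: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]
    latents: dict[str, LatentPopulation]
    fates: dict[str, list] = field(default_factory=dict)
    extinct: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {
            "params": {k: conv(v) for k, v in self.params.items()},
            "rates": {k: conv(v) for k, v in self.rates.items()},
            "latents": {
                S: {"N": lat.N.tolist(), "R": lat.R.tolist(), "S": lat.S.tolist(), "d": lat.d}
                for S, lat in self.latents.items()
            },
            "extinct": self.extinct,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ----------------------------------------------------------------------
def simulate_latents(scenario: ScenarioConfig, rng: np.random.Generator) -> TruthRecord:
    """Draw the year random effects, expand all rate series, and iterate the
    binomial system process forward from initial levels N0*(1+g)^(t-1)."""
    cfg = scenario.study
    T = cfg.T
    params: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}

    params["sigma_delta_rho"] = np.array([scenario.sigma_delta_rho])
    params["sigma_delta_phi"] = np.array([scenario.sigma_delta_phi])
    params["delta_rho"] = scenario.sigma_delta_rho * rng.normal(size=T)
    params["delta_phi"] = scenario.sigma_delta_phi * rng.normal(size=T - 1)
    for sp in cfg.species:
        S = sp.code
        params[f"beta_rho_{S}"] = np.array([scenario.beta_rho[S]])
        params[f"beta_phi_{S}"] = np.array([scenario.beta_phi[S]])
        se_r, se_p = scenario.sigma_eps("rho", S), scenario.sigma_eps("phi", S)
        params[f"sigma_eps_rho_{S}"] = np.array([se_r])
        params[f"sigma_eps_phi_{S}"] = np.array([se_p])
        params[f"eps_rho_{S}"] = se_r * rng.normal(size=T)
        params[f"eps_phi_{S}"] = se_p * rng.normal(size=T - 1)
        params[f"lpstar_{S}"] = np.full(T - 1, logit(scenario.pstar[S]))
        params[f"a_{S}"] = np.array([scenario.trap_a[S]])
        if not sp.murre_like:
            params[f"phi_c_{S}"] = np.array([scenario.phi_c[S]])
        params[f"sigma_x_{S}"] = np.array([scenario.sigma_x[S]])
        rho = np.full(T + 1, np.nan)
        rho[1:] = expit(
            scenario.beta_rho[S] + params["delta_rho"] + params[f"eps_rho_{S}"]
        )
        s_a = np.full(T + 1, np.nan)
        s_a[1:T] = expit(
            scenario.beta_phi[S] + params["delta_phi"] + params[f"eps_phi_{S}"]
        )
        rates[f"rho_{S}"] = rho
        rates[f"s_a_{S}"] = s_a

    murre = cfg.mrr_species
    if murre is not None:
        params["B"] = expit(logit(scenario.B_mean) + scenario.B_sd_logit * rng.normal(size=T))
        params["s1"] = expit(
            scenario.s1_mean_logit + scenario.s1_sd_logit * rng.normal(size=T - 1)
        )
        for nm in ("s2", "s35", "F5", "F6", "psi", "alpha0", "alpha1"):
            params[nm] = np.array([getattr(scenario, nm)])
        for area in cfg.areas:
            for cls, p in scenario.chick_p[area].items():
                lo, hi = cfg.window(area, cls)
                params[f"pw_{area}_{cls}"] = np.full(hi - lo + 1, p)
        rates["B"] = np.concatenate([[np.nan], params["B"]])
        rates["s1"] = np.concatenate([[np.nan], params["s1"], [np.nan]])
        y = standardized_years(T)
        lam = np.full(T + 1, np.nan)
        lam[1:T] = expit(scenario.alpha0 + scenario.alpha1 * y[1:T])
        rates["lambda"] = lam

    truth = TruthRecord(params=params, rates=rates, latents={})
    for sp in cfg.species:
        S, d = sp.code, sp.d
        rho, s_a = rates[f"rho_{S}"], rates[f"s_a_{S}"]
        if sp.murre_like:
            tau = (
                rates["B"] * rho * 0.5
                * np.concatenate([rates["s1"][:T], [np.nan]])
                * scenario.s2 * scenario.s35**3 * scenario.F5 * scenario.F6
            )
            tau = np.where(np.isnan(tau), 0.0, tau)
        else:
            tau = np.nan_to_num(rho) * scenario.phi_c[S] / 2.0
        N = np.zeros(T + 1)
        R = np.zeros(T + 1)
        Su = np.zeros(T + 1)
        g = scenario.init_growth
        N[1 : d + 1] = np.round(scenario.N0[S] * (1 + g) ** np.arange(d))
        for t in range(d + 1, T + 1):
            R[t] = rng.binomial(int(N[t - d]), tau[t - d] * s_a[t - 1])
            Su[t] = rng.binomial(int(N[t - 1]), s_a[t - 1])
            N[t] = R[t] + Su[t]
        lat = LatentPopulation(N, R, Su, d)
        truth.latents[S] = lat
        params[f"Ninit_{S}"] = N[1 : d + 1].copy()
        params[f"R_{S}"] = R[d + 1 :].copy()
        params[f"Ssur_{S}"] = Su[d + 1 :].copy()
        if (N[1:] == 0).any():
            truth.extinct.append(S)
            warnings.warn(f"species {S} went extinct in simulation")
    return truth


def simulate_observations(truth: TruthRecord, scenario: ScenarioConfig, rng):
    """Counts with rounded, floored normal error (masked to the configured
    count years), binomial breeding-success and non-breeding monitoring."""
    cfg = scenario.study
    T = cfg.T
    out: dict[str, dict] = {}
    for sp in cfg.species:
        S = sp.code
        N = truth.latents[S].N
        x = np.full(T, np.nan)
        years = sp.count_years or range(1, T + 1)
        for t in years:
            x[t - 1] = max(0.0, np.round(N[t] + scenario.sigma_x[S] * rng.normal()))
        E = np.full(T, scenario.E[S])
        C = rng.binomial(E, truth.rates[f"rho_{S}"][1:])
        out[S] = {
            "counts": CountSeries.from_values(x, T),
            "breeding": BreedingSuccessSeries.from_values(E, C, T),
        }
        if sp.murre_like and scenario.xi_m > 0:
            xim = np.full(T, scenario.xi_m)
            xib = rng.binomial(xim, truth.params["B"])
            out[S]["nonbreeding"] = NonBreedingSeries.from_values(xim, xib, T)
    return out


def simulate_marked_individuals(truth: TruthRecord, scenario: ScenarioConfig, rng):
    """Individual-level simulation of the adult mark-resight histories and
    (for the murre-like species) the chick MRR records."""
    cfg = scenario.study
    T = cfg.T
    adults: dict[str, list[AdultEncounterHistory]] = {}
    fates: dict[str, list] = {}
    for sp in cfg.species:
        S = sp.code
        s_a = truth.rates[f"s_a_{S}"]
        lp = logit(scenario.pstar[S])
        a_S = scenario.trap_a[S]
        hist = []
        fate = []
        k = 0
        for t0 in range(1, T):
            for _ in range(scenario.adults_marked[S]):
                k += 1
                resights = []
                seen_prev = True  # capture at marking counts as seen
                death = None
                for t in range(t0 + 1, T + 1):
                    if rng.random() >= s_a[t - 1]:
                        death = t
                        break
                    p = expit(lp + (a_S if seen_prev else 0.0))
                    det = rng.random() < p
                    if det:
                        resights.append(t)
                    seen_prev = det
                hist.append(
                    AdultEncounterHistory.from_resights(f"{S}{k:04d}", S, t0, resights, T)
                )
                fate.append({"id": f"{S}{k:04d}", "death": death})
        adults[S] = hist
        fates[f"adults_{S}"] = fate

    chick_records: list[ChickEncounterRecord] = []
    murre = cfg.mrr_species
    if murre is not None and scenario.chicks_banded:
        M = murre.code
        s_aM = truth.rates[f"s_a_{M}"]
        s1 = truth.rates["s1"]
        lam = truth.rates["lambda"]
        k = 0
        for area in cfg.areas:
            per_year = scenario.chicks_banded.get(area, 0)
            for t0 in range(1, cfg.last_banding_t(area) + 1):
                for _ in range(per_year):
                    k += 1
                    resights = []
                    recovery = None
                    state = 1
                    a, y = 1, t0
                    death = None
                    emig = None
                    while y <= T - 1:
                        if a == 1:
                            phi = s1[y]
                        elif a == 2:
                            phi = scenario.s2
                        elif a <= 5:
                            phi = scenario.s35
                        else:
                            phi = s_aM[y]
                        if rng.random() >= phi:
                            death = y
                            if rng.random() < lam[y]:
                                recovery = y + 1
                            break
                        if state == 1:
                            if a <= 4:
                                F = 1.0
                            elif a == 5:
                                F = scenario.F5
                            elif a == 6:
                                F = scenario.F6
                            else:
                                F = scenario.psi
                            if rng.random() >= F:
                                state = 0
                                emig = y + 1
                        a += 1
                        y += 1
                        if state == 1 and a >= 3 and y <= T:
                            cls = resight_class_of_age(a)
                            lo, hi = cfg.window(area, cls)
                            p = scenario.chick_p[area][cls] if lo <= y <= hi else 0.0
                            if rng.random() < p:
                                resights.append(y)
                    chick_records.append(
                        ChickEncounterRecord(f"C{k:05d}", area, t0, tuple(resights), recovery)
                    )
                    fates.setdefault("chicks", []).append(
                        {"id": f"C{k:05d}", "death": death, "state0": emig}
                    )
    truth.fates = fates
    return adults, chick_records


def simulate_bundle(scenario: ScenarioConfig, seed: int):
    """Generate a complete validated DatasetBundle plus its TruthRecord."""
    rng = np.random.default_rng(seed)
    truth = simulate_latents(scenario, rng)
    obs = simulate_observations(truth, scenario, rng)
    adults, chicks = simulate_marked_individuals(truth, scenario, rng)
    cfg = scenario.study
    species = {}
    for sp in cfg.species:
        S = sp.code
        sd = SpeciesData(
            counts=obs[S]["counts"],
            breeding=obs[S]["breeding"],
            adults=adults[S],
            nonbreeding=obs[S].get("nonbreeding"),
        )
        if sp.murre_like:
            sd.chick_records = [r for r in chicks]
            sd.mrr_stats = build_mrr_sufficient_stats(sd.chick_records, cfg)
        species[S] = sd
    bundle = DatasetBundle(cfg, species)
    bundle.validate()
    return bundle, truth


def empty_bundle(config: StudyConfig) -> DatasetBundle:
    """A bundle with every dataset empty (no counts, no monitored pairs, no
    marked birds).  Fitting it samples the joint prior: the posterior of every
    top-level parameter reduces to its prior, which is how the prior-recovery
    check exercises the sampler."""
    T = config.T
    species = {
        sp.code: SpeciesData(
            counts=CountSeries.from_values(np.full(T, np.nan), T),
            breeding=BreedingSuccessSeries.from_values(np.zeros(T, int), np.zeros(T, int), T),
        )
        for sp in config.species
    }
    bundle = DatasetBundle(config, species)
    bundle.validate()
    return bundle


def monitored_parameters(truth: TruthRecord, config: StudyConfig) -> dict[str, float]:
    """The constant parameters monitored in recovery studies: species
    intercepts, random-effect SDs, the constant immature survivals, combined
    juvenile survivals, band retention and the observation SDs."""
    out = {}
    for kind in ("rho", "phi"):
        out[f"sigma_delta_{kind}"] = float(truth.params[f"sigma_delta_{kind}"][0])
        for sp in config.species:
            S = sp.code
            out[f"beta_{kind}_{S}"] = float(truth.params[f"beta_{kind}_{S}"][0])
            out[f"sigma_eps_{kind}_{S}"] = float(truth.params[f"sigma_eps_{kind}_{S}"][0])
    for sp in config.species:
        S = sp.code
        if not sp.murre_like:
            out[f"phi_c_{S}"] = float(truth.params[f"phi_c_{S}"][0])
        out[f"sigma_x_{S}"] = float(truth.params[f"sigma_x_{S}"][0])
    if config.has_mrr_species:
        for nm in ("s2", "s35", "psi"):
            out[nm] = float(truth.params[nm][0])
    return out
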