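# msipm — multi-species integrated population modelling of a seabird breeding community

`msipm` fits a joint Bayesian population model for a community of three
sympatric alcids (razorbill, Atlantic puffin, common murre) monitored over
decades at a single colony: annual breeding-pair counts, breeding-success
monitoring, non-breeding (skipped-breeding) monitoring for the murre, adult
mark-resight histories, and a murre chick mark-resight-recovery (MRR) study
across two banding areas.  Each species contributes a single-species
integrated population model (IPM); the species are joined through shared
year random effects on productivity and adult survival, whose variance
components measure demographic **synchrony** across the community.

It is written for quantitative population ecologists who want a tested,
reusable implementation of this model class: all component likelihoods, the
joint posterior, an MCMC fitter with convergence diagnostics, and a
synthetic-data generator that is the exact generative dual of the model, so
the whole pipeline is verifiable by parameter recovery without any field
data.

## The model in brief

For species S, year t (logit scale):

    rho_S(t)  : productivity        logit rho_S(t) = beta_rho_S + delta_rho(t) + eps_rho_S(t)
    s_aS(t)   : adult survival      logit s_aS(t)  = beta_phi_S + delta_phi(t) + eps_phi_S(t)
    delta(t) ~ N(0, sigma_delta^2)      common to all species
    eps_S(t) ~ N(0, sigma_eps_S^2)      species-specific

with the synchrony index I_S = sigma_delta^2 / (sigma_delta^2 + sigma_eps_S^2)
computed per posterior draw.  Data enter through:

* binomial breeding success C(t) ~ bin(E(t), rho_S(t)) and murre
  non-breeding xi_b(t) ~ bin(xi_m(t), B(t));
* a Cormack–Jolly–Seber likelihood for adults with one-year trap dependence
  (logit p = logit p* + a for birds seen the season before);
* a two-state (colony / permanently emigrated) product-multinomial MRR
  likelihood for murre chicks, with age-structured survival (s1(t), s2,
  s35, adult), pre-recruitment fidelity F5 and F6, band-retention/visible-
  recruitment psi, area- and age-class-specific resighting, and a
  logit-linear declining dead-recovery reporting rate;
* a binomial state-space population model, N_a(t) = R(t) + S(t), with
  recruits R(t) ~ bin(N_a(t-d), tau(t-d) s_a(t-1)) (tau = rho phi_c / 2,
  or the fully age-structured murre variant) and counts observed with
  normal error x(t) ~ N(N_a(t), sigma_x^2).

See `docs/methods.md` for the full specification, priors, the sampler, and
all conventions.

## Worked example

Simulate a reduced-scale community (T = 15 years, about one quarter of
field-study sample sizes, synchrony generated at I = 0.8) and refit it:

```python
from msipm import run_mcmc, summarize_posterior
from msipm.simulate import default_scenario, simulate_bundle

bundle, truth = simulate_bundle(default_scenario(), seed=11)
result = run_mcmc(bundle, n_chains=2, n_iter=6000, seed=18, thin=4)
summary = summarize_posterior(result)
print(summary.loc[["beta_phi_M", "s2", "s35", "psi", "phi_c_R",
                   "I_phi_M", "I_rho_M"]].round(3))
```

which prints (posterior medians with symmetric 95% credible intervals):

```
            median   q2.5  q97.5   rhat
parameter
beta_phi_M   2.462  2.191  2.800  1.026
s2           0.718  0.602  0.833  1.029
s35          0.944  0.901  0.979  1.045
psi          0.853  0.791  0.910  1.001
phi_c_R      0.521  0.251  0.829  1.221
I_phi_M      0.331  0.002  0.996  1.252
I_rho_M      0.812  0.245  1.000  1.020
```

Read this as: the murre adult-survival intercept, second-year survival, the
band-retention probability and the razorbill combined juvenile survival are
recovered with intervals covering the generating values (2.789, 0.763,
0.850, 0.501); third-to-fifth-year survival (truth 0.898) lands a hair
outside its interval in this particular replicate — one miss among ~20
monitored parameters is what 95% intervals promise.  The productivity
synchrony index sits at the generating 0.8; the adult-survival index has a
near-full-width interval and a shrunken median, which is what weak
survival data genuinely support (see the shrinkage discussion in
`docs/methods.md`).  `R-hat` is reported per parameter; inspect
`result.worst_rhat()` before trusting a fit.

The same pipeline is scriptable from the shell:

```bash
msipm simulate --config scenario.yaml --seed 2 --out data/
msipm fit --data data/ --config fit.yaml --out run/
msipm summarize --run run/
msipm recover --config scenario.yaml --reps 3 --seed 1 --out rec/
```

Each command writes a `manifest.json` (command, config hash, seed, version,
wall clock) so every artifact is reproducible from its manifest.  `fit` also
logs the per-component log-likelihoods at the posterior median — the
first place to look when a joint fit misbehaves.

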