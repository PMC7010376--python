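# Methods

## The model

`msipm` fits a joint Bayesian model for a breeding community of three alcid
species (razorbill *R*, puffin *P*, common murre/guillemot *M*) monitored
over `T` annual occasions.  Each species contributes a single-species
integrated population model (IPM); the species are tied together by shared
year random effects on two demographic rates, which is what makes the model
multi-species and yields synchrony estimates.

### Demographic rates and synchrony layer

For productivity (rho, the probability that a pair's single egg yields a
fledged chick, t = 1..T) and adult survival (s_a, t = 1..T-1):

    logit rho_S(t) = beta_rho_S + delta_rho(t) + eps_rho_S(t)
    logit s_aS(t)  = beta_phi_S + delta_phi(t) + eps_phi_S(t)

with delta(t) ~ N(0, sigma_delta^2) common to all species and
eps_S(t) ~ N(0, sigma_eps_S^2) species-specific, all independent.  The
synchrony index per species and rate,

    I_S = sigma_delta^2 / (sigma_delta^2 + sigma_eps_S^2),

is the fraction of between-year logit-scale variance shared with the rest of
the community.  It is computed per posterior draw and summarized by the
median and central 95% interval; the plug-in index of the posterior-median
SDs is emitted alongside (suffix `_plugin`) but the draw-wise summary is the
primary quantity.  No sum-to-zero constraints are placed on the effects; the
additive confounding between intercepts and effect means is resolved by the
mean-zero hierarchical priors (and the sampler moves along those flat
directions explicitly; see below).

### Likelihood components

* **Breeding success** (all species): C(t) ~ bin(E(t), rho(t)) from E(t)
  monitored pairs.  Years with E(t)=0 contribute nothing.
* **Non-breeding** (murre): xi_b(t) ~ bin(xi_m(t), B(t)), B(t) the annual
  probability that a monitored pair does not skip breeding; each B(t) has a
  U(0,1) prior.
* **Adult mark-resight** (all species): Cormack-Jolly-Seber, conditioned on
  first capture, fully year-dependent survival s_a(t) and resighting with
  one-year trap dependence: logit p(t) = logit p*(t) + a for birds seen the
  previous season, p_bar(t) = p*(t) otherwise.  The physical capture at
  marking counts as "seen" for the lag.  The parameterization (baseline =
  not-seen-last-season, a = trap-happiness shift) is one of several
  equivalent full-rank choices; it matters when comparing p* estimates
  across analyses.  No adult emigration is assumed, so s_a is true survival;
  if data were generated with emigration the estimates would be biased low.
  The final-season p*(T) is left free (it is weakly identified and
  essentially prior-driven).
* **Chick mark-resight-recovery** (murre): the two-state (at-colony /
  permanently-emigrated) product-multinomial likelihood over release cohorts
  built from the Q/O/D/chi recursions, with sufficient statistics n/d/v.
  Age/year structure: year-specific first-year survival s1(t); constant s2
  and s35 (ages 3-5 of life); adult survival shared with the CJS component;
  fidelity 1 up to the fourth transition, then F5, F6, and band-retention /
  visible recruitment psi after recruitment age; resight probabilities in
  four age classes per banding area (A, and B where banding stops part-way);
  dead-recovery reporting logit-linear in the standardized occasion index,
  lambda(t) = logistic(alpha0 + alpha1 * y(t)).
* **Population state space** (all species): integer latent abundances with
  R(t) ~ bin(N(t-d), tau(t-d) s_a(t-1)), S(t) ~ bin(N(t-1), s_a(t-1)),
  N = R + S, where tau = rho phi_c / 2 for razorbill/puffin (phi_c the
  combined fledging-to-recruitment survival-and-fidelity) and
  tau = B rho s1 s2 s35^3 F5 F6 / 2 for the murre (d = 6).  Counts are
  observed as x(t) ~ N(N(t), sigma_x^2) for t > d (untruncated; the density
  is evaluated at the integer N without continuity correction).  Counts in
  the first d years set informative normal initialization priors on
  N(1..d) with the same SD; for the sparse-count puffin the init-prior means
  interpolate linearly between the nearest counted years.  A species with no
  counts at all gets no latent block (there is nothing to anchor it); its
  demographic parameters are then informed by the remaining data only, and a
  fully empty dataset samples the joint prior exactly (used as a sampler
  calibration check).

### Age/occasion bookkeeping for the chick MRR component

Occasions are 1-based everywhere; calendar years appear only in files.  A
chick banded at occasion t0 is released at bookkeeping age 1; it has age a
at occasion t0 + a - 1.  Resighting is impossible at ages 1-2 (the release
summer and the first return summer), so the field age-class labels
"2-year-olds", "3-year-olds", "4-to-5" and adults map to bookkeeping ages 3,
4, 5-6 and >= 7.  With banding from occasion 1, the earliest occasion at
which each class can occur is 3, 4, 5 and 7 — exactly the opening occasions
of the per-class resight windows.  Area-B windows close 3/4/6 occasions
after the last area-B banding for the first three classes (occasions 17, 18
and 20 in the full 26-year design, followed verbatim) and at T for adults.
Under this scheme the murre recruit rate s1 s2 s35^3 F5 F6 s_a lands
recruits at calendar age 6, the species' median age at first breeding.  A
recovery occasion r in a chick record means the band was reported during
year r after death in the interval (r-1, r), so recoveries are strictly
later than the last live sighting.

## Priors

U(0,1) for all probability parameters (phi_c, F5, F6, psi, B(t), s1(t), s2,
s35, window resight probabilities); U(-5,5) for logit-scale intercepts, trap
dependence a and the reporting coefficients alpha0, alpha1; N(0, 10^4) on
logit p*; U(0,3) for random-effect SDs; U(0,5000) for count-observation SDs,
widened to U(0,15000) for the sparse-count puffin.  Year effects and latent
abundances carry no separate prior: their densities are the random-effect
and system-process/initialization components of the joint posterior.

## Sampler

The posterior is sampled by adaptive Metropolis-within-Gibbs.  Each
parameter block records which likelihood components depend on it, so a
single-site update re-evaluates only those components.  Details:

* continuous scalars: Gaussian random walk, per-site step size adapted
  during warmup (Robbins-Monro on the log scale) toward acceptance 0.44;
  bounded parameters additionally take an independence proposal from their
  proper prior with probability `indep_prob` (default 0.05), for which prior
  and proposal ratios cancel exactly;
* latent abundances: integer random-walk steps (zero steps resampled to
  +/-1, preserving symmetry);
* the per-area resight-window vectors move as joint vector proposals
  (target acceptance 0.25) — they are numerous, weakly identified and
  expensive to update one at a time;
* the synchrony layer is resampled by exact Gibbs along its
  likelihood-flat directions: the likelihood sees the effects only through
  the per-species sums beta_S + delta(t) + eps_S(t), so conditional on
  those sums and the SDs the delta/eps decomposition is Gaussian per year
  and is drawn in closed form, as are the intercept-vs-effect-mean shifts
  (truncated normal at the uniform intercept bounds);
* the random-effect SDs and the count-observation SDs have exact
  conditionals under their uniform priors — with v = sigma^-2,
  v ~ Gamma((n-1)/2, sum(x^2)/2) truncated at the prior bound — and are
  drawn by inverse-CDF Gibbs (the observation SD pools the count residuals
  with the initialization-window residuals, which share it);
* amplitude moves rescale each (SD, effect-vector) pair jointly,
  (sigma, v) -> (u sigma, u v) with u = exp(z), z Gaussian, accepted with
  the (n+1) log u Jacobian term — the slow direction of hierarchical
  funnels;
* latent-trajectory moves: whole-trajectory integer shifts, shifts of the
  initialization window alone, and recruit/survivor exchanges at fixed N(t);
* a joint (phi_c, initialization level) ridge move for razorbill/puffin:
  phi_c is scaled by u on the log scale while Ninit is proposed from a
  discrete uniform window around Ninit/u; the move is rejected outright if
  the reverse proposal could not regenerate the current state, keeping the
  kernel exactly reversible.  Without this move the combined juvenile
  survival of the sparse-count species mixes extremely slowly along the
  ridge it shares with the unobserved early population level.

Chains are initialized at crude data-driven estimates (empirical
proportions, interpolated counts) with chain-specific jitter, retried until
the posterior is finite; an unresolvable initialization reports the
offending component by name.  Adaptation runs during warmup (default: first
half of the iterations) and is frozen afterwards.  Two or more chains are
required for the Gelman-Rubin statistic, computed with the classic
between/within-variance PSRF (identical constant chains return 1.0 rather
than NaN).  Summaries are medians and central 95% intervals with
linear-interpolation (type-7) quantiles.

Evaluation hot paths (the MRR table recursions, the CJS individual scan and
the summed binomial log-pmf) have compiled numba kernels with pure-numpy
equivalents kept alongside; the two paths are asserted equal in the tests.

## Synthetic-data generator

The generator is the exact generative dual of the likelihood: the same rate
assembly, the same windows and conventions, individual-level simulation of
adult histories (trap dependence included) and chick MRR fates (emigration
absorbing, band loss after recruitment age, reporting by the lambda trend).
Observed counts are rounded and floored at zero even though the fitted
observation model is an untruncated normal — a deliberate, negligible
realism mismatch at the configured noise-to-abundance ratios.

Default scenario (the study conditions at desk scale): T = 15 occasions and
roughly one quarter of the field sample sizes — monitored pairs per year
34/40/207 (R/P/M), non-breeding sample 78/yr, newly marked adults 3/10/15
per year, 40 + 20 chicks banded per year in areas A and B (area B until
occasion 8), puffin counts in 7 years only.  Intercepts and structural
parameters sit at field-realistic values (e.g. beta_phi giving adult
survival ~0.91-0.94, s2 = 0.763, s35 = 0.898, F5 = 0.865, F6 = 0.834,
psi = 0.85, alpha0 = -3.084, alpha1 = -0.687, observation SDs 90/1388/376);
synchrony variance components default to sigma_delta = 0.4,
sigma_eps = 0.2, i.e. a generating synchrony index of 0.8 for every species
and both rates.  First-year survival is drawn per year on the logit scale
with SD 1.2 around 0.5, reproducing its large between-year variability.
A full-scale (T = 26) scenario of the same structure exists for exercising
the complete study shape.

What the generator does not emulate: immigration, environmental covariates,
observer heterogeneity, within-season detection structure (detections are
already collapsed to one per bird-year), overdispersion in breeding success,
or dependence between datasets (the monitored birds are simulated
independently of the census).  Passing recovery tests therefore show
calibration under the model's own assumptions, not robustness to their
violation.

## Verification and problem sizes

The test suite checks, among others: the MRR cell probabilities against
brute-force enumeration over individual fates (A,T <= 5; agreement to
1e-12); normalization of every cohort cell vector and CJS release-pattern
distribution (1e-10); the collapse of the two-state chi onto an
independently coded CJS chi when fidelity is 1 and reporting 0 (1e-12);
additivity of the joint log posterior against independently evaluated
public components (1e-9); prior recovery on empty data (KS tests of U(0,1)
marginals at the 1% level with 10,000 draws); Gelman-Rubin calibration; and
parameter recovery.  The recovery study runs 2 replicate communities at the
default reduced scale with 2 chains of 6,000 sweeps (half warmup, thinned
by 4), checking >=90% coverage of the 95% CIs over the monitored constant
parameters and that the posterior-median synchrony indices average within
+/-0.15 of the generating 0.8.  These replication counts and chain lengths
are the package's default desk-scale verification settings; larger studies
(more replicates, longer chains, T = 26) use the same code paths via the
CLI (`msipm recover`, `iterations` in the fit config).

## Known limitations

* The sampler is a single-machine, single-chain-at-a-time random-walk
  scheme; full-scale analyses need long runs (the latent/ridge directions
  dominate the mixing time).  R-hat should always be inspected; values well
  above 1.1 on phi_c or latent blocks signal an under-mixed ridge.
* phi_c for a sparse-count species is intrinsically weakly identified: its
  posterior width reflects the initialization-level uncertainty, and desk-
  scale credible intervals for it can be wide or occasionally miss.
* Posterior medians of the synchrony indices are shrinkage estimators: with
  weak survival data the survival-side index posterior is wide and its
  median is pulled toward the prior median of I (0.5 under independent
  U(0,3) priors on the two SDs).  At the default desk-scale marking effort
  the survival-side medians sit well below a generating index of 0.8 even
  though their credible intervals cover it; a diagnostic with an order of
  magnitude more marked adults recovers the index essentially unbiased.
  Interpret point estimates of I jointly with their intervals.
* The murre recruit rate hard-codes d = 6 (s2 s35^3 spans ages 2-5 of
  life); murre-like species with a different age at first breeding are
  rejected rather than silently mis-modelled.
* No goodness-of-fit machinery beyond convergence diagnostics and
  component-wise log-likelihood reporting at the posterior median.
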