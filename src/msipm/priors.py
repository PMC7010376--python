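"""Prior specification: as uninformative as the model tolerates.

Defaults: U(0,1) for all probability parameters (phi_c, F5, F6, psi, B(t),
area resight probabilities, s1(t), s2, s35); U(-5,5) for logit-scale
intercepts, trap dependence a_S and the reporting-trend coefficients alpha0,
alpha1; N(0, 10^4) on logit p* for the adult resight baselines; U(0,3) for
the random-effect SDs; U(0, 5000) for the count-observation SDs, raised to
U(0, 15000) for the sparse-count (puffin-like) species.  Year random effects
and latent abundances carry no prior entry here: their densities are the
hierarchical random-effect terms and the system-process/initialization
components of the joint posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Prior", "Uniform", "Normal", "ImproperFlat", "PriorSpec", "default_priors"]


class Prior:
    proper = True

    def logpdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator) -> float:  # pragma: no cover
        raise NotImplementedError

    def in_support(self, x: float) -> bool:
        return True


@dataclass(frozen=True)
class Uniform(Prior):
    lo: float
    hi: float

    def logpdf(self, x):
        if self.lo <= x <= self.hi:
            return -np.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng):
        return rng.uniform(self.lo, self.hi)

    def in_support(self, x):
        return self.lo <= x <= self.hi


@dataclass(frozen=True)
class Normal(Prior):
    mu: float
    sd: float

    def logpdf(self, x):
        z = (x - self.mu) / self.sd
        return -0.5 * z * z - np.log(self.sd) - 0.5 * np.log(2 * np.pi)

    def sample(self, rng):
        return self.mu + self.sd * rng.normal()


@dataclass(frozen=True)
class ImproperFlat(Prior):
    """Flat placeholder for quantities whose density lives in a model
    component (year effects, latent abundances)."""

    proper = False

    def logpdf(self, x):
        return 0.0


@dataclass
class PriorSpec:
    """Rule-based prior table: one proper prior per parameter group, with
    optional per-parameter-name overrides."""

    groups: dict[str, Prior]
    overrides: dict[str, Prior] = field(default_factory=dict)

    def for_param(self, name: str, group: str) -> Prior:
        if name in self.overrides:
            return self.overrides[name]
        if group not in self.groups:
            raise KeyError(f"no prior rule for parameter group {group!r} ({name})")
        return self.groups[group]


def default_priors(sigma_x_upper: dict[str, float] | None = None) -> PriorSpec:
    """The default prior table.  ``sigma_x_upper`` maps species codes to the
    upper bound of the observation-SD prior (default 5000 per species; the
    model supplies 15000 for sparse-count species via the study config)."""
    spec = PriorSpec(
        groups={
            "prob": Uniform(0.0, 1.0),
            "intercept": Uniform(-5.0, 5.0),
            "logit_pstar": Normal(0.0, 100.0),
            "re_sd": Uniform(0.0, 3.0),
            "sigma_x": Uniform(0.0, 5000.0),
            "effect": ImproperFlat(),
            "latent": ImproperFlat(),
        }
    )
    for code, hi in (sigma_x_upper or {}).items():
        spec.overrides[f"sigma_x_{code}"] = Uniform(0.0, float(hi))
    return spec
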