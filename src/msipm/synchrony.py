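"""Cross-species synchrony layer: shared and species-specific year random
effects on logit demographic rates, and the synchrony indices.

For each demographic rate (productivity rho over t = 1..T, adult survival
s_a over t = 1..T-1) and species S:

    logit(rate_S(t)) = beta_S + delta(t) + eps_S(t),
    delta(t)  ~ N(0, sigma_delta^2)   (common year effect, all species)
    eps_S(t)  ~ N(0, sigma_eps_S^2)   (species-specific year effect)

all effects independent across years and species.  The synchrony index

    I_S = sigma_delta^2 / (sigma_delta^2 + sigma_eps_S^2)

is the fraction of species S's between-year logit-scale variance shared with
the rest of the community; it is computed per MCMC draw and then summarized.
No sum-to-zero constraints are imposed on the effects; the mean-zero
hierarchical priors resolve the additive confounding with the intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import expit, norm_logpdf

__all__ = ["SynchronyBlock", "assemble_rate_series", "re_logpdf", "synchrony_index"]


@dataclass
class SynchronyBlock:
    """Intercepts, year effects and their SDs for one demographic rate.

    ``delta`` is 1-based of length L+1 with L = T (productivity) or T-1
    (survival); ``eps[S]`` has the same length per species code.
    """

    beta: dict[str, float]
    delta: np.ndarray
    eps: dict[str, np.ndarray]
    sigma_delta: float
    sigma_eps: dict[str, float] = field(default_factory=dict)

    @property
    def L(self) -> int:
        return len(self.delta) - 1


def assemble_rate_series(block: SynchronyBlock, species: str) -> np.ndarray:
    """rate_S(t) = logistic(beta_S + delta(t) + eps_S(t)), 1-based array of
    length L+1 (index 0 is NaN)."""
    out = np.full(block.L + 1, np.nan)
    out[1:] = expit(block.beta[species] + block.delta[1:] + block.eps[species][1:])
    return out


def re_logpdf(block: SynchronyBlock) -> float:
    """Log-density of all year random effects under their mean-zero normals.
    A zero SD gives -inf (the priors keep SDs strictly positive)."""
    total = norm_logpdf(block.delta[1:], 0.0, block.sigma_delta).sum()
    for S, e in block.eps.items():
        total += norm_logpdf(e[1:], 0.0, block.sigma_eps[S]).sum()
    return float(total)


def synchrony_index(sigma_delta, sigma_eps):
    """I = sigma_delta^2 / (sigma_delta^2 + sigma_eps^2), elementwise over
    MCMC draws; NaN (flagged) where both SDs are zero."""
    sd2 = np.asarray(sigma_delta, dtype=float) ** 2
    se2 = np.asarray(sigma_eps, dtype=float) ** 2
    denom = sd2 + se2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, sd2 / np.where(denom > 0, denom, 1.0), np.nan)
    return out if out.ndim else float(out)
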