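"""Cormack-Jolly-Seber likelihood for birds marked as breeding adults.

Survival s(t) (t = 1..T-1) is fully year-dependent; resighting at occasion
t = 2..T uses a year-specific baseline p*(t) with one-year trap dependence:
birds seen the season before are resighted with logit p(t) = logit p*(t) + a,
birds not seen with p_bar(t) = p*(t).  The physical capture at marking counts
as "seen" for the trap-dependence lag.  No adult emigration is assumed, so s
is true survival.

The likelihood conditions on first capture and is evaluated per individual:
explicit survival/detection terms up to the last sighting, then a chi-type
probability of never being seen again.
"""

from __future__ import annotations

import numpy as np

from ..data import AdultEncounterHistory, ValidationError
from ..util import as_1based, expit, logit

__all__ = ["effective_resight_probs", "cjs_chi", "cjs_loglik", "prepare_histories"]


def effective_resight_probs(p_star, a: float):
    """(p, p_bar): resight probabilities for birds seen / not seen the
    previous season.  logit p = logit p* + a; p_bar = p*."""
    p_star = np.asarray(p_star, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = expit(logit(p_star) + a)
    return p, p_star.copy()


def cjs_chi(s: np.ndarray, p: np.ndarray, p_bar: np.ndarray):
    """chi recursions: (chi_seen, chi_notseen), each 1-based over t = 1..T.

    chi_z(t) is the probability a bird alive at occasion t, with
    previous-season detection state z, is never seen after t.  All input
    arrays are 1-based: s valid at 1..T-1, p/p_bar at 2..T.
    """
    T = len(s) - 1
    chi1 = np.ones(T + 1)
    chi0 = np.ones(T + 1)
    for t in range(T - 1, 0, -1):
        dead = 1.0 - s[t]
        chi1[t] = dead + s[t] * (1.0 - p[t + 1]) * chi0[t + 1]
        chi0[t] = dead + s[t] * (1.0 - p_bar[t + 1]) * chi0[t + 1]
    return chi1, chi0


def prepare_histories(histories: list[AdultEncounterHistory], T: int):
    """Pack histories into (f, last, seen) arrays for the vectorized core."""
    nind = len(histories)
    f = np.zeros(nind, dtype=np.int64)
    last = np.zeros(nind, dtype=np.int64)
    seen = np.zeros((nind, T + 1), dtype=np.uint8)
    for i, h in enumerate(histories):
        if len(h.seen) != T + 1:
            raise ValidationError(f"adult {h.id}: history length != T+1")
        if not h.seen[h.f]:
            raise ValidationError(f"adult {h.id}: not marked as seen at f={h.f}")
        if h.seen[: h.f].any():
            raise ValidationError(f"adult {h.id}: sighting before marking occasion")
        f[i] = h.f
        last[i] = h.last_seen
        seen[i] = h.seen
    return f, last, seen


try:  # compiled kernel for the sampler's hot loop; numpy path kept below
    import math

    from numba import njit as _njit

    @_njit(cache=False)
    def _cjs_kernel(f, last, seen, s, p, pbar):
        T = s.shape[0] - 1
        chi1 = np.ones(T + 1)
        chi0 = np.ones(T + 1)
        for t in range(T - 1, 0, -1):
            dead = 1.0 - s[t]
            chi1[t] = dead + s[t] * (1.0 - p[t + 1]) * chi0[t + 1]
            chi0[t] = dead + s[t] * (1.0 - pbar[t + 1]) * chi0[t + 1]
        total = 0.0
        for i in range(f.shape[0]):
            li = last[i]
            for t in range(f[i] + 1, li + 1):
                st = s[t - 1]
                if st <= 0.0:
                    return -np.inf
                total += math.log(st)
                pz = p[t] if seen[i, t - 1] else pbar[t]
                if seen[i, t]:
                    if pz <= 0.0:
                        return -np.inf
                    total += math.log(pz)
                else:
                    if pz >= 1.0:
                        return -np.inf
                    total += math.log1p(-pz)
            c = chi1[li]
            if c <= 0.0:
                return -np.inf
            total += math.log(c)
        return total

except Exception:  # pragma: no cover - numba is normally available
    _cjs_kernel = None


def cjs_loglik_core(f, last, seen, s, p_star, a: float) -> float:
    """CJS log-likelihood on packed arrays (1-based parameters)."""
    if len(f) == 0:
        return 0.0
    p, p_bar = effective_resight_probs(p_star, a)
    if _cjs_kernel is not None:
        return float(
            _cjs_kernel(f, last, seen, np.asarray(s, float), p, p_bar)
        )
    return _cjs_loglik_numpy(f, last, seen, s, p, p_bar)


def _cjs_loglik_numpy(f, last, seen, s, p, p_bar) -> float:
    """Vectorized pure-numpy evaluation; same value as the kernel."""
    T = len(s) - 1
    chi1, _ = cjs_chi(s, p, p_bar)

    t = np.arange(2, T + 1)
    active = (t[None, :] > f[:, None]) & (t[None, :] <= last[:, None])
    z = seen[:, 1:T].astype(bool)  # detection state at t-1
    w = seen[:, 2 : T + 1].astype(bool)  # detected at t?
    with np.errstate(divide="ignore", invalid="ignore"):
        log_s = np.log(s[1:T])
        lp = np.where(z, np.log(p[2:]), np.log(p_bar[2:]))
        lq = np.where(z, np.log1p(-p[2:]), np.log1p(-p_bar[2:]))
        det = np.where(w, lp, lq)
        tail = np.log(chi1[last])
    contrib = np.where(active, det + log_s[None, :], 0.0)
    return float(contrib.sum() + tail.sum())


def cjs_loglik(histories: list[AdultEncounterHistory], s, p_star, a: float) -> float:
    """CJS log-likelihood for a list of adult encounter histories.

    ``s`` covers occasions 1..T-1 and ``p_star`` resight occasions 2..T
    (plain length-(T-1) arrays or 1-based length-(T+1) arrays).
    """
    if not histories:
        return 0.0
    T = len(histories[0].seen) - 1
    s1 = as_1based(s, T, first=1, last=T - 1)
    ps1 = as_1based(p_star, T, first=2)
    f, last, seen = prepare_histories(histories, T)
    return cjs_loglik_core(f, last, seen, s1, ps1, a)
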