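"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions of the observation processes
(per-bird fates enumerated explicitly), deliberately avoiding the recursion
structure of the production code.
"""

from __future__ import annotations

import numpy as np


# ----------------------------------------------------------------------
# CJS: exhaustive enumeration over death times for one encounter history
def cjs_history_prob(f, w, s, p, p_bar, T) -> float:
    """Probability of one adult encounter history by summing over the last
    year alive D = l..T.  ``w`` is the 1-based 0/1 sighting vector (w[f]=1),
    ``s`` survival (1-based, 1..T-1), ``p``/``p_bar`` resight probabilities
    at occasions 2..T for birds seen / not seen the previous season."""
    last = max(t for t in range(f, T + 1) if w[t])
    total = 0.0
    for D in range(last, T + 1):
        alive = 1.0
        for t in range(f + 1, D + 1):
            alive *= s[t - 1]
        if D < T:
            alive *= 1.0 - s[D]
        det = 1.0
        for t in range(f + 1, D + 1):
            pz = p[t] if w[t - 1] else p_bar[t]
            det *= pz if w[t] else (1.0 - pz)
        total += alive * det
    return total


# ----------------------------------------------------------------------
# MRR: exhaustive enumeration over (death age, emigration age, report) paths
def _avoidance_sum(a0, t0, af, F, p):
    """Sum over emigration transitions (at ages a0..af-1, or never) of the
    probability of the corresponding fidelity path times the probability of
    never being resighted while alive in state 1 at ages a0+1..af."""

    def year(j):
        return t0 + j - a0

    total = 0.0
    for e in range(a0, af):  # transition e -> e+1 leaves the colony
        term = 1.0 - F[e, year(e)]
        for j in range(a0, e):
            term *= F[j, year(j)]
        for j in range(a0 + 1, e + 1):
            term *= 1.0 - p[j, year(j)]
        total += term
    stay = 1.0
    for j in range(a0, af):
        stay *= F[j, year(j)]
    for j in range(a0 + 1, af + 1):
        stay *= 1.0 - p[j, year(j)]
    return total + stay


def mrr_enum_cell_probs(a0, t0, phi, F, p, lam, A, T):
    """Multinomial cell probabilities for a release at (a0, t0): live
    resights at ages a0+1..bmax+1 (O cells), dead recoveries at ages
    a0..bmax (D cells), then never-seen-again, all from first principles."""

    def year(j):
        return t0 + j - a0

    bmax = min(A - 1, a0 + T - 1 - t0)
    O = []
    D = []
    for b in range(a0, bmax + 1):
        m = b + 1  # resighted alive at age m
        prob = p[m, year(m)]
        for j in range(a0, m):
            prob *= phi[j, year(j)] * F[j, year(j)]
        for j in range(a0 + 1, m):
            prob *= 1.0 - p[j, year(j)]
        O.append(prob)
        # recovered dead at age b: survive to b, die, be reported, and have
        # avoided detection at ages a0+1..b over all emigration paths
        prob = (1.0 - phi[b, year(b)]) * lam[b, year(b)]
        for j in range(a0, b):
            prob *= phi[j, year(j)]
        prob *= _avoidance_sum(a0, t0, b, F, p)
        D.append(prob)
    # never seen again: unreported deaths at any age, or survival to the end
    chi = 0.0
    for k in range(a0, a0 + T - t0):  # dies while aged k, year(k) <= T-1
        term = (1.0 - phi[k, year(k)]) * (1.0 - lam[k, year(k)])
        for j in range(a0, k):
            term *= phi[j, year(j)]
        term *= _avoidance_sum(a0, t0, k, F, p)
        chi += term
    aT = a0 + T - t0  # alive at the final occasion, undetected throughout
    term = 1.0
    for j in range(a0, aT):
        term *= phi[j, year(j)]
    term *= _avoidance_sum(a0, t0, aT, F, p)
    chi += term
    return np.array(O), np.array(D), chi


# ----------------------------------------------------------------------
# MRR sufficient statistics: naive per-record double loop
def naive_mrr_stats(records, A, T):
    """n/d/v arrays built by walking each record's observation chain with
    plain loops (independent of the production builder)."""
    n = np.zeros((A + 1, A + 1, T + 1), dtype=int)
    d = np.zeros((A + 1, A + 1, T + 1), dtype=int)
    v = np.zeros((A + 1, T + 1), dtype=int)
    for rec in records:
        chain = [(1, rec.t0)] + [(t - rec.t0 + 1, t) for t in sorted(rec.resights)]
        for i in range(len(chain) - 1):
            (a, t), (a2, _) = chain[i], chain[i + 1]
            n[a, a2 - 1, t] += 1
        a_last, t_last = chain[-1]
        if rec.recovery is not None:
            d[a_last, rec.recovery - rec.t0, t_last] += 1
        else:
            v[a_last, t_last] += 1
    return n, d, v
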