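"""Multi-state mark-resight-recovery (MRR) likelihood for birds banded as chicks.

Two mutually exclusive states: state 1 "at the colony" (recruited or natal)
and state 0 "emigrated" (absorbing, unobservable alive; bands can still be
recovered from dead birds).  Survival phi(a,t) is shared between states,
fidelity F(a,t) is the probability of staying in state 1 over the a -> a+1
transition, resighting p(a,t) applies only in state 1, and lambda(a,t) is the
probability a bird that dies while aged a in year t is recovered dead and its
band reported.

The likelihood is product-multinomial over release cohorts (a, t): cell
probabilities are next-seen-alive terms O(a,b,t), dead-recovery terms
D(a,b,t), and the never-seen-again terms chi(a,t), all computed from the
first-step/recursive quantities Q(r,s):

  Q_{a,b,t}(1,1) = phi*F                       (b = a)
                   phi*F*(1-p(a+1,t+1))*Q_{a+1,b,t+1}(1,1)            (b > a)
  Q_{a,b,t}(0,0) = phi                         (b = a)
                   phi*Q_{a+1,b,t+1}(0,0)                             (b > a)
  Q_{a,b,t}(1,0) = phi*(1-F)                   (b = a)
                   phi*{(1-F)*Q(0,0) + F*(1-p(a+1,t+1))*Q(1,0)}       (b > a)
  O_{a,b,t}(1,1) = Q_{a,b,t}(1,1) * p(b+1, t+b-a+1)
  D_{a,b,t}(1)   = (1-phi)*lambda              (b = a)
                   (1-phi(b,t+b-a))*lambda(b,t+b-a)
                     * {Q_{a,b-1,t}(1,0) + (1-p(b,t+b-a))*Q_{a,b-1,t}(1,1)}
  chi_{a,t}(0)   = 1 at t=T, else (1-lam)(1-phi) + phi*chi_{a+1,t+1}(0)
  chi_{a,t}(1)   = 1 at t=T, else (1-lam)(1-phi)
                   + phi*{(1-F)*chi(0) + F*(1-p(a+1,t+1))*chi(1)}

Age/year structure: phi(1,t)=s1(t) year-specific, phi(2,.)=s2,
phi(3..5,.)=s35, phi(a>5,t)=s_a(t) (the adult survival shared with the adult
CJS component); F(1..4)=1, F(5)=F5, F(6)=F6, F(a>6)=psi (band retention +
visible recruitment); p(1..2,.)=0, then the area-specific age-class windows;
logit lambda = alpha0 + alpha1*y(t) with y the standardized year index over
1..T-1, identical across ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ..config import RESIGHT_CLASSES, StudyConfig
from ..data import MRRSufficientStats
from ..util import expit

__all__ = [
    "MRRStructuralParams",
    "MRRTables",
    "standardized_years",
    "assemble_age_year_params",
    "compute_mrr_tables",
    "mrr_cohort_cell_probs",
    "mrr_loglik",
    "prepare_mrr_stats",
    "mrr_loglik_prepared",
]


@dataclass
class MRRStructuralParams:
    """Structural parameters of the chick MRR model (arrays 1-based).

    ``p[area][cls]`` holds the resight probability series of age class
    ``cls`` in banding area ``area`` as a 1-based length-(T+1) array; only
    entries inside the configured window are read.
    """

    s1: np.ndarray  # first-year survival, valid t=1..T-1
    s2: float
    s35: float
    s_a: np.ndarray  # adult survival, valid t=1..T-1
    F5: float
    F6: float
    psi: float
    alpha0: float
    alpha1: float
    p: dict[str, dict[str, np.ndarray]]


@lru_cache(maxsize=8)
def standardized_years(T: int) -> np.ndarray:
    """Standardized year index over survival intervals 1..T-1 (1-based array:
    y[t] = (t - mean) / sd with the sample SD).  Cached; treat as read-only."""
    t = np.arange(1, T, dtype=float)
    y = np.full(T + 1, np.nan)
    y[1:T] = (t - t.mean()) / t.std(ddof=1)
    y.setflags(write=False)
    return y


# age-class -> bookkeeping ages helper
def _class_ages(cls: str, A: int) -> list[int]:
    lo, hi = RESIGHT_CLASSES[cls]
    return list(range(lo, (A if hi is None else min(hi, A)) + 1))


def assemble_age_year_params(structural: MRRStructuralParams, config: StudyConfig):
    """Expand the structural parameters into full (phi, F, lam, p-per-area)
    tables over bookkeeping ages 1..A and occasions 1..T.

    Returns ``(phi, F, lam, p_by_area)``; phi/F/lam have shape (A+1, T+1)
    with valid occasions 1..T-1, p arrays are (A+1, T+1) with valid resight
    occasions 2..T (zero where resighting is impossible or outside the
    configured window).
    """
    A, T = config.A, config.T
    phi = np.zeros((A + 1, T + 1))
    F = np.zeros((A + 1, T + 1))
    lam = np.zeros((A + 1, T + 1))
    ts = slice(1, T)  # survival/reporting intervals 1..T-1
    phi[1, ts] = structural.s1[ts]
    if A >= 2:
        phi[2, ts] = structural.s2
    phi[3 : min(5, A) + 1, ts] = structural.s35
    phi[6:, ts] = structural.s_a[ts][None, :]
    F[1:5, ts] = 1.0
    if A >= 5:
        F[5, ts] = structural.F5
    if A >= 6:
        F[6, ts] = structural.F6
    F[7:, ts] = structural.psi
    y = standardized_years(T)
    lam[1:, ts] = expit(structural.alpha0 + structural.alpha1 * y[ts])[None, :]

    p_by_area: dict[str, np.ndarray] = {}
    for area in config.areas:
        p = np.zeros((A + 1, T + 1))
        for cls in RESIGHT_CLASSES:
            lo, hi = config.window(area, cls)
            arr = structural.p[area][cls]
            if arr.shape != (T + 1,):
                raise ValueError(
                    f"area {area} class {cls}: expected 1-based length {T + 1} array"
                )
            vals = arr[lo : hi + 1]
            if np.isnan(vals).any():
                raise ValueError(f"area {area} class {cls}: NaN inside window {lo}..{hi}")
            alo, ahi = _class_ages(cls, A)[0], _class_ages(cls, A)[-1]
            p[alo : ahi + 1, lo : hi + 1] = vals[None, :]
        p_by_area[area] = p
    return phi, F, lam, p_by_area


@dataclass
class MRRTables:
    """Fully expanded MRR probability tables.

    ``Q11/Q10/Q00/O/D`` are gap-indexed: ``X[g, a, t]`` is the quantity for
    release age ``a``, final age ``b = a + g``, release year ``t``.  ``chi1``
    and ``chi0`` are (a, t)-indexed.  Entries outside the valid index ranges
    of the likelihood are zero-filled and never read.
    """

    Q11: np.ndarray
    Q10: np.ndarray
    Q00: np.ndarray
    O: np.ndarray
    D: np.ndarray
    chi1: np.ndarray
    chi0: np.ndarray
    A: int
    T: int

    def O_cell(self, a: int, b: int, t: int) -> float:
        return float(self.O[b - a, a, t])

    def D_cell(self, a: int, b: int, t: int) -> float:
        return float(self.D[b - a, a, t])

    def chi_cell(self, a: int, t: int) -> float:
        return float(self.chi1[a, t])


try:  # compiled kernel for the hot path; the numpy path below is equivalent
    from numba import njit as _njit

    @_njit(cache=False)
    def _tables_kernel(phi, F, p, lam, A, T, Q11, Q10, Q00, O, D, chi1, chi0):
        G = Q11.shape[0]
        for g in range(G):
            for a in range(1, A + 1):
                for t in range(1, T + 1):
                    ph = phi[a, t]
                    Fd = F[a, t]
                    if g == 0:
                        Q11[0, a, t] = ph * Fd
                        Q00[0, a, t] = ph
                        Q10[0, a, t] = ph * (1.0 - Fd)
                        D[0, a, t] = (1.0 - ph) * lam[a, t]
                    else:
                        pn = p[a + 1, t + 1]
                        Q11[g, a, t] = ph * Fd * (1.0 - pn) * Q11[g - 1, a + 1, t + 1]
                        Q00[g, a, t] = ph * Q00[g - 1, a + 1, t + 1]
                        Q10[g, a, t] = ph * (
                            (1.0 - Fd) * Q00[g - 1, a + 1, t + 1]
                            + Fd * (1.0 - pn) * Q10[g - 1, a + 1, t + 1]
                        )
                        b = a + g
                        tb = t + g
                        if b <= A and tb <= T:
                            phib = phi[b, tb]
                            lamb = lam[b, tb]
                            pb = p[b, tb]
                            D[g, a, t] = (1.0 - phib) * lamb * (
                                Q10[g - 1, a, t] + (1.0 - pb) * Q11[g - 1, a, t]
                            )
                    b1 = a + g + 1
                    t1 = t + g + 1
                    if b1 <= A and t1 <= T:
                        O[g, a, t] = Q11[g, a, t] * p[b1, t1]
        for t in range(T - 1, 0, -1):
            for a in range(1, A + 1):
                ph = phi[a, t]
                dead = (1.0 - lam[a, t]) * (1.0 - ph)
                chi0[a, t] = dead + ph * chi0[a + 1, t + 1]
                chi1[a, t] = dead + ph * (
                    (1.0 - F[a, t]) * chi0[a + 1, t + 1]
                    + F[a, t] * (1.0 - p[a + 1, t + 1]) * chi1[a + 1, t + 1]
                )

except Exception:  # pragma: no cover - numba is normally available
    _tables_kernel = None


def compute_mrr_tables(phi, F, p, lam, A: int, T: int) -> MRRTables:
    """Evaluate the Q/O/D/chi recursions (compiled kernel when available)."""
    if _tables_kernel is not None:
        pad = np.zeros((4, A + 2, T + 2))
        pad[0, : A + 1, : T + 1] = phi
        pad[1, : A + 1, : T + 1] = F
        pad[2, : A + 1, : T + 1] = p
        pad[3, : A + 1, : T + 1] = lam
        G = max(A - 1, 1)
        Q11 = np.zeros((G, A + 2, T + 2))
        Q10 = np.zeros((G, A + 2, T + 2))
        Q00 = np.zeros((G, A + 2, T + 2))
        O = np.zeros((G, A + 2, T + 2))
        D = np.zeros((G, A + 2, T + 2))
        chi1 = np.ones((A + 2, T + 1))
        chi0 = np.ones((A + 2, T + 1))
        _tables_kernel(pad[0], pad[1], pad[2], pad[3], A, T, Q11, Q10, Q00, O, D, chi1, chi0)
        return MRRTables(Q11, Q10, Q00, O, D, chi1, chi0, A, T)
    return _compute_mrr_tables_numpy(phi, F, p, lam, A, T)


def _compute_mrr_tables_numpy(phi, F, p, lam, A: int, T: int) -> MRRTables:
    """Pure-numpy evaluation by vectorized diagonal recursion in the age gap
    g = b - a (and backward in t for chi); same results as the kernel."""
    # padded parameter tables so shifted reads (a+g, t+g) stay in bounds
    pad_a, pad_t = 2 * A + 2, T + A + 2
    phiP = np.zeros((pad_a, pad_t))
    FP = np.zeros((pad_a, pad_t))
    pP = np.zeros((pad_a, pad_t))
    lamP = np.zeros((pad_a, pad_t))
    phiP[: A + 1, : T + 1] = phi
    FP[: A + 1, : T + 1] = F
    pP[: A + 1, : T + 1] = p
    lamP[: A + 1, : T + 1] = lam

    G = max(A - 1, 1)
    shape = (G, A + 2, T + 2)
    Q11 = np.zeros(shape)
    Q10 = np.zeros(shape)
    Q00 = np.zeros(shape)
    O = np.zeros(shape)
    D = np.zeros(shape)

    AS, TS = slice(1, A + 1), slice(1, T + 1)
    ph = phiP[AS, TS]
    Fd = FP[AS, TS]
    lm = lamP[AS, TS]
    Q11[0, AS, TS] = ph * Fd
    Q00[0, AS, TS] = ph
    Q10[0, AS, TS] = ph * (1.0 - Fd)
    D[0, AS, TS] = (1.0 - ph) * lm

    for g in range(1, G):
        nxt = (slice(2, A + 2), slice(2, T + 2))
        pnext = pP[2 : A + 2, 2 : T + 2]
        Q11[g, AS, TS] = ph * Fd * (1.0 - pnext) * Q11[g - 1][nxt]
        Q00[g, AS, TS] = ph * Q00[g - 1][nxt]
        Q10[g, AS, TS] = ph * (
            (1.0 - Fd) * Q00[g - 1][nxt] + Fd * (1.0 - pnext) * Q10[g - 1][nxt]
        )
        # death while aged b = a+g in year t+g, unobserved in between
        phi_b = phiP[1 + g : A + 1 + g, 1 + g : T + 1 + g]
        lam_b = lamP[1 + g : A + 1 + g, 1 + g : T + 1 + g]
        p_b = pP[1 + g : A + 1 + g, 1 + g : T + 1 + g]
        D[g, AS, TS] = (1.0 - phi_b) * lam_b * (
            Q10[g - 1, AS, TS] + (1.0 - p_b) * Q11[g - 1, AS, TS]
        )

    for g in range(G):
        O[g, AS, TS] = Q11[g, AS, TS] * pP[g + 2 : A + g + 2, g + 2 : T + g + 2]

    chi1 = np.ones((A + 2, T + 1))
    chi0 = np.ones((A + 2, T + 1))
    for t in range(T - 1, 0, -1):
        ph_t = phiP[1 : A + 1, t]
        dead = (1.0 - lamP[1 : A + 1, t]) * (1.0 - ph_t)
        chi0[1 : A + 1, t] = dead + ph_t * chi0[2 : A + 2, t + 1]
        chi1[1 : A + 1, t] = dead + ph_t * (
            (1.0 - FP[1 : A + 1, t]) * chi0[2 : A + 2, t + 1]
            + FP[1 : A + 1, t] * (1.0 - pP[2 : A + 2, t + 1]) * chi1[2 : A + 2, t + 1]
        )
    return MRRTables(Q11, Q10, Q00, O, D, chi1, chi0, A, T)


def mrr_cohort_cell_probs(a: int, t: int, tables: MRRTables) -> np.ndarray:
    """Multinomial cell probabilities for the release cohort observed at
    (age a, year t): resights O(a, a..bmax, t), recoveries D(a, a..bmax, t),
    then chi(a, t); bmax = min(A-1, a+T-1-t) truncates at the study horizon."""
    A, T = tables.A, tables.T
    if not (1 <= a <= A and a <= t <= T):
        raise ValueError(f"invalid release cohort (a={a}, t={t}) for A={A}, T={T}")
    bmax = min(A - 1, a + T - 1 - t)
    if bmax < a:
        return np.array([tables.chi1[a, t]])
    gs = np.arange(0, bmax - a + 1)
    return np.concatenate(
        [tables.O[gs, a, t], tables.D[gs, a, t], [tables.chi1[a, t]]]
    )


def prepare_mrr_stats(stats: MRRSufficientStats):
    """Index/count arrays of the nonzero sufficient statistics, for repeated
    likelihood evaluation against fresh tables.  Index-range validity (b = a+g
    with a <= b <= min(A-1, a+T-1-t)) is checked here, once, since the data
    do not change between evaluations."""
    A, T = stats.A, stats.T
    out = {}
    counts = []
    invalid = False
    for name, arr in (("n", stats.n), ("d", stats.d)):
        a, b, t = np.nonzero(arr)
        g = b - a
        out[name] = (g, a, t)
        counts.append(arr[a, b, t].astype(float))
        if len(g) and ((g < 0) | (a + g > A - 1) | (g > T - 1 - t)).any():
            invalid = True
    a, t = np.nonzero(stats.v)
    out["v"] = (a, t)
    counts.append(stats.v[a, t].astype(float))
    out["counts"] = np.concatenate(counts)
    out["invalid"] = invalid
    return out


def mrr_loglik_prepared(prep, tables: MRRTables) -> float:
    if prep["invalid"]:
        return -np.inf  # positive count on a structurally impossible cell
    gn, an, tn = prep["n"]
    gd, ad, td = prep["d"]
    av, tv = prep["v"]
    probs = np.concatenate(
        (tables.O[gn, an, tn], tables.D[gd, ad, td], tables.chi1[av, tv])
    )
    if probs.size == 0:
        return 0.0
    if probs.min() <= 0.0:
        return -np.inf
    return float(np.log(probs) @ prep["counts"])


def mrr_loglik(
    statsA: MRRSufficientStats,
    statsB: MRRSufficientStats,
    structural: MRRStructuralParams,
    config: StudyConfig,
) -> float:
    """Log-likelihood of the complete chick MRR dataset: sum over the two
    banding areas (shared survival/fidelity/reporting, area-specific resight
    probabilities) of sum over cells of count * log(cell probability).
    Multinomial coefficients are constant in the parameters and omitted."""
    phi, F, lam, p_by_area = assemble_age_year_params(structural, config)
    total = 0.0
    for stats in (statsA, statsB):
        tables = compute_mrr_tables(phi, F, p_by_area[stats.area], lam, config.A, config.T)
        total += mrr_loglik_prepared(prepare_mrr_stats(stats), tables)
    return total
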