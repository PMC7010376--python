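"""In-memory containers for the observed datasets.

All time series are stored as 1-based numpy arrays of length ``T + 1`` with
index 0 unused, so code reads like the model equations.  Missing counts are
NaN, never 0 (0 is a legal count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import StudyConfig, resight_class_of_age

__all__ = [
    "CountSeries",
    "BreedingSuccessSeries",
    "NonBreedingSeries",
    "AdultEncounterHistory",
    "ChickEncounterRecord",
    "MRRSufficientStats",
    "SpeciesData",
    "DatasetBundle",
    "ValidationError",
    "build_mrr_sufficient_stats",
]


class ValidationError(ValueError):
    """Raised when an input dataset violates a structural invariant."""


def _series(values, T: int, dtype=float) -> np.ndarray:
    out = np.full(T + 1, np.nan if dtype is float else 0, dtype=dtype)
    v = np.asarray(values, dtype=dtype)
    if v.shape != (T,):
        raise ValidationError(f"series has length {v.shape}, expected ({T},)")
    out[1:] = v
    return out


@dataclass
class CountSeries:
    """Observed breeding-pair (female) counts x(t); NaN where not counted."""

    x: np.ndarray  # float, index 1..T; NaN = missing

    @classmethod
    def from_values(cls, values, T: int) -> "CountSeries":
        s = cls(_series(values, T))
        if np.nanmin(s.x[1:], initial=np.inf) < 0:
            raise ValidationError("counts must be nonnegative")
        return s

    @property
    def T(self) -> int:
        return len(self.x) - 1

    def observed_years(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.x[1:])) + 1


@dataclass
class BreedingSuccessSeries:
    """E(t) monitored pairs and C(t) fledged chicks, 0 <= C <= E."""

    E: np.ndarray  # int, index 1..T
    C: np.ndarray

    @classmethod
    def from_values(cls, E, C, T: int) -> "BreedingSuccessSeries":
        s = cls(_series(E, T, int), _series(C, T, int))
        s.validate()
        return s

    def validate(self) -> None:
        bad = np.flatnonzero((self.C[1:] > self.E[1:]) | (self.C[1:] < 0) | (self.E[1:] < 0))
        if bad.size:
            raise ValidationError(
                f"breeding success: C(t) outside [0, E(t)] at t={bad[0] + 1}"
            )

    @property
    def T(self) -> int:
        return len(self.E) - 1


@dataclass
class NonBreedingSeries:
    """xi_m(t) monitored birds and xi_b(t) of them that bred."""

    xi_m: np.ndarray
    xi_b: np.ndarray

    @classmethod
    def from_values(cls, xi_m, xi_b, T: int) -> "NonBreedingSeries":
        s = cls(_series(xi_m, T, int), _series(xi_b, T, int))
        bad = np.flatnonzero((s.xi_b[1:] > s.xi_m[1:]) | (s.xi_b[1:] < 0))
        if bad.size:
            raise ValidationError(
                f"non-breeding: xi_b(t) outside [0, xi_m(t)] at t={bad[0] + 1}"
            )
        return s

    @property
    def T(self) -> int:
        return len(self.xi_m) - 1


@dataclass
class AdultEncounterHistory:
    """One bird marked as a breeding adult at occasion ``f`` and searched for
    at occasions f+1..T.  ``seen`` is a 0/1 array over occasions 1..T (1-based)
    including the marking occasion itself (physical capture counts as a
    sighting for the trap-dependence lag)."""

    id: str
    species: str
    f: int
    seen: np.ndarray  # uint8, index 1..T

    @classmethod
    def from_resights(cls, id, species, f, resight_occasions, T) -> "AdultEncounterHistory":
        if not (1 <= f < T):
            raise ValidationError(f"adult {id}: marking occasion f={f} outside 1..T-1")
        seen = np.zeros(T + 1, dtype=np.uint8)
        seen[f] = 1
        for t in resight_occasions:
            if t <= f:
                raise ValidationError(f"adult {id}: sighting at t={t} not after marking f={f}")
            if t > T:
                raise ValidationError(f"adult {id}: sighting at t={t} beyond T={T}")
            seen[t] = 1
        return cls(str(id), species, int(f), seen)

    @property
    def last_seen(self) -> int:
        return int(np.flatnonzero(self.seen).max())


@dataclass
class ChickEncounterRecord:
    """One bird banded as a chick: banding occasion ``t0`` in ``area``, a set
    of live resight occasions, and optionally the occasion at which its band
    was reported after death (the bird died in the interval ending at that
    occasion)."""

    id: str
    area: str
    t0: int
    resights: tuple[int, ...] = ()
    recovery: int | None = None

    def validate(self, config: StudyConfig) -> None:
        T = config.T
        if not (1 <= self.t0 <= T):
            raise ValidationError(f"chick {self.id}: banding occasion {self.t0} outside 1..T")
        if self.area not in config.areas:
            raise ValidationError(f"chick {self.id}: unknown banding area {self.area!r}")
        last = self.t0
        for t in sorted(self.resights):
            a = t - self.t0 + 1  # bookkeeping age at the sighting
            if t <= self.t0:
                raise ValidationError(f"chick {self.id}: resight at t={t} not after banding")
            if a <= 2:
                raise ValidationError(
                    f"chick {self.id}: live sighting at t={t} in the first return "
                    "summer (resight probability is fixed at zero there)"
                )
            if t > T:
                raise ValidationError(f"chick {self.id}: resight at t={t} beyond T")
            cls_ = resight_class_of_age(a)
            lo, hi = config.window(self.area, cls_)
            if not (lo <= t <= hi):
                raise ValidationError(
                    f"chick {self.id}: resight at t={t} (age class {cls_}) outside "
                    f"area-{self.area} window {lo}..{hi}"
                )
            last = t
        if self.recovery is not None:
            if not (last < self.recovery <= T):
                raise ValidationError(
                    f"chick {self.id}: recovery occasion {self.recovery} must lie in "
                    f"({last}, {T}]"
                )


@dataclass
class MRRSufficientStats:
    """Cohort-level summary of the chick MRR data for one banding area.

    ``n[a, b, t]``: birds observed (alive, at the colony) at bookkeeping age
    ``a`` in year ``t`` and next seen alive aged ``b+1``;
    ``d[a, b, t]``: birds recovered dead at age ``b`` whose last live
    observation was at age ``a`` in year ``t``;
    ``v[a, t]``: birds seen alive for the last time at age ``a`` in year
    ``t`` (initial release counts as an observation) and never recovered.

    Arrays are 1-based: shapes ``(A+1, A+1, T+1)`` and ``(A+1, T+1)``.
    """

    area: str
    n: np.ndarray
    d: np.ndarray
    v: np.ndarray

    @classmethod
    def zeros(cls, area: str, A: int, T: int) -> "MRRSufficientStats":
        return cls(
            area,
            np.zeros((A + 1, A + 1, T + 1), dtype=np.int64),
            np.zeros((A + 1, A + 1, T + 1), dtype=np.int64),
            np.zeros((A + 1, T + 1), dtype=np.int64),
        )

    @property
    def A(self) -> int:
        return self.n.shape[0] - 1

    @property
    def T(self) -> int:
        return self.n.shape[2] - 1

    def validate(self) -> None:
        for name, arr in (("n", self.n), ("d", self.d), ("v", self.v)):
            if (arr < 0).any():
                raise ValidationError(f"MRR stats {name}: negative count")
        A = self.A
        a_idx, b_idx = np.meshgrid(np.arange(A + 1), np.arange(A + 1), indexing="ij")
        off = (b_idx < a_idx)[:, :, None] & ((self.n > 0) | (self.d > 0))
        if off.any():
            raise ValidationError("MRR stats: count with b < a")

    def total_birds(self) -> int:
        """Number of distinct encounter histories summarized (every history
        terminates exactly once, in a d or a v cell)."""
        return int(self.d.sum() + self.v.sum())

    def release_cohort_sizes(self) -> np.ndarray:
        """releases[a, t]: birds observed alive at (age a, year t) — each such
        observation opens one multinomial trial."""
        return self.n.sum(axis=1) + self.d.sum(axis=1) + self.v


@dataclass
class SpeciesData:
    """All observed data for one species."""

    counts: CountSeries
    breeding: BreedingSuccessSeries
    adults: list[AdultEncounterHistory] = field(default_factory=list)
    nonbreeding: NonBreedingSeries | None = None
    mrr_stats: dict[str, MRRSufficientStats] | None = None
    chick_records: list[ChickEncounterRecord] | None = None


@dataclass
class DatasetBundle:
    """The community dataset: one SpeciesData per species code."""

    config: StudyConfig
    species: dict[str, SpeciesData]

    def validate(self) -> None:
        T = self.config.T
        for spec in self.config.species:
            if spec.code not in self.species:
                raise ValidationError(f"bundle missing species {spec.code}")
            sd = self.species[spec.code]
            for obj in (sd.counts, sd.breeding):
                if obj.T != T:
                    raise ValidationError(f"species {spec.code}: series length != T")
            for h in sd.adults:
                if len(h.seen) != T + 1:
                    raise ValidationError(f"adult {h.id}: history length != T")
            if spec.murre_like:
                if sd.nonbreeding is not None and sd.nonbreeding.T != T:
                    raise ValidationError("non-breeding series length != T")
                if sd.mrr_stats is None and sd.chick_records is not None:
                    sd.mrr_stats = build_mrr_sufficient_stats(sd.chick_records, self.config)
                if sd.mrr_stats is not None:
                    for st in sd.mrr_stats.values():
                        st.validate()

    def __getitem__(self, code: str) -> SpeciesData:
        return self.species[code]


def build_mrr_sufficient_stats(
    records: list[ChickEncounterRecord], config: StudyConfig
) -> dict[str, MRRSufficientStats]:
    """Summarize raw chick encounter records into per-area n/d/v arrays.

    Each record contributes one observation chain: the release at
    (age 1, t0), then each live resight in turn, closing with either a dead
    recovery (a ``d`` cell) or the final live observation (a ``v`` cell).
    Every pair of successive live observations at (a, t) -> age b+1 increments
    ``n[a, b, t]``.
    """
    A, T = config.A, config.T
    out = {area: MRRSufficientStats.zeros(area, A, T) for area in config.areas}
    for rec in records:
        rec.validate(config)
        st = out[rec.area]
        occasions = [rec.t0] + sorted(rec.resights)
        ages = [t - rec.t0 + 1 for t in occasions]
        if max(ages) > A:
            raise ValidationError(f"chick {rec.id}: age {max(ages)} exceeds A={A}")
        for (a, t), (a2, t2) in zip(
            zip(ages, occasions), zip(ages[1:], occasions[1:])
        ):
            if a2 - a != t2 - t:  # ages derive from years, but guard file input
                raise ValidationError(f"chick {rec.id}: age/year arithmetic broken")
            st.n[a, a2 - 1, t] += 1
        a_last, t_last = ages[-1], occasions[-1]
        if rec.recovery is not None:
            b = rec.recovery - rec.t0  # aged b at the start of the death interval
            if b < a_last or b > A:
                raise ValidationError(
                    f"chick {rec.id}: recovery age {b} inconsistent with last sighting"
                )
            st.d[a_last, b, t_last] += 1
        else:
            st.v[a_last, t_last] += 1
    return out
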