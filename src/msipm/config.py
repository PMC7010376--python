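"""Study design configuration.

The study layout follows a long-term seabird monitoring design: ``T`` annual
occasions, a community of alcid species indexed by single-letter codes
(``R`` razorbill-like, ``P`` puffin-like, ``M`` murre-like), each with its own
median age at first breeding ``d``.  One species (the murre-like one) carries
the extra datasets: non-breeding proportions and a chick mark-resight-recovery
(MRR) study with two banding areas, A and B, where banding in area B stops
part-way through the study.

Occasions are 1-based throughout the package; calendar years appear only in
file I/O.

Age bookkeeping for the chick MRR component
-------------------------------------------
A chick banded at occasion ``t0`` is released at bookkeeping age 1 (``a = 1``
at occasion ``t0``); it has bookkeeping age ``a`` at occasion ``t0 + a - 1``.
Resighting is impossible at bookkeeping ages 1-2 (release occasion and the
first return summer).  The field age-class labels for resight probabilities
("2-year-olds", "3-year-olds", "4-to-5", adults) therefore map to bookkeeping
ages 3, 4, 5-6 and >=7; with banding starting at occasion 1, the earliest
occasion at which each class can occur is 3, 4, 5 and 7 respectively, which is
exactly where the per-class resight windows open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SpeciesSpec",
    "StudyConfig",
    "RESIGHT_CLASSES",
    "resight_class_of_age",
]

# Resight age classes for birds marked as chicks, keyed by field label.
# Values are (lowest bookkeeping age, highest bookkeeping age); None = open.
RESIGHT_CLASSES: dict[str, tuple[int, int | None]] = {
    "p2": (3, 3),
    "p3": (4, 4),
    "p45": (5, 6),
    "pa": (7, None),
}


def resight_class_of_age(a: int) -> str | None:
    """Field age-class label for bookkeeping age ``a`` (None: not resightable)."""
    if a <= 2:
        return None
    if a == 3:
        return "p2"
    if a == 4:
        return "p3"
    if a in (5, 6):
        return "p45"
    return "pa"


@dataclass(frozen=True)
class SpeciesSpec:
    """One species of the breeding community.

    Parameters
    ----------
    code:
        Single-letter tag used in data files and parameter names.
    name:
        Human-readable name.
    d:
        Median age at first breeding (years); the lag of the recruitment
        process and the length of the population-initialization window.
    murre_like:
        If True the species carries the non-breeding dataset and the chick
        MRR dataset, and its population model uses the fully age-structured
        recruit rate B*rho*s1*s2*s35^3*F5*F6*s_a/2.  Otherwise recruits
        follow the combined-juvenile-survival rate rho*phi_c*s_a/2.
    count_years:
        Occasions with breeding-pair counts, or None for every year.
    sigma_x_upper:
        Upper bound of the uniform prior for the count observation SD.
    """

    code: str
    name: str
    d: int
    murre_like: bool = False
    count_years: tuple[int, ...] | None = None
    sigma_x_upper: float = 5000.0


@dataclass(frozen=True)
class StudyConfig:
    """Global design of the study: occasions, species set, MRR windows."""

    T: int
    species: tuple[SpeciesSpec, ...]
    first_year: int = 1984
    A: int | None = None  # max tracked bookkeeping age for chick MRR; default T
    areaB_last_banding_t: int | None = None
    # per-area, per-class resight windows (first occasion, last occasion)
    resight_windows: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("study needs at least two occasions")
        codes = [s.code for s in self.species]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes")
        for s in self.species:
            if not (1 <= s.d < self.T):
                raise ValueError(
                    f"species {s.code}: age at first breeding d={s.d} must be in [1, T)"
                )
            if s.count_years is not None:
                bad = [t for t in s.count_years if not (1 <= t <= self.T)]
                if bad:
                    raise ValueError(f"species {s.code}: count years {bad} outside 1..T")
        if self.A is None:
            object.__setattr__(self, "A", self.T)
        if self.has_mrr_species and not self.resight_windows:
            object.__setattr__(self, "resight_windows", self._default_windows())
        for area, wins in self.resight_windows.items():
            for cls, (lo, hi) in wins.items():
                if hi > self.T:
                    raise ValueError(
                        f"area {area} window {cls} ends at {hi} > T={self.T}"
                    )

    # -- species access -------------------------------------------------
    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(s.code for s in self.species)

    def species_by_code(self, code: str) -> SpeciesSpec:
        for s in self.species:
            if s.code == code:
                return s
        raise KeyError(f"no species with code {code!r}")

    @property
    def mrr_species(self) -> SpeciesSpec | None:
        for s in self.species:
            if s.murre_like:
                return s
        return None

    @property
    def has_mrr_species(self) -> bool:
        return self.mrr_species is not None

    # -- window construction --------------------------------------------
    def _default_windows(self) -> dict[str, dict[str, tuple[int, int]]]:
        """Area-A windows span each class's earliest occasion to T.  Area-B
        windows close a fixed number of occasions after the last area-B
        banding (the time for the final cohort to age through the class:
        +3/+4/+6 occasions for the 2-, 3- and 4-to-5-year classes), adults to T.
        """
        T = self.T
        last_b = self.areaB_last_banding_t
        areaA = {"p2": (3, T), "p3": (4, T), "p45": (5, T), "pa": (7, T)}
        out = {"A": areaA}
        if last_b is not None:
            out["B"] = {
                "p2": (3, min(T, last_b + 3)),
                "p3": (4, min(T, last_b + 4)),
                "p45": (5, min(T, last_b + 6)),
                "pa": (7, T),
            }
        return out

    def window(self, area: str, cls: str) -> tuple[int, int]:
        return self.resight_windows[area][cls]

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(sorted(self.resight_windows))

    def last_banding_t(self, area: str) -> int:
        """Last occasion at which chicks are banded in ``area`` (banding at T
        is pointless: no resight or recovery could follow within the study)."""
        if area == "B" and self.areaB_last_banding_t is not None:
            return min(self.areaB_last_banding_t, self.T - 1)
        return self.T - 1

    # -- canned designs ---------------------------------------------------
    @staticmethod
    def full_study() -> "StudyConfig":
        """The 26-year three-species design: razorbill (d=5), puffin (d=7,
        sparse counts), murre (d=6, non-breeding + chick MRR, area-B banding
        until occasion 14)."""
        return StudyConfig(
            T=26,
            first_year=1984,
            species=(
                SpeciesSpec("R", "razorbill", d=5),
                SpeciesSpec(
                    "P",
                    "puffin",
                    d=7,
                    count_years=(1, 6, 9, 15, 20, 25, 26),
                    sigma_x_upper=15000.0,
                ),
                SpeciesSpec("M", "murre", d=6, murre_like=True),
            ),
            areaB_last_banding_t=14,
        )

    @staticmethod
    def reduced(T: int = 15) -> "StudyConfig":
        """Desk-scale analogue of the full design with the same species
        structure; area-B banding stops a proportional way through."""
        last_b = max(2, round(T * 14 / 26))
        # seven count years for the sparse species: two early anchors for the
        # initialization window, then widely spaced years ending in a pair
        frac = [0.0, 0.2, 0.5, 0.72, 0.86, 0.93, 1.0]
        years = []
        for f in frac:
            t = 1 + round(f * (T - 1))
            while t in years:
                t += 1
            if t <= T:
                years.append(t)
        puffin_years = tuple(sorted(years))
        return StudyConfig(
            T=T,
            first_year=1984,
            species=(
                SpeciesSpec("R", "razorbill", d=5),
                SpeciesSpec(
                    "P", "puffin", d=7, count_years=puffin_years, sigma_x_upper=15000.0
                ),
                SpeciesSpec("M", "murre", d=6, murre_like=True),
            ),
            areaB_last_banding_t=last_b,
        )

    def with_species(self, *codes: str) -> "StudyConfig":
        """Restrict the design to a subset of its species."""
        keep = tuple(s for s in self.species if s.code in codes)
        missing = set(codes) - {s.code for s in keep}
        if missing:
            raise KeyError(f"unknown species codes {sorted(missing)}")
        windows = self.resight_windows if any(s.murre_like for s in keep) else {}
        return replace(self, species=keep, resight_windows=windows)
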