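"""Delimited-text input/output for community datasets and fit results.

File schemas (calendar years in files, 1-based occasions in memory):

* ``counts.csv``: species, year, pairs (blank = not counted)
* ``breeding_success.csv``: species, year, monitored, fledged
* ``nonbreeding.csv``: year, monitored, bred
* ``adult_histories.csv``: species, id, mark_year, then one 0/1 column per
  study year (``y1984``, ...)
* ``chick_records.csv``: id, area, band_year, resight_years
  (semicolon-separated), recovery_year (blank allowed)
* ``mrr_nd.csv`` / ``mrr_v.csv``: long-format sufficient statistics
  (area, a, b, t, n, d) and (area, a, t, v)

``read_bundle`` prefers raw chick records and builds the sufficient
statistics; if only the long-format statistic files are present they are read
directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .data import (
    AdultEncounterHistory,
    BreedingSuccessSeries,
    ChickEncounterRecord,
    CountSeries,
    DatasetBundle,
    MRRSufficientStats,
    NonBreedingSeries,
    SpeciesData,
    ValidationError,
)

__all__ = ["read_bundle", "write_bundle", "write_results"]

FILES = {
    "counts": "counts.csv",
    "breeding_success": "breeding_success.csv",
    "nonbreeding": "nonbreeding.csv",
    "adult_histories": "adult_histories.csv",
    "chick_records": "chick_records.csv",
    "mrr_nd": "mrr_nd.csv",
    "mrr_v": "mrr_v.csv",
}


def _year_to_t(year: int, config: StudyConfig, fname: str, row: int) -> int:
    t = int(year) - config.first_year + 1
    if not (1 <= t <= config.T):
        raise ValidationError(f"{fname}, row {row}: year {year} outside the study")
    return t


def read_bundle(path, config: StudyConfig) -> DatasetBundle:
    """Read and validate a community dataset from a directory (or a mapping
    of file keys to paths).  Validation failures name the file and row."""
    if isinstance(path, (str, Path)):
        base = Path(path)
        paths = {k: base / v for k, v in FILES.items()}
    else:
        paths = {k: Path(v) for k, v in path.items()}
    T = config.T

    def load(key, required=True, **kw):
        p = paths.get(key)
        if p is None or not p.exists():
            if required:
                raise ValidationError(f"missing required input file: {FILES[key]}")
            return None
        return pd.read_csv(p, **kw)

    counts = load("counts")
    bs = load("breeding_success")
    species: dict[str, SpeciesData] = {}
    for sp in config.species:
        S = sp.code
        x = np.full(T, np.nan)
        for i, row in counts[counts["species"] == S].iterrows():
            t = _year_to_t(row["year"], config, FILES["counts"], i)
            if not pd.isna(row["pairs"]):
                if row["pairs"] < 0:
                    raise ValidationError(f"{FILES['counts']}, row {i}: negative count")
                x[t - 1] = float(row["pairs"])
        E = np.zeros(T, dtype=int)
        C = np.zeros(T, dtype=int)
        for i, row in bs[bs["species"] == S].iterrows():
            t = _year_to_t(row["year"], config, FILES["breeding_success"], i)
            E[t - 1] = int(row["monitored"])
            C[t - 1] = int(row["fledged"])
            if C[t - 1] > E[t - 1] or C[t - 1] < 0:
                raise ValidationError(
                    f"{FILES['breeding_success']}, row {i}: fledged outside [0, monitored]"
                )
        species[S] = SpeciesData(
            counts=CountSeries.from_values(x, T),
            breeding=BreedingSuccessSeries.from_values(E, C, T),
        )

    ah = load("adult_histories", required=False)
    if ah is not None:
        ycols = [c for c in ah.columns if c.startswith("y")]
        for i, row in ah.iterrows():
            S = row["species"]
            if S not in species:
                raise ValidationError(f"{FILES['adult_histories']}, row {i}: unknown species {S}")
            f = _year_to_t(row["mark_year"], config, FILES["adult_histories"], i)
            resights = []
            for c in ycols:
                if int(row[c]) == 1:
                    t = _year_to_t(int(c[1:]), config, FILES["adult_histories"], i)
                    if t != f:
                        resights.append(t)
            try:
                species[S].adults.append(
                    AdultEncounterHistory.from_resights(row["id"], S, f, resights, T)
                )
            except ValidationError as e:
                raise ValidationError(f"{FILES['adult_histories']}, row {i}: {e}") from e

    murre = config.mrr_species
    if murre is not None:
        nb = load("nonbreeding", required=False)
        if nb is not None:
            xim = np.zeros(T, dtype=int)
            xib = np.zeros(T, dtype=int)
            for i, row in nb.iterrows():
                t = _year_to_t(row["year"], config, FILES["nonbreeding"], i)
                xim[t - 1] = int(row["monitored"])
                xib[t - 1] = int(row["bred"])
                if xib[t - 1] > xim[t - 1]:
                    raise ValidationError(
                        f"{FILES['nonbreeding']}, row {i}: bred > monitored"
                    )
            species[murre.code].nonbreeding = NonBreedingSeries.from_values(xim, xib, T)
        cr = load("chick_records", required=False, dtype={"resight_years": str})
        if cr is not None:
            recs = []
            for i, row in cr.iterrows():
                t0 = _year_to_t(row["band_year"], config, FILES["chick_records"], i)
                rs = row.get("resight_years")
                resights = tuple(
                    _year_to_t(int(y), config, FILES["chick_records"], i)
                    for y in str(rs).split(";")
                    if y and not pd.isna(rs) and str(rs) != "nan" and y.strip()
                )
                rec_year = row.get("recovery_year")
                recovery = (
                    None if pd.isna(rec_year) else _year_to_t(int(rec_year), config,
                                                              FILES["chick_records"], i)
                )
                rec = ChickEncounterRecord(str(row["id"]), row["area"], t0, resights, recovery)
                try:
                    rec.validate(config)
                except ValidationError as e:
                    raise ValidationError(f"{FILES['chick_records']}, row {i}: {e}") from e
                recs.append(rec)
            species[murre.code].chick_records = recs
        else:
            nd = load("mrr_nd", required=False)
            vv = load("mrr_v", required=False)
            if nd is not None and vv is not None:
                stats = {
                    area: MRRSufficientStats.zeros(area, config.A, T)
                    for area in config.areas
                }
                for i, row in nd.iterrows():
                    st = stats[row["area"]]
                    st.n[int(row["a"]), int(row["b"]), int(row["t"])] = int(row["n"])
                    st.d[int(row["a"]), int(row["b"]), int(row["t"])] = int(row["d"])
                for i, row in vv.iterrows():
                    stats[row["area"]].v[int(row["a"]), int(row["t"])] = int(row["v"])
                for st in stats.values():
                    st.validate()
                species[murre.code].mrr_stats = stats

    bundle = DatasetBundle(config, species)
    bundle.validate()
    return bundle


def write_bundle(bundle: DatasetBundle, out_dir) -> None:
    """Write a bundle back to the CSV schemas (inverse of ``read_bundle``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    T, y0 = cfg.T, cfg.first_year
    years = [y0 + t - 1 for t in range(1, T + 1)]

    rows = []
    bs_rows = []
    for sp in cfg.species:
        S = sp.code
        sd = bundle[S]
        for t in range(1, T + 1):
            v = sd.counts.x[t]
            rows.append({"species": S, "year": years[t - 1],
                         "pairs": "" if np.isnan(v) else v})
            bs_rows.append({"species": S, "year": years[t - 1],
                            "monitored": sd.breeding.E[t], "fledged": sd.breeding.C[t]})
    pd.DataFrame(rows).to_csv(out / FILES["counts"], index=False)
    pd.DataFrame(bs_rows).to_csv(out / FILES["breeding_success"], index=False)

    ah_rows = []
    for sp in cfg.species:
        for h in bundle[sp.code].adults:
            row = {"species": sp.code, "id": h.id, "mark_year": y0 + h.f - 1}
            for t in range(1, T + 1):
                row[f"y{years[t - 1]}"] = int(h.seen[t]) if t != h.f else int(h.seen[t])
            ah_rows.append(row)
    if ah_rows:
        pd.DataFrame(ah_rows).to_csv(out / FILES["adult_histories"], index=False)

    murre = cfg.mrr_species
    if murre is not None:
        sd = bundle[murre.code]
        if sd.nonbreeding is not None:
            pd.DataFrame(
                {
                    "year": years,
                    "monitored": sd.nonbreeding.xi_m[1:],
                    "bred": sd.nonbreeding.xi_b[1:],
                }
            ).to_csv(out / FILES["nonbreeding"], index=False)
        if sd.chick_records is not None:
            cr_rows = [
                {
                    "id": r.id,
                    "area": r.area,
                    "band_year": y0 + r.t0 - 1,
                    "resight_years": ";".join(str(y0 + t - 1) for t in sorted(r.resights)),
                    "recovery_year": "" if r.recovery is None else y0 + r.recovery - 1,
                }
                for r in sd.chick_records
            ]
            pd.DataFrame(cr_rows).to_csv(out / FILES["chick_records"], index=False)
        if sd.mrr_stats is not None:
            nd_rows, v_rows = [], []
            for area, st in sd.mrr_stats.items():
                a, b, t = np.nonzero(st.n + st.d)
                for ai, bi, ti in zip(a, b, t):
                    nd_rows.append({"area": area, "a": ai, "b": bi, "t": ti,
                                    "n": st.n[ai, bi, ti], "d": st.d[ai, bi, ti]})
                a, t = np.nonzero(st.v)
                for ai, ti in zip(a, t):
                    v_rows.append({"area": area, "a": ai, "t": ti, "v": st.v[ai, ti]})
            pd.DataFrame(nd_rows, columns=["area", "a", "b", "t", "n", "d"]).to_csv(
                out / FILES["mrr_nd"], index=False
            )
            pd.DataFrame(v_rows, columns=["area", "a", "t", "v"]).to_csv(
                out / FILES["mrr_v"], index=False
            )


def write_results(result, out_dir) -> None:
    """Persist a fit: parameter summary CSV, abundance trajectory CSV, run
    metadata JSON and the raw draws (.npz with a JSON dimension manifest)."""
    from .mcmc import summarize_posterior

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize_posterior(result)
    summary.to_csv(out / "params_summary.csv")

    cfg = result.config
    ab_rows = []
    for S in result.latent_species:
        for t in range(1, cfg.T + 1):
            row = summary.loc[f"N_{S}[{t}]"]
            ab_rows.append(
                {"species": S, "t": t, "year": cfg.first_year + t - 1,
                 "median": row["median"], "q2.5": row["q2.5"], "q97.5": row["q97.5"]}
            )
    pd.DataFrame(ab_rows).to_csv(out / "abundance.csv", index=False)

    worst_name, worst = result.worst_rhat()
    meta = {
        "seed": result.seed,
        "n_chains": result.n_chains,
        "n_iter": result.n_iter,
        "warmup": result.warmup,
        "thin": result.thin,
        "worst_rhat": {"parameter": worst_name, "value": worst},
        "acceptance": result.acceptance,
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)

    np.savez_compressed(out / "draws.npz", **result.draws)
    manifest = {
        "dims": {name: ["chain", "draw", "element"] for name in result.draws},
        "labels": {k: list(v) for k, v in result.labels.items()},
        "groups": result.groups,
    }
    with open(out / "draws_manifest.json", "w") as fh:
        json.dump(manifest, fh)
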