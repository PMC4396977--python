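"""Delimited-text readers/writers for cohort, tract, and prevalence tables,
plus CSV/GeoJSON result export.

A curated table of 29 published case-control study populations genotyped at
the SLC30A8 rs13266634 locus (21 Asian, 7 European, 1 Mexican Mestizo
cohort) ships with the package; ``load_bundled_cohorts`` returns it.  Cells
whose CC-genotype counts were derived from risk-allele frequencies under
Hardy-Weinberg equilibrium rather than reported directly are flagged
``hwe_derived``, so analyses restricted to explicitly genotyped cohorts can
filter on the flag.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .geo import CountySummary, TractRiskProfile
from .par import EthnicityRisk
from .records import (
    CCSource,
    CohortRecord,
    CohortValidationError,
    PrevalenceEntry,
    TractDemographics,
)

_COHORT_COLUMNS = {
    "cohort_id",
    "group",
    "n_cases",
    "cc_cases",
    "raf_cases",
    "n_controls",
    "cc_controls",
    "raf_controls",
    "cc_source_cases",
    "cc_source_controls",
}


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_source(v) -> CCSource | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return CCSource(str(v))


def read_cohorts(path: str | Path, delimiter: str = ",") -> list[CohortRecord]:
    """Read a cohort table into validated :class:`CohortRecord` objects.

    Rows violating an invariant — in particular rows lacking both a CC
    count and a risk-allele frequency in either arm, which carry inadequate
    information to compute genotype frequencies — are rejected collectively
    with a per-row report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    unknown = set(df.columns) - _COHORT_COLUMNS
    if unknown:
        raise CohortValidationError(f"unrecognised columns {sorted(unknown)}")
    required = {"cohort_id", "group", "n_cases", "n_controls"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"missing required columns {sorted(missing)}")
    records: list[CohortRecord] = []
    errors: list[tuple[int | None, str]] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CohortRecord(
                    cohort_id=str(row["cohort_id"]),
                    group=str(row["group"]),
                    n_cases=int(row["n_cases"]),
                    n_controls=int(row["n_controls"]),
                    cc_cases=_opt_int(row.get("cc_cases")),
                    cc_controls=_opt_int(row.get("cc_controls")),
                    raf_cases=_opt_float(row.get("raf_cases")),
                    raf_controls=_opt_float(row.get("raf_controls")),
                    cc_source_cases=_opt_source(row.get("cc_source_cases")),
                    cc_source_controls=_opt_source(row.get("cc_source_controls")),
                )
            )
        except (CohortValidationError, ValueError) as exc:
            errors.append((int(idx), str(exc)))
    if errors:
        report = "; ".join(f"row {i}: {msg}" for i, msg in errors)
        raise CohortValidationError(f"{len(errors)} invalid row(s): {report}", errors)
    return records


def load_bundled_cohorts() -> list[CohortRecord]:
    """The packaged 29-cohort rs13266634 case-control table."""
    with resources.as_file(
        resources.files("parscreen").joinpath("data/slc30a8_cohorts.csv")
    ) as p:
        return read_cohorts(p)


def write_cohorts(recs: Sequence[CohortRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write cohort records in the same dialect ``read_cohorts`` accepts."""
    rows = []
    for r in recs:
        rows.append(
            {
                "cohort_id": r.cohort_id,
                "group": r.group,
                "n_cases": r.n_cases,
                "cc_cases": r.cc_cases,
                "raf_cases": r.raf_cases,
                "n_controls": r.n_controls,
                "cc_controls": r.cc_controls,
                "raf_controls": r.raf_controls,
                "cc_source_cases": r.cc_source_cases.value if r.cc_source_cases else None,
                "cc_source_controls": r.cc_source_controls.value if r.cc_source_controls else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_tracts(path: str | Path, delimiter: str = ",") -> list[TractDemographics]:
    """Read a tract demographics table (tract_id, optional county_id, one
    column per subgroup).  Duplicate tract IDs are rejected; all-zero
    population tracts are accepted with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"tract_id": str, "county_id": str})
    if "tract_id" not in df.columns:
        raise ValueError("missing tract_id column")
    dupes = df["tract_id"][df["tract_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate tract_id(s): {dupes}")
    subgroup_cols = [c for c in df.columns if c not in ("tract_id", "county_id")]
    tracts = []
    for _, row in df.iterrows():
        dem = TractDemographics(
            tract_id=row["tract_id"],
            county_id=row["county_id"] if "county_id" in df.columns else "",
            populations={c: float(row[c]) for c in subgroup_cols},
        )
        if dem.is_zero_population:
            warnings.warn(f"tract {dem.tract_id} has zero population", stacklevel=2)
        tracts.append(dem)
    return tracts


def write_tracts(tracts: Sequence[TractDemographics], path: str | Path, delimiter: str = ",") -> None:
    subgroups = sorted({g for t in tracts for g in t.populations})
    rows = [
        {"tract_id": t.tract_id, "county_id": t.county_id,
         **{g: t.populations.get(g, 0) for g in subgroups}}
        for t in tracts
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_prevalence(path: str | Path, delimiter: str = ",") -> list[PrevalenceEntry]:
    """Read a subgroup prevalence table (subgroup, prevalence, optional
    weight_n), fractions as decimals."""
    df = pd.read_csv(path, sep=delimiter)
    return [
        PrevalenceEntry(
            subgroup=str(r["subgroup"]),
            prevalence=float(r["prevalence"]),
            weight_n=_opt_float(r.get("weight_n")),
        )
        for _, r in df.iterrows()
    ]


def _profile_row(t: TractRiskProfile, subgroups: Sequence[str]) -> dict[str, Any]:
    row: dict[str, Any] = {
        "tract_id": t.tract_id,
        "county_id": t.county_id,
        "total_pop": t.total_pop,
        "total_par": t.total_par,
        "quintile": t.quintile,
        "at_risk_pct": t.at_risk_pct,
        "at_risk_count": t.at_risk_count,
        "at_risk_low": t.at_risk_bounds[0] if t.at_risk_bounds else None,
        "at_risk_high": t.at_risk_bounds[1] if t.at_risk_bounds else None,
    }
    for g in subgroups:
        row[f"contrib_{g}"] = t.contributions.get(g)
    return row


def write_tract_profiles(
    profiles: Sequence[TractRiskProfile],
    path: str | Path,
    format: str = "csv",
    geometry: Mapping[str, dict] | None = None,
    delimiter: str = ",",
) -> None:
    """Export tract risk profiles as CSV or a GeoJSON FeatureCollection.

    GeoJSON export requires a ``geometry`` mapping of tract_id to GeoJSON
    geometry dicts; tracts absent from the mapping are emitted with a null
    geometry and a warning.  Numeric fields round-trip at full precision.
    """
    subgroups = sorted({g for t in profiles for g in t.contributions})
    if format == "csv":
        rows = [_profile_row(t, subgroups) for t in profiles]
        pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, float_format="%.17g")
        return
    if format == "geojson":
        if geometry is None:
            raise ValueError("geojson export requires a geometry mapping keyed by tract_id")
        features = []
        for t in profiles:
            geom = geometry.get(t.tract_id)
            if geom is None:
                warnings.warn(f"no geometry for tract {t.tract_id}; emitting null", stacklevel=2)
            features.append(
                {
                    "type": "Feature",
                    "geometry": geom,
                    "properties": _profile_row(t, subgroups),
                }
            )
        collection = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(collection))
        return
    raise ValueError(f"unknown format {format!r}")


def read_tract_profiles(path: str | Path, delimiter: str = ",") -> list[TractRiskProfile]:
    """Read back a CSV written by :func:`write_tract_profiles`."""
    df = pd.read_csv(
        path, sep=delimiter, dtype={"tract_id": str, "county_id": str},
        float_precision="round_trip",
    )
    contrib_cols = [c for c in df.columns if c.startswith("contrib_")]
    out = []
    for _, r in df.iterrows():
        q = _opt_float(r.get("quintile"))
        low, high = _opt_float(r.get("at_risk_low")), _opt_float(r.get("at_risk_high"))
        out.append(
            TractRiskProfile(
                tract_id=r["tract_id"],
                county_id=r["county_id"],
                total_pop=float(r["total_pop"]),
                total_par=_opt_float(r.get("total_par")),
                contributions={
                    c[len("contrib_"):]: v
                    for c in contrib_cols
                    if (v := _opt_float(r.get(c))) is not None
                },
                quintile=int(q) if q is not None else None,
                at_risk_pct=_opt_float(r.get("at_risk_pct")),
                at_risk_count=_opt_float(r.get("at_risk_count")),
                at_risk_bounds=(low, high) if low is not None and high is not None else None,
            )
        )
    return out


def write_ethnicity_risks(risks: Iterable[EthnicityRisk], path: str | Path) -> None:
    """Summary CSV: group, E, OR with CI, PAR with CI, basis."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["group", "e_cc", "or", "or_low", "or_high", "par", "par_low", "par_high",
             "basis", "n_cohorts", "significant"]
        )
        for r in risks:
            w.writerow(
                [r.group, repr(r.e_cc), repr(r.or_), repr(r.or_ci[0]), repr(r.or_ci[1]),
                 repr(r.par), repr(r.par_ci[0]), repr(r.par_ci[1]),
                 r.basis, r.n_cohorts, r.significant]
            )


def write_county_summaries(summaries: Iterable[CountySummary], path: str | Path) -> None:
    """County table mirroring the hotspot report: class-5 tract count and
    population, county total population, and class-5 population share."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["county_id", "n_q5_tracts", "q5_pop", "total_pop", "pct_in_q5", "hotspot"])
        for s in summaries:
            w.writerow(
                [s.county_id, s.n_q5_tracts, repr(s.q5_pop), repr(s.total_pop),
                 repr(s.pct_in_q5), s.hotspot]
            )
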