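"""Census-tract risk aggregation, quintile hotspot classification, and
county summaries.

Each tract's total PAR is the mean of the subgroup PARs weighted by the
tract's subgroup populations; subgroups without a risk estimate are left
out of both numerator and denominator, so the "total" population covers
only subgroups with a PAR.  Tracts are classified into equal-count
quintiles of total PAR (tracts as units, unweighted by population; the
highest-PAR fifth is class 5), and a county is a hotspot when strictly more
than a threshold share (default 25%) of its included population lives in
class-5 tracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .par import EthnicityRisk
from .records import PrevalenceEntry, TractDemographics


@dataclass(frozen=True)
class TractRiskProfile:
    """Per-tract weighted PAR, subgroup contributions, and quintile class."""

    tract_id: str
    county_id: str
    total_pop: float
    total_par: float | None
    contributions: Mapping[str, float] = field(default_factory=dict)
    quintile: int | None = None
    at_risk_pct: float | None = None
    at_risk_count: float | None = None
    at_risk_bounds: tuple[float, float] | None = None


@dataclass(frozen=True)
class CountySummary:
    """Highest-quintile tract counts and population shares for one county."""

    county_id: str
    n_q5_tracts: int
    q5_pop: float
    total_pop: float
    pct_in_q5: float
    hotspot: bool


def _included(dem: TractDemographics, risks: Mapping[str, EthnicityRisk]):
    return {g: p for g, p in dem.populations.items() if g in risks}


def tract_total_par(
    dem: TractDemographics, risks: Mapping[str, EthnicityRisk]
) -> float | None:
    """Population-weighted mean PAR over the tract's included subgroups.

    Returns None when the included population is zero (the tract cannot be
    classified).
    """
    pops = _included(dem, risks)
    total = sum(pops.values())
    if total == 0:
        return None
    return sum(p * risks[g].par for g, p in pops.items()) / total


def subgroup_contributions(
    dem: TractDemographics, risks: Mapping[str, EthnicityRisk]
) -> dict[str, float]:
    """Each subgroup's share of the tract total PAR: pop·PAR over total
    included population.  Contributions sum to the tract total PAR."""
    pops = _included(dem, risks)
    total = sum(pops.values())
    if total == 0:
        return {g: 0.0 for g in pops}
    return {g: p * risks[g].par / total for g, p in pops.items()}


def quintile_classify(
    values: Sequence[tuple[str, float]]
) -> dict[str, int]:
    """Equal-count quintile classes 1-5 from (tract_id, total_par) pairs.

    Thresholds sit at the 20/40/60/80th percentiles of the tract values
    (tracts as units); equal values always share a class, and a value equal
    to a threshold takes the lower class.  Class 5 holds the highest values.
    Fewer than 5 distinct values triggers a degenerate-classification
    warning and classes collapse.
    """
    if len(values) < 5:
        warnings.warn(
            f"only {len(values)} tracts: quintile classification is degenerate",
            stacklevel=2,
        )
    vals = np.asarray([v for _, v in values], dtype=float)
    if len(set(vals.tolist())) < 5:
        warnings.warn(
            "fewer than 5 distinct values: quintile classes collapse", stacklevel=2
        )
    thresholds = np.percentile(vals, [20, 40, 60, 80]) if len(vals) else np.array([])
    classes = 1 + np.searchsorted(thresholds, vals, side="left")
    return {tid: int(c) for (tid, _), c in zip(values, classes)}


def profile_tracts(
    tracts: Iterable[TractDemographics],
    risks: Mapping[str, EthnicityRisk],
    prevalence: Sequence[PrevalenceEntry] | None = None,
) -> list[TractRiskProfile]:
    """Full tract-level pipeline: weighted PAR, contributions, quintile
    classes, and (when prevalence is given) at-risk population estimates.

    Zero-included-population tracts appear in the output with a null PAR
    and null quintile; they are excluded from classification.
    """
    profiles: list[TractRiskProfile] = []
    interim = []
    for dem in tracts:
        pops = _included(dem, risks)
        total = sum(pops.values())
        tpar = tract_total_par(dem, risks)
        contrib = subgroup_contributions(dem, risks)
        risk = at_risk(dem, risks, prevalence) if prevalence is not None else None
        interim.append((dem, total, tpar, contrib, risk))
    classifiable = [(d.tract_id, tpar) for d, _, tpar, _, _ in interim if tpar is not None]
    classes = quintile_classify(classifiable) if classifiable else {}
    for dem, total, tpar, contrib, risk in interim:
        at_pct = at_cnt = at_bounds = None
        if risk is not None:
            at_pct, at_cnt, at_bounds = risk
        profiles.append(
            TractRiskProfile(
                tract_id=dem.tract_id,
                county_id=dem.county_id,
                total_pop=total,
                total_par=tpar,
                contributions=contrib,
                quintile=classes.get(dem.tract_id),
                at_risk_pct=at_pct,
                at_risk_count=at_cnt,
                at_risk_bounds=at_bounds,
            )
        )
    return profiles


def county_summaries(
    tracts: Sequence[TractRiskProfile],
    hotspot_threshold: float = 0.25,
    include_all: bool = False,
) -> list[CountySummary]:
    """Per-county highest-quintile (class 5) tract counts and population
    shares.

    County total population is the sum of included-subgroup populations over
    all the county's tracts.  A county is a hotspot when its class-5
    population share strictly exceeds ``hotspot_threshold``.  By default
    only counties with at least one class-5 tract are returned; pass
    ``include_all=True`` for every county.
    """
    by_county: dict[str, list[TractRiskProfile]] = {}
    for t in tracts:
        by_county.setdefault(t.county_id, []).append(t)
    out = []
    for county_id in sorted(by_county):
        members = by_county[county_id]
        q5 = [t for t in members if t.quintile == 5]
        q5_pop = sum(t.total_pop for t in q5)
        total_pop = sum(t.total_pop for t in members)
        pct = q5_pop / total_pop if total_pop > 0 else 0.0
        if not include_all and not q5:
            continue
        out.append(
            CountySummary(
                county_id=county_id,
                n_q5_tracts=len(q5),
                q5_pop=q5_pop,
                total_pop=total_pop,
                pct_in_q5=pct,
                hotspot=pct > hotspot_threshold,
            )
        )
    out.sort(key=lambda s: s.pct_in_q5, reverse=True)
    return out


def at_risk(
    dem: TractDemographics,
    risks: Mapping[str, EthnicityRisk],
    prevalence: Sequence[PrevalenceEntry],
) -> tuple[float, float, tuple[float, float]]:
    """Share and count of the tract population at attributable risk.

    Combines subgroup disease prevalence with subgroup PAR: the expected
    number of attributable cases is pop·prevalence·PAR summed over included
    subgroups, and the fraction is that count over the included population.
    Bounds propagate each subgroup's PAR confidence interval.
    Returns (fraction, count, (count_low, count_high)); zero included
    population yields (0, 0, (0, 0)).
    """
    prev = {e.subgroup: e.prevalence for e in prevalence}
    pops = _included(dem, risks)
    missing = [g for g in pops if g not in prev]
    if missing:
        raise KeyError(f"no prevalence entry for subgroup(s) {missing}")
    total = sum(pops.values())
    if total == 0:
        return 0.0, 0.0, (0.0, 0.0)
    count = sum(p * prev[g] * risks[g].par for g, p in pops.items())
    low = sum(p * prev[g] * risks[g].par_ci[0] for g, p in pops.items())
    high = sum(p * prev[g] * risks[g].par_ci[1] for g, p in pops.items())
    return count / total, count, (low, high)


def weighted_prevalence(entries: Sequence[PrevalenceEntry]) -> float:
    """N-weighted mean prevalence across entries, Σ prevᵢ·nᵢ / Σ nᵢ."""
    if not entries:
        raise ValueError("no prevalence entries")
    for e in entries:
        if e.weight_n is None:
            raise ValueError(f"{e.subgroup}: weight_n required for weighting")
    total_w = sum(e.weight_n for e in entries)
    if total_w == 0:
        raise ValueError("zero total weight")
    return sum(e.prevalence * e.weight_n for e in entries) / total_w
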