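"""Synthetic cohort tables and census geographies with known ground truth.

``simulate_cohorts`` draws case-control studies around a known true odds
ratio on the dominant (CC vs rest) scale: control-arm CC probability is
raf² under Hardy-Weinberg equilibrium, the case-arm probability is solved
from the 2x2 odds identity so the simulated OR is exactly the target in
expectation, and optional between-study variance τ² perturbs each cohort's
log OR.  ``simulate_census`` draws county/tract population mixtures from a
Dirichlet model and can plant hotspot counties whose tracts are enriched
for the highest-risk subgroup, returning the planted labels so end-to-end
hotspot recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import CCSource, CohortRecord, TractDemographics


@dataclass(frozen=True)
class CohortSimConfig:
    """Generator settings for synthetic case-control cohorts.

    ``true_or`` is the common dominant-model odds ratio; ``control_raf``
    the typical control risk-allele frequency; ``raf_jitter`` the SD of
    between-cohort RAF variation on the logit scale; ``tau2`` the
    between-study variance of the log OR (0 for a fixed-effect truth).
    """

    true_or: float = 1.2
    control_raf: float = 0.55
    n_cohorts: int = 20
    size_range: tuple[int, int] = (500, 2500)
    raf_jitter: float = 0.15
    tau2: float = 0.0
    group: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not 0.0 < self.control_raf < 1.0:
            raise ValueError("control_raf must be in (0, 1)")
        if self.size_range[0] < 20:
            raise ValueError("per-arm sizes must be at least 20")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


@dataclass(frozen=True)
class CensusSimConfig:
    """Generator settings for a synthetic census geography.

    ``subgroup_mix`` gives Dirichlet concentrations for tract subgroup
    shares; counties listed in ``planted_hotspots`` have ``boost_subgroup``
    concentration multiplied by ``boost_factor``, concentrating the
    highest-PAR subgroup there.
    """

    n_counties: int = 12
    tracts_per_county: tuple[int, int] = (8, 16)
    pop_range: tuple[int, int] = (1200, 8000)
    subgroup_mix: Mapping[str, float] = field(
        default_factory=lambda: {"european": 6.0, "asian": 2.0, "mexican": 1.5}
    )
    planted_hotspots: tuple[int, ...] = ()
    boost_subgroup: str = "mexican"
    boost_factor: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.subgroup_mix.values()):
            raise ValueError("Dirichlet concentrations must be positive")
        if any(not 0 <= i < self.n_counties for i in self.planted_hotspots):
            raise ValueError("planted hotspot index out of range")
        if self.boost_subgroup not in self.subgroup_mix:
            raise ValueError(f"boost subgroup {self.boost_subgroup!r} not in mix")


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def case_cc_probability(p0: float, or_: float) -> float:
    """Case-arm CC probability implied by control probability ``p0`` and a
    dominant-model odds ratio ``or_`` (the 2x2 odds identity)."""
    odds = or_ * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def simulate_cohorts(cfg: CohortSimConfig) -> list[CohortRecord]:
    """Draw ``cfg.n_cohorts`` case-control cohorts; reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.size_range
    n_cases = rng.integers(lo, hi + 1, cfg.n_cohorts)
    n_controls = rng.integers(lo, hi + 1, cfg.n_cohorts)
    rafs = _expit(_logit(cfg.control_raf) + rng.normal(0.0, cfg.raf_jitter, cfg.n_cohorts))
    log_ors = np.log(cfg.true_or) + rng.normal(0.0, np.sqrt(cfg.tau2), cfg.n_cohorts)
    records = []
    for i in range(cfg.n_cohorts):
        p0 = float(rafs[i] ** 2)
        p1 = case_cc_probability(p0, float(np.exp(log_ors[i])))
        cc_controls = int(rng.binomial(n_controls[i], p0))
        cc_cases = int(rng.binomial(n_cases[i], p1))
        records.append(
            CohortRecord(
                cohort_id=f"sim{i:03d}",
                group=cfg.group,
                n_cases=int(n_cases[i]),
                n_controls=int(n_controls[i]),
                cc_cases=cc_cases,
                cc_controls=cc_controls,
                raf_controls=float(rafs[i]),
                cc_source_cases=CCSource.REPORTED,
                cc_source_controls=CCSource.REPORTED,
            )
        )
    return records


def simulate_census(
    cfg: CensusSimConfig,
) -> tuple[list[TractDemographics], list[str]]:
    """Draw a synthetic tract table; returns (tracts, planted county IDs)."""
    rng = np.random.default_rng(cfg.seed)
    subgroups = list(cfg.subgroup_mix)
    base_conc = np.array([cfg.subgroup_mix[g] for g in subgroups], dtype=float)
    tracts: list[TractDemographics] = []
    planted_ids: list[str] = []
    for ci in range(cfg.n_counties):
        county_id = f"{ci:05d}"
        planted = ci in cfg.planted_hotspots
        if planted:
            planted_ids.append(county_id)
        conc = base_conc.copy()
        if planted:
            conc[subgroups.index(cfg.boost_subgroup)] *= cfg.boost_factor
        n_tracts = int(rng.integers(cfg.tracts_per_county[0], cfg.tracts_per_county[1] + 1))
        for ti in range(n_tracts):
            total = int(rng.integers(cfg.pop_range[0], cfg.pop_range[1] + 1))
            shares = rng.dirichlet(conc)
            pops = rng.multinomial(total, shares)
            tracts.append(
                TractDemographics(
                    tract_id=f"{county_id}{ti:06d}",
                    populations={g: int(p) for g, p in zip(subgroups, pops)},
                )
            )
    return tracts, planted_ids
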