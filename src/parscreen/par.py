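"""Levin's population attributable risk per ancestry subgroup.

The population attributable risk (PAR) is the fraction of disease cases in
a population attributable to an exposure — here carriage of the homozygous
risk genotype.  Levin's formula,

    PAR = E·(OR − 1) / (1 + E·(OR − 1)),

takes the exposure frequency E (the pooled CC-genotype frequency) and the
odds ratio OR as an approximation to the relative risk.  PAR is kept as a
fraction throughout; multiply by 100 only for presentation.

Subgroups whose pooled odds ratio is not statistically significant can be
handled three ways (``NonsignificantPolicy``): dropped from downstream
aggregation entirely; retained with their point-estimate OR regardless of
significance; or, most conservatively, every subgroup's PAR evaluated at
the lower 95% confidence bound of its OR, floored at 1 (so non-significant
groups contribute zero attributable risk but remain in the population
denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .genotype import complete_cohort, pooled_cc_frequency
from .meta import PooledEffect, odds_ratio, pool_auto, two_by_two
from .records import CohortRecord


class NonsignificantPolicy(str, Enum):
    """How to treat subgroups whose pooled OR is not significant at 0.05."""

    EXCLUDE = "exclude"
    POINT_ESTIMATE = "point_estimate"
    LOWER_BOUND = "lower_bound"


@dataclass(frozen=True)
class EthnicityRisk:
    """Per-subgroup exposure frequency, odds ratio, and attributable risk."""

    group: str
    e_cc: float
    or_: float
    or_ci: tuple[float, float]
    par: float
    par_ci: tuple[float, float]
    basis: str  # "pooled" or "single-study"
    n_cohorts: int = 1
    significant: bool = True


def levin_par(e_cc: float, or_: float) -> float:
    """Attributable fraction E·(OR−1)/(1+E·(OR−1)); zero iff OR=1 or E=0."""
    if not 0.0 <= e_cc <= 1.0:
        raise ValueError(f"exposure frequency {e_cc} outside [0, 1]")
    if or_ <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_}")
    x = e_cc * (or_ - 1.0)
    return x / (1.0 + x)


def par_interval(e_cc: float, or_ci: tuple[float, float]) -> tuple[float, float]:
    """Levin's formula evaluated at the OR confidence bounds.

    PAR is strictly increasing in OR for fixed E > 0, so mapping the bounds
    through the formula preserves their ordering.
    """
    low, high = or_ci
    if low <= 0 or high <= 0:
        raise ValueError("odds-ratio bounds must be positive")
    if low > high:
        raise ValueError("lower bound exceeds upper bound")
    return levin_par(e_cc, low), levin_par(e_cc, high)


def solve_or(par: float, e_cc: float) -> float:
    """Invert Levin's formula: the OR that yields ``par`` at exposure ``e_cc``."""
    if e_cc <= 0:
        raise ValueError("exposure frequency must be positive to invert")
    if par >= 1:
        raise ValueError("attributable fraction must be below 1")
    return 1.0 + par / (e_cc * (1.0 - par))


def ethnicity_risk(
    recs: Sequence[CohortRecord],
    p_q_threshold: float = 0.10,
    i2_threshold: float = 50.0,
) -> EthnicityRisk:
    """Exposure frequency, pooled OR, and PAR for one subgroup's cohorts.

    Multi-cohort groups are pooled (fixed effect, random-effects fallback on
    heterogeneity); a single-cohort group uses its own study OR.  The PAR is
    always computed from the unrounded OR.
    """
    if not recs:
        raise ValueError("no cohorts supplied")
    completed = [complete_cohort(r) for r in recs]
    freq = pooled_cc_frequency(completed)
    if len(completed) == 1:
        eff = odds_ratio(two_by_two(completed[0]))
        or_, ci = eff.or_, (eff.ci_low, eff.ci_high)
        z = eff.log_or / eff.se
        significant = 2.0 * _norm_sf(abs(z)) < 0.05
        basis = "single-study"
    else:
        pooled: PooledEffect = pool_auto(
            [odds_ratio(two_by_two(r)) for r in completed],
            p_q_threshold=p_q_threshold,
            i2_threshold=i2_threshold,
        )
        or_, ci = pooled.or_, (pooled.ci_low, pooled.ci_high)
        significant = pooled.significant
        basis = "pooled"
    return EthnicityRisk(
        group=freq.group,
        e_cc=freq.e_cc,
        or_=or_,
        or_ci=ci,
        par=levin_par(freq.e_cc, or_),
        par_ci=par_interval(freq.e_cc, ci),
        basis=basis,
        n_cohorts=len(completed),
        significant=significant,
    )


def ethnicity_risks(
    recs: Sequence[CohortRecord],
    policy: NonsignificantPolicy = NonsignificantPolicy.EXCLUDE,
    p_q_threshold: float = 0.10,
    i2_threshold: float = 50.0,
) -> dict[str, EthnicityRisk]:
    """Per-subgroup risks for a mixed cohort table, applying the policy for
    non-significant groups.

    Under ``LOWER_BOUND`` every group's OR is replaced by max(CI lower
    bound, 1), the most conservative treatment; under ``EXCLUDE`` groups
    with a non-significant pooled OR are dropped from the result.
    """
    by_group: dict[str, list[CohortRecord]] = {}
    for r in recs:
        by_group.setdefault(r.group, []).append(r)
    out: dict[str, EthnicityRisk] = {}
    for group, members in by_group.items():
        risk = ethnicity_risk(members, p_q_threshold, i2_threshold)
        if policy is NonsignificantPolicy.EXCLUDE and not risk.significant:
            continue
        if policy is NonsignificantPolicy.LOWER_BOUND:
            or_lb = max(risk.or_ci[0], 1.0)
            risk = EthnicityRisk(
                group=risk.group,
                e_cc=risk.e_cc,
                or_=or_lb,
                or_ci=risk.or_ci,
                par=levin_par(risk.e_cc, or_lb),
                par_ci=risk.par_ci,
                basis=risk.basis + " (lower-bound OR)",
                n_cohorts=risk.n_cohorts,
                significant=risk.significant,
            )
        out[group] = risk
    return out


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))
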