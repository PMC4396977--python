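"""Hardy-Weinberg genotype expansion and pooled CC-genotype frequencies.

Under Hardy-Weinberg equilibrium a risk allele at frequency *p* yields
homozygous carriers at frequency *p²*, so a study arm of size *n* that
reports only its risk-allele frequency contributes an expected ``p²·n``
CC carriers.  The pooled CC frequency for an ancestry group is the
study-size-weighted mean of per-cohort frequencies, computed from summed
carrier counts over summed study populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .records import CCSource, CohortRecord, CohortValidationError


@dataclass(frozen=True)
class GenotypeFrequency:
    """Pooled CC-genotype frequency for one subgroup.

    ``e_cc`` is the exposure frequency *E* that enters Levin's attributable
    risk formula: summed CC carriers over summed study population.
    """

    group: str
    e_cc: float
    total_cc: int
    total_n: int
    n_cohorts: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_cc <= 1.0:
            raise ValueError(f"e_cc {self.e_cc} outside [0, 1]")
        if self.total_cc > self.total_n:
            raise ValueError("total_cc exceeds total_n")


def expected_cc_count(
    raf: float, n: int | float, rounding: Literal["nearest", "none"] = "nearest"
) -> float:
    """Expected number of homozygous risk-genotype carriers, ``p²·n``.

    With ``rounding="nearest"`` the value is rounded to the nearest integer,
    half away from zero, matching how derived genotype counts are tabulated.
    """
    if not 0.0 <= raf <= 1.0:
        raise ValueError(f"risk-allele frequency {raf} outside [0, 1]")
    if n < 0:
        raise ValueError(f"negative population size {n}")
    expected = raf * raf * n
    if rounding == "nearest":
        return float(math.floor(expected + 0.5))
    return expected


def complete_cohort(rec: CohortRecord) -> CohortRecord:
    """Fill in missing CC counts from risk-allele frequencies under HWE.

    Reported counts are never touched; arms completed here are flagged
    ``hwe_derived``.  A record that is already complete is returned with its
    source flags defaulted to ``reported`` where unset.
    """
    changes: dict = {}
    if rec.cc_cases is None:
        changes["cc_cases"] = int(expected_cc_count(rec.raf_cases, rec.n_cases))
        changes["cc_source_cases"] = CCSource.HWE_DERIVED
    elif rec.cc_source_cases is None:
        changes["cc_source_cases"] = CCSource.REPORTED
    if rec.cc_controls is None:
        changes["cc_controls"] = int(expected_cc_count(rec.raf_controls, rec.n_controls))
        changes["cc_source_controls"] = CCSource.HWE_DERIVED
    elif rec.cc_source_controls is None:
        changes["cc_source_controls"] = CCSource.REPORTED
    return rec.with_(**changes) if changes else rec


def hwe_count_discrepancy(rec: CohortRecord) -> dict[str, float]:
    """QC statistic: |p²·n − reported CC| for arms that report both a CC
    count and a RAF.  Large values flag departure from HWE or transcription
    errors; arms lacking either quantity are omitted."""
    out: dict[str, float] = {}
    if rec.cc_cases is not None and rec.raf_cases is not None:
        out["cases"] = abs(expected_cc_count(rec.raf_cases, rec.n_cases, "none") - rec.cc_cases)
    if rec.cc_controls is not None and rec.raf_controls is not None:
        out["controls"] = abs(
            expected_cc_count(rec.raf_controls, rec.n_controls, "none") - rec.cc_controls
        )
    return out


def cohort_cc_frequency(rec: CohortRecord) -> float:
    """CC-genotype frequency in one completed cohort: total carriers over
    total study population (cases and controls combined)."""
    if not rec.is_complete:
        raise CohortValidationError(f"{rec.cohort_id}: complete the record first")
    return rec.total_cc / rec.total_n


def pooled_cc_frequency(recs: Sequence[CohortRecord]) -> GenotypeFrequency:
    """Study-size-weighted CC frequency across cohorts of a single subgroup.

    Equivalent to the size-weighted mean of per-cohort frequencies but
    computed from the summed counts, which are the primary data.
    """
    if not recs:
        raise ValueError("no cohorts supplied")
    groups = {r.group for r in recs}
    if len(groups) > 1:
        raise ValueError(f"mixed subgroups {sorted(groups)}; pool one group at a time")
    total_cc = sum(r.total_cc for r in recs)
    total_n = sum(r.total_n for r in recs)
    return GenotypeFrequency(
        group=recs[0].group,
        e_cc=total_cc / total_n,
        total_cc=total_cc,
        total_n=total_n,
        n_cohorts=len(recs),
    )


def mean_case_raf(recs: Iterable[CohortRecord]) -> float:
    """Unweighted arithmetic mean of the case-arm risk-allele frequency."""
    rafs = []
    for r in recs:
        if r.raf_cases is None:
            raise ValueError(f"{r.cohort_id}: case-arm risk-allele frequency missing")
        rafs.append(r.raf_cases)
    if not rafs:
        raise ValueError("no cohorts supplied")
    return sum(rafs) / len(rafs)
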