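"""Domain record types shared across the pipeline.

A :class:`CohortRecord` is one case-control study population genotyped at a
single biallelic risk locus.  Each arm (cases, controls) carries either an
explicit count of homozygous risk-genotype (CC) carriers, a risk-allele
frequency (RAF) from which that count can be derived under Hardy-Weinberg
equilibrium, or both.  :class:`TractDemographics` is one census tract with
per-subgroup population counts; the county is identified by the first five
characters of the tract identifier (the FIPS convention, without requiring
actual FIPS codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping


class CCSource(str, Enum):
    """Provenance of a CC-genotype count: reported by the study, or derived
    from the risk-allele frequency under Hardy-Weinberg equilibrium."""

    REPORTED = "reported"
    HWE_DERIVED = "hwe_derived"


class CohortValidationError(ValueError):
    """Raised when a cohort record (or file row) violates an invariant.

    ``errors`` holds ``(row_index, message)`` pairs when raised from a file
    reader, so callers can report every bad row at once.
    """

    def __init__(self, message: str, errors: list[tuple[int | None, str]] | None = None):
        super().__init__(message)
        self.errors = errors or []


@dataclass(frozen=True)
class CohortRecord:
    """One case-control study population.

    Parameters
    ----------
    cohort_id
        Study label; unique within a table.
    group
        Ancestry/ethnicity subgroup label (e.g. ``asian``, ``european``,
        ``mexican``).
    n_cases, n_controls
        Arm sizes (diseased and disease-free participants).
    cc_cases, cc_controls
        Counts of homozygous risk-genotype carriers per arm, when known.
    raf_cases, raf_controls
        Risk-allele frequency per arm, as a fraction in [0, 1], when known.
    cc_source_cases, cc_source_controls
        Whether each CC count was reported or HWE-derived.
    """

    cohort_id: str
    group: str
    n_cases: int
    n_controls: int
    cc_cases: int | None = None
    cc_controls: int | None = None
    raf_cases: float | None = None
    raf_controls: float | None = None
    cc_source_cases: CCSource | None = None
    cc_source_controls: CCSource | None = None

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise CohortValidationError(
                f"{self.cohort_id}: arm sizes must be positive "
                f"(n_cases={self.n_cases}, n_controls={self.n_controls})"
            )
        for arm, cc, n, raf in (
            ("cases", self.cc_cases, self.n_cases, self.raf_cases),
            ("controls", self.cc_controls, self.n_controls, self.raf_controls),
        ):
            if cc is None and raf is None:
                raise CohortValidationError(
                    f"{self.cohort_id}: {arm} arm has neither a CC count nor a "
                    "risk-allele frequency; genotype frequency cannot be computed"
                )
            if cc is not None and not 0 <= cc <= n:
                raise CohortValidationError(
                    f"{self.cohort_id}: CC count {cc} outside [0, {n}] in {arm}"
                )
            if raf is not None and not 0.0 <= raf <= 1.0:
                raise CohortValidationError(
                    f"{self.cohort_id}: risk-allele frequency {raf} outside [0, 1] in {arm}"
                )

    @property
    def total_n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def is_complete(self) -> bool:
        """True when both arms carry an explicit CC count."""
        return self.cc_cases is not None and self.cc_controls is not None

    @property
    def total_cc(self) -> int:
        if not self.is_complete:
            raise CohortValidationError(f"{self.cohort_id}: CC counts incomplete")
        return self.cc_cases + self.cc_controls  # type: ignore[operator]

    def with_(self, **changes) -> "CohortRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class PrevalenceEntry:
    """Disease prevalence in one subgroup, optionally with a weighting N."""

    subgroup: str
    prevalence: float
    weight_n: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.subgroup}: prevalence {self.prevalence} outside [0, 1]")


@dataclass(frozen=True)
class TractDemographics:
    """One census tract with per-subgroup population counts.

    ``county_id`` must equal the first five characters of ``tract_id``; it is
    derived automatically when omitted.
    """

    tract_id: str
    populations: Mapping[str, float]
    county_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.county_id:
            object.__setattr__(self, "county_id", self.tract_id[:5])
        if self.county_id != self.tract_id[:5]:
            raise ValueError(
                f"tract {self.tract_id}: county_id {self.county_id!r} is not the "
                "5-character prefix of the tract id"
            )
        for sub, pop in self.populations.items():
            if pop < 0:
                raise ValueError(f"tract {self.tract_id}: negative population for {sub!r}")

    @property
    def total_population(self) -> float:
        return float(sum(self.populations.values()))

    @property
    def is_zero_population(self) -> bool:
        return self.total_population == 0
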