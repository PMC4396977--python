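"""Odds ratios under a dominant genotype model and meta-analytic pooling.

Each cohort yields a 2x2 table of homozygous risk-genotype carriers (CC)
versus all other genotypes (CT + TT) in cases and controls.  Log odds
ratios are pooled with inverse-variance (Woolf) fixed-effect weights;
between-study heterogeneity is quantified with Cochran's Q and I², and a
DerSimonian-Laird random-effects model is available as a fallback when the
heterogeneity diagnostics exceed their thresholds.  A Mantel-Haenszel
fixed-effect pooler over the raw tables is provided as an alternative
weighting scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from scipy import stats

from .records import CohortRecord, CohortValidationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoByTwo:
    """Dominant-model contingency table: CC vs non-CC, cases vs controls."""

    a: float  # CC cases
    b: float  # non-CC cases
    c: float  # CC controls
    d: float  # non-CC controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """A single study's odds ratio on the log scale with its Woolf SE."""

    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z95 * self.se)


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its chi-square p-value and the derived I² (0-100)."""

    q: float
    df: int
    p_q: float
    i2: float


class PoolModel(str, Enum):
    FIXED = "fixed"
    RANDOM = "random"


@dataclass(frozen=True)
class PooledEffect:
    """Pooled odds ratio with 95% CI, Z test, and heterogeneity diagnostics."""

    model: PoolModel
    log_or: float
    se: float
    z: float
    p: float
    het: HeterogeneityStats | None = None
    tau2: float = 0.0

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z95 * self.se)

    @property
    def significant(self) -> bool:
        """Z-test p < 0.05, the conventional pooled-effect criterion."""
        return self.p < 0.05


def two_by_two(rec: CohortRecord) -> TwoByTwo:
    """Build the dominant-model table from a completed cohort record."""
    if not rec.is_complete:
        raise CohortValidationError(f"{rec.cohort_id}: complete the record first")
    return TwoByTwo(
        a=rec.cc_cases,
        b=rec.n_cases - rec.cc_cases,
        c=rec.cc_controls,
        d=rec.n_controls - rec.cc_controls,
    )


def odds_ratio(tbl: TwoByTwo, correction: float = 0.5) -> EffectEstimate:
    """Odds ratio (a·d)/(b·c) with Woolf standard error on the log scale.

    When any cell is zero, ``correction`` (Haldane-Anscombe, default 0.5) is
    added to all four cells; a table with an all-zero margin has no defined
    effect and raises.
    """
    a, b, c, d = tbl.a, tbl.b, tbl.c, tbl.d
    corrected = False
    if min(a, b, c, d) == 0:
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            raise ValueError("all-zero margin: odds ratio undefined")
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_or=log_or, se=se, corrected=corrected)


def _weights(effects: Sequence[EffectEstimate], tau2: float = 0.0) -> list[float]:
    return [1.0 / (e.se**2 + tau2) for e in effects]


def _pool(effects: Sequence[EffectEstimate], tau2: float, model: PoolModel) -> PooledEffect:
    w = _weights(effects, tau2)
    sw = sum(w)
    mu = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    se = math.sqrt(1.0 / sw)
    z = mu / se
    p = 2.0 * stats.norm.sf(abs(z))
    het = heterogeneity(effects) if len(effects) >= 2 else None
    return PooledEffect(model=model, log_or=mu, se=se, z=z, p=p, het=het, tau2=tau2)


def pool_fixed(effects: Sequence[EffectEstimate]) -> PooledEffect:
    """Inverse-variance fixed-effect pooling of log odds ratios.

    Weights are 1/SE²; the pooled estimate is the weighted mean log OR and
    the Z statistic is the pooled log OR over its pooled SE.
    """
    if not effects:
        raise ValueError("no effects supplied")
    return _pool(effects, 0.0, PoolModel.FIXED)


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q (chi-square test on k-1 df) and I² = max(0, (Q-df)/Q)·100."""
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least 2 effects")
    w = _weights(effects)
    sw = sum(w)
    mu = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    q = sum(wi * (e.log_or - mu) ** 2 for wi, e in zip(w, effects))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i2=i2)


def pool_random(effects: Sequence[EffectEstimate]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling.

    The method-of-moments between-study variance τ² = max(0, (Q-df)/C) is
    added to each study's within-study variance before inverse-variance
    weighting; with Q ≤ df this reduces exactly to the fixed-effect model.
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs at least 2 effects")
    w = _weights(effects)
    sw = sum(w)
    het = heterogeneity(effects)
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (het.q - het.df) / c) if c > 0 else 0.0
    return _pool(effects, tau2, PoolModel.RANDOM)


def pool_auto(
    effects: Sequence[EffectEstimate],
    p_q_threshold: float = 0.10,
    i2_threshold: float = 50.0,
) -> PooledEffect:
    """Fixed-effect pooling with a random-effects fallback.

    Heterogeneity is assumed when the Q-test p-value falls below
    ``p_q_threshold`` or I² exceeds ``i2_threshold``; the chosen model is
    recorded on the result.
    """
    if len(effects) < 2:
        raise ValueError("pool_auto needs at least 2 effects")
    het = heterogeneity(effects)
    if het.p_q < p_q_threshold or het.i2 > i2_threshold:
        return pool_random(effects)
    return pool_fixed(effects)


def pool_mantel_haenszel(tables: Sequence[TwoByTwo]) -> PooledEffect:
    """Mantel-Haenszel fixed-effect pooled odds ratio over raw 2x2 tables,
    with the Robins-Breslow-Greenland variance for the log OR."""
    if not tables:
        raise ValueError("no tables supplied")
    r = sum(t.a * t.d / t.n for t in tables)
    s = sum(t.b * t.c / t.n for t in tables)
    if r == 0 or s == 0:
        raise ValueError("Mantel-Haenszel odds ratio undefined (zero numerator or denominator)")
    log_or = math.log(r / s)
    p_sum = q_sum = pr = ps_qr = qs = 0.0
    for t in tables:
        pi = (t.a + t.d) / t.n
        qi = (t.b + t.c) / t.n
        ri = t.a * t.d / t.n
        si = t.b * t.c / t.n
        pr += pi * ri
        ps_qr += pi * si + qi * ri
        qs += qi * si
    var = pr / (2 * r**2) + ps_qr / (2 * r * s) + qs / (2 * s**2)
    se = math.sqrt(var)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    het = None
    if len(tables) >= 2:
        effects = [odds_ratio(t) for t in tables]
        het = heterogeneity(effects)
    return PooledEffect(model=PoolModel.FIXED, log_or=log_or, se=se, z=z, p=p, het=het)
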