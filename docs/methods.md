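# Methods

## Scope and model

`parscreen` estimates, for a single biallelic risk genotype, how much
disease burden each ancestry group carries because of that genotype, and
where that burden concentrates geographically.  The chain is:

1. **Genotype frequencies.** Each case-control cohort contributes CC
   (homozygous risk) carrier counts per arm.  Arms reporting only a
   risk-allele frequency *p* are completed under Hardy-Weinberg
   equilibrium as `round(p²·n)` and flagged `hwe_derived`; reported counts
   are never overwritten, and when both are present the absolute
   difference `|p²·n − CC|` is surfaced as a QC statistic.  The
   per-ancestry exposure frequency *E* is the study-size-weighted CC
   frequency, computed from summed carrier counts over summed study
   populations — counts, not the rounded per-cohort frequencies, are the
   primary data.

2. **Odds ratios.** Dominant-model 2×2 tables (CC vs CT+TT) give
   per-cohort ORs with Woolf standard errors
   `sqrt(1/a + 1/b + 1/c + 1/d)`.  Pooling uses inverse-variance
   fixed-effect weights; the pooled OR is declared significant at a
   two-sided Z-test p < 0.05.  Heterogeneity is assessed with Cochran's Q
   (chi-square on k−1 df) and `I² = max(0, (Q−df)/Q)·100`; when the Q
   p-value is below 0.10 or I² exceeds 50, `pool_auto` switches to a
   DerSimonian–Laird random-effects model (method-of-moments τ² added to
   within-study variances).  With Q ≤ df the random-effects model reduces
   exactly to the fixed-effect one.  A Mantel–Haenszel pooler over raw
   tables (Robins–Breslow–Greenland variance) is provided as an
   alternative weighting; on the bundled data it agrees with the
   inverse-variance estimate to well under the reporting precision, so the
   choice between the two is immaterial here and inverse-variance is the
   default.

3. **Attributable risk.** Levin's formula
   `PAR = E(OR−1)/(1+E(OR−1))`, with the OR standing in for the relative
   risk, gives the fraction of cases attributable to the genotype.  PAR is
   always computed from the *unrounded* pooled OR — feeding the 2-decimal
   presentation value through the formula visibly shifts the third decimal
   of the result.  PAR is stored as a fraction; any ×100 is presentation.
   Confidence bounds map the OR interval bounds through the formula, which
   is strictly increasing in OR, so the ordering is preserved.  This
   propagation treats *E* as fixed, so the PAR interval reflects OR
   uncertainty only.

4. **Geography.** A tract's total PAR is the mean of subgroup PARs
   weighted by the tract's subgroup populations; subgroups without a risk
   estimate are excluded from numerator *and* denominator, so the
   "total" population means the included subgroups only.  Subgroup
   contributions `pop·PAR/total` sum to the tract total by construction.
   Tracts are classified into equal-count quintiles of total PAR, with
   tracts (not people) as the units — matching how GIS quantile
   classification treats features — and zero-population tracts excluded
   before classification but retained in output with a null class.  A
   county is a hotspot when strictly more than 25% (configurable) of its
   included population lives in class-5 tracts.

5. **Prevalence combination.** `pop·prevalence·PAR`, summed over included
   subgroups, estimates the expected count of residents who will develop
   the disease because of the genotype; this is a reconstruction from the
   named ingredients (PAR is a share of cases; prevalence converts it to a
   share of people) and is kept out of any exactness claims.  An
   N-weighted prevalence helper aggregates finer prevalence categories
   into one subgroup value.

## Numerical and tie-breaking choices

- HWE-derived counts round half away from zero; this is the rounding that
  reproduces published derived-count cells (e.g. 557.8 → 558,
  694.8 → 695).
- Quintile thresholds are the 20/40/60/80th linear-interpolation
  percentiles; a value exactly on a threshold takes the *lower* class, and
  equal values therefore always share a class.  Fewer than five distinct
  values triggers a degenerate-classification warning.
- Zero cells in a 2×2 table get the Haldane–Anscombe 0.5 correction on all
  four cells; an all-zero margin raises instead of guessing.
- The normal 95% multiplier is 1.959963984540054.
- Mean case-arm risk-allele frequency is the *unweighted* arithmetic mean
  across cohorts: the weighted alternative does not reproduce the
  published summary values, the unweighted one does.

## Non-significant subgroups

Groups whose pooled OR is not significant can be handled three ways,
selectable via `NonsignificantPolicy`: **exclude** (default) drops the
group from tract aggregation entirely, so it neither contributes nor
dilutes; **point_estimate** keeps the group with its central OR regardless
of significance; **lower_bound** evaluates *every* group at the lower 95%
bound of its OR, floored at 1 — the most conservative treatment, under
which a non-significant group contributes zero attributable risk but
remains in the population denominator.  No overlap correction is applied
when census categories double-count people (e.g. an ethnicity "of any
race" overlapping a race category); excluding a subgroup via the policy
flag is the supported sensitivity analysis.

## Bundled data and its quirks

The packaged table stores the 29 cohorts cell-for-cell as published,
including which cells were HWE-derived (flagged per arm), because the
reported-genotypes-only sub-analysis needs that distinction.  Three
printed "Total CC" cells are internally inconsistent with their own
per-arm cells (3597 vs 1453+2114=3567; 3084 vs 1578+1505=3083; 377 vs
175+203=378 — the latter two consistent with summing unrounded HWE
expectations before rounding).  The per-arm cells are primary everywhere,
and the recomputed totals are what the pipeline reports; notably the
3567 total matches that cohort's published frequency (0.512) while the
printed 3597 does not.  The source also describes the collection as 28
study populations while listing 29 rows; the package keeps all 29 printed
rows.

## Synthetic data: what it emulates, what it does not

`simulate_cohorts` draws per-cohort arm sizes uniformly, jitters the
control risk-allele frequency on the logit scale (keeping it in (0,1)),
sets the control CC probability to raf² (HWE), and solves the 2×2 odds
identity for the case CC probability so the simulated dominant-model OR
equals the target exactly in expectation; τ² > 0 adds between-study
log-OR variance for heterogeneity studies.  Counts are binomial.
`simulate_census` draws tract subgroup mixtures from a Dirichlet model
inside counties, with planted counties receiving a boosted concentration
(×25 by default) of the highest-PAR subgroup and the planted labels
returned as ground truth.

Defaults emulate the bundled study conditions: cohorts of hundreds to a
few thousand per arm around control RAFs near 0.55–0.73 and ORs of
1.19–1.28; geographies of a dozen counties with 8–16 tracts of 1,200–8,000
residents.  What the generators deliberately lack: spatial
autocorrelation between neighbouring tracts, linkage disequilibrium or
multi-locus genotypes, covariate confounding, and survey measurement
error.  Passing tests therefore demonstrate the *arithmetic and
inferential machinery* — they do not validate the representativeness
assumptions (e.g. that study-population PARs transfer to census
populations) that any real screening application must defend.

## Verification strategy

Pooling is checked three independent ways: an exact-rational-arithmetic
evaluation of the weighted-mean formulas on small tables, statsmodels'
`combine_effects` / `StratifiedTable`, and R's `metafor` — all oracles
only, never the implementation.  Hardy-Weinberg expansion is checked
against a brute-force multinomial expectation at small n.  Fixed-effect
CI calibration is measured by simulation: 2,000 replicates of 20 cohorts
(≈2,000 per arm) at a true OR of 1.2, asserting ≈95% coverage within ±3
points.  Hotspot detection is validated by exact recovery of planted
counties.  Headline quantities that depend on the original census
extract (statewide tract counts, at-risk totals) are out of scope of the
exact checks and covered by these property-based equivalents instead.

## Known limitations

- ORs are crude (unadjusted); confounder-adjusted pooling is out of scope.
- The PAR interval ignores uncertainty in *E* and in prevalence.
- Levin's formula uses the OR as a relative-risk approximation, which
  overstates PAR for common outcomes.
- Quintile classes, and therefore hotspot flags, depend on the tract set
  supplied: screening a subset of a geography reclassifies it.
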