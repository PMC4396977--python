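"""Combining attributable risk with disease prevalence.

The tract PAR is a share of *cases*; multiplying by subgroup prevalence
converts it into a share of the *whole population* at attributable risk.
Here an Asian-subgroup prevalence is first built as an N-weighted average
of finer CDC-style categories, then a synthetic geography is screened and
the expected number of at-risk residents summed statewide.
"""

import parscreen as ps

# N-weighted prevalence for a heterogeneous subgroup
asian_parts = [
    ps.PrevalenceEntry("chinese", 0.044, weight_n=12000),
    ps.PrevalenceEntry("asian_indian", 0.130, weight_n=6000),
    ps.PrevalenceEntry("other_asian", 0.088, weight_n=18000),
]
asian_prev = ps.weighted_prevalence(asian_parts)
print(f"weighted Asian prevalence: {100 * asian_prev:.1f}%")

prevalence = [
    ps.PrevalenceEntry("asian", asian_prev),
    ps.PrevalenceEntry("european", 0.076),
    ps.PrevalenceEntry("mexican", 0.139),
]

risks = ps.ethnicity_risks(ps.load_bundled_cohorts())
tracts, _ = ps.simulate_census(ps.CensusSimConfig(n_counties=20, seed=7))
profiles = ps.profile_tracts(tracts, risks, prevalence)

total_pop = sum(p.total_pop for p in profiles)
total = sum(p.at_risk_count for p in profiles)
low = sum(p.at_risk_bounds[0] for p in profiles)
high = sum(p.at_risk_bounds[1] for p in profiles)

print(f"\n{len(profiles)} tracts, {total_pop:,.0f} residents in included subgroups")
print(f"expected at-risk residents: {total:,.0f} (95% CI {low:,.0f}-{high:,.0f})")
print(f"that is {100 * total / total_pop:.2f}% of the included population —")
print("people expected to develop the disease *because of* the risk genotype,")
print("given subgroup prevalence and attributable fractions.")
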