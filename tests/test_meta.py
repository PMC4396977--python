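"""Dominant-model odds ratios and fixed/random-effects pooling."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parscreen as ps


def rational_pool(tables):
    """Oracle: inverse-variance pooled log OR with exact rational weights.

    Weights 1/SE² = 1/(1/a+1/b+1/c+1/d) are exact rationals for integer
    cells; only the final log and division touch floats.  Independent of
    the EffectEstimate/pool_fixed path under test.
    """
    num = Fraction(0)
    den = Fraction(0)
    for a, b, c, d in tables:
        w = 1 / (Fraction(1, a) + Fraction(1, b) + Fraction(1, c) + Fraction(1, d))
        log_or = math.log(Fraction(a * d, b * c))
        num += w * Fraction(log_or).limit_denominator(10**15)
        den += w
    return float(num / den), math.sqrt(1 / float(den))


tables_strategy = st.lists(
    st.tuples(*(st.integers(1, 500) for _ in range(4))), min_size=2, max_size=8
)


class TestTwoByTwo:
    @pytest.mark.parametrize(
        "cohort_id, expected",
        [
            ("Gamboa-Melendez", (609, 418, 526, 464)),
            ("Horikoshi", (328, 532, 293, 566)),
        ],
    )
    def test_tables_from_published_rows(self, completed, cohort_id, expected):
        rec = next(r for r in completed if r.cohort_id == cohort_id)
        t = ps.two_by_two(rec)
        assert (t.a, t.b, t.c, t.d) == expected

    def test_equal_arms_give_symmetric_table(self):
        rec = ps.CohortRecord(
            cohort_id="s", group="g", n_cases=100, cc_cases=40,
            n_controls=100, cc_controls=40,
        )
        t = ps.two_by_two(rec)
        assert t.a == t.c and t.b == t.d


class TestOddsRatio:
    def test_mexican_cohort_cross_product(self):
        eff = ps.odds_ratio(ps.TwoByTwo(609, 418, 526, 464))
        assert eff.or_ == pytest.approx(609 * 464 / (418 * 526))
        assert eff.or_ == pytest.approx(1.285, abs=0.001)

    def test_null_table(self):
        eff = ps.odds_ratio(ps.TwoByTwo(10, 10, 10, 10))
        assert eff.or_ == 1.0
        assert eff.ci_low < 1.0 < eff.ci_high

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        eff = ps.odds_ratio(ps.TwoByTwo(0, 10, 5, 5))
        assert eff.corrected
        assert eff.or_ == pytest.approx(0.5 * 5.5 / (10.5 * 5.5))
        assert eff.se == pytest.approx(math.sqrt(1 / 0.5 + 1 / 10.5 + 1 / 5.5 + 1 / 5.5))

    def test_all_zero_margin_is_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            ps.odds_ratio(ps.TwoByTwo(0, 0, 5, 5))

    @given(st.tuples(*(st.integers(1, 500) for _ in range(4))))
    @settings(derandomize=True, max_examples=100)
    def test_swapping_case_control_rows_inverts_the_odds_ratio(self, cells):
        a, b, c, d = cells
        fwd = ps.odds_ratio(ps.TwoByTwo(a, b, c, d))
        rev = ps.odds_ratio(ps.TwoByTwo(c, d, a, b))
        assert fwd.log_or == pytest.approx(-rev.log_or, abs=1e-12)
        assert fwd.se == pytest.approx(rev.se, rel=1e-12)


class TestPoolFixed:
    def test_asian_pooled_or_matches_published(self, by_group):
        pooled = ps.pool_fixed([ps.odds_ratio(ps.two_by_two(r)) for r in by_group["asian"]])
        assert pooled.or_ == pytest.approx(1.19, abs=0.02)
        assert pooled.p < 0.01

    def test_european_pooled_or_matches_published(self, by_group):
        pooled = ps.pool_fixed([ps.odds_ratio(ps.two_by_two(r)) for r in by_group["european"]])
        assert pooled.or_ == pytest.approx(1.21, abs=0.02)
        assert pooled.ci_low == pytest.approx(1.13, abs=0.04)
        assert pooled.ci_high == pytest.approx(1.30, abs=0.04)
        assert pooled.p < 0.001

    def test_reported_genotype_asian_subset_matches_published_subanalysis(self, by_group):
        subset = [r for r in by_group["asian"]
                  if r.cc_source_cases == ps.CCSource.REPORTED]
        assert len(subset) == 10
        pooled = ps.pool_fixed([ps.odds_ratio(ps.two_by_two(r)) for r in subset])
        assert pooled.or_ == pytest.approx(1.20, abs=0.02)

    def test_single_effect_identity(self):
        eff = ps.odds_ratio(ps.TwoByTwo(30, 70, 20, 80))
        pooled = ps.pool_fixed([eff])
        assert pooled.log_or == pytest.approx(eff.log_or)
        assert pooled.se == pytest.approx(eff.se)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.pool_fixed([])

    @given(tables_strategy)
    @settings(derandomize=True, max_examples=60)
    def test_pooled_log_or_is_a_convex_combination(self, cells):
        effects = [ps.odds_ratio(ps.TwoByTwo(*t)) for t in cells]
        pooled = ps.pool_fixed(effects)
        logs = [e.log_or for e in effects]
        assert min(logs) - 1e-12 <= pooled.log_or <= max(logs) + 1e-12

    @pytest.mark.parametrize(
        "tables",
        [
            [(12, 28, 9, 31), (40, 60, 35, 65)],
            [(5, 15, 4, 16), (22, 18, 17, 23), (9, 11, 12, 8)],
            [(100, 200, 90, 210)],
        ],
    )
    def test_agrees_with_exact_rational_oracle(self, tables):
        effects = [ps.odds_ratio(ps.TwoByTwo(*t)) for t in tables]
        pooled = ps.pool_fixed(effects)
        mu, se = rational_pool(tables)
        assert pooled.log_or == pytest.approx(mu, abs=1e-12)
        assert pooled.se == pytest.approx(se, abs=1e-12)

    def test_agrees_with_statsmodels_combine_effects(self, by_group):
        from statsmodels.stats.meta_analysis import combine_effects

        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in by_group["european"]]
        res = combine_effects(
            np.array([e.log_or for e in effects]),
            np.array([e.se**2 for e in effects]),
            method_re="dl",
        )
        pooled = ps.pool_fixed(effects)
        assert pooled.log_or == pytest.approx(res.mean_effect_fe, abs=1e-10)
        assert pooled.se == pytest.approx(res.sd_eff_w_fe, abs=1e-10)


class TestMetaforCrossCheck:
    def test_fixed_effect_and_i2_agree_with_metafor(self, by_group, tmp_path):
        """R's metafor package, run on the same log ORs and variances, is a
        fully independent implementation of fixed-effect pooling and I²."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in by_group["european"]]
        yi = ",".join(repr(e.log_or) for e in effects)
        vi = ",".join(repr(e.se**2) for e in effects)
        script = tmp_path / "pool.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"res <- rma(yi=c({yi}), vi=c({vi}), method='FE')\n"
            "cat(sprintf('%.12f %.12f %.6f\\n', res$beta, res$se, res$I2))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        pooled = ps.pool_fixed(effects)
        het = ps.heterogeneity(effects)
        assert pooled.log_or == pytest.approx(float(out[0]), abs=1e-10)
        assert pooled.se == pytest.approx(float(out[1]), abs=1e-10)
        assert het.i2 == pytest.approx(float(out[2]), abs=0.01)


class TestHeterogeneity:
    def test_european_statistics_match_published(self, by_group):
        het = ps.heterogeneity([ps.odds_ratio(ps.two_by_two(r)) for r in by_group["european"]])
        assert het.df == 6
        assert het.i2 == pytest.approx(10.4, abs=1.0)
        assert het.p_q == pytest.approx(0.35, abs=0.03)

    def test_asian_statistics_match_published(self, by_group):
        het = ps.heterogeneity([ps.odds_ratio(ps.two_by_two(r)) for r in by_group["asian"]])
        assert het.df == 20
        assert het.i2 == 0.0  # floored: Q below its degrees of freedom
        assert het.p_q == pytest.approx(0.46, abs=0.03)

    def test_identical_effects_have_zero_q_and_i2(self):
        eff = ps.odds_ratio(ps.TwoByTwo(30, 70, 20, 80))
        het = ps.heterogeneity([eff, eff, eff])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            ps.heterogeneity([ps.odds_ratio(ps.TwoByTwo(1, 2, 3, 4))])


class TestPoolRandom:
    def test_reduces_to_fixed_when_q_below_df(self, by_group):
        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in by_group["asian"]]
        fixed, random = ps.pool_fixed(effects), ps.pool_random(effects)
        assert random.tau2 == 0.0
        assert random.log_or == pytest.approx(fixed.log_or)
        assert random.se == pytest.approx(fixed.se)

    def test_asian_random_effects_close_to_fixed(self, by_group):
        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in by_group["asian"]]
        assert ps.pool_random(effects).or_ == pytest.approx(
            ps.pool_fixed(effects).or_, abs=0.02
        )

    def test_heterogeneous_effects_widen_the_interval(self):
        cohorts = ps.simulate_cohorts(
            ps.CohortSimConfig(true_or=1.3, tau2=0.3, n_cohorts=12, seed=7)
        )
        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in cohorts]
        fixed, random = ps.pool_fixed(effects), ps.pool_random(effects)
        assert random.tau2 > 0
        assert random.se > fixed.se

    def test_agrees_with_statsmodels_dersimonian_laird(self):
        from statsmodels.stats.meta_analysis import combine_effects

        cohorts = ps.simulate_cohorts(
            ps.CohortSimConfig(true_or=1.4, tau2=0.1, n_cohorts=8, seed=3)
        )
        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in cohorts]
        res = combine_effects(
            np.array([e.log_or for e in effects]),
            np.array([e.se**2 for e in effects]),
            method_re="dl",
        )
        pooled = ps.pool_random(effects)
        assert pooled.log_or == pytest.approx(res.mean_effect_re, abs=1e-10)


class TestPoolAuto:
    def test_homogeneous_published_cohorts_use_fixed(self, by_group):
        for group in ("asian", "european"):
            effects = [ps.odds_ratio(ps.two_by_two(r)) for r in by_group[group]]
            assert ps.pool_auto(effects).model == ps.PoolModel.FIXED

    def test_injected_between_study_variance_triggers_random(self):
        cohorts = ps.simulate_cohorts(
            ps.CohortSimConfig(true_or=1.3, tau2=0.4, n_cohorts=15, seed=11)
        )
        effects = [ps.odds_ratio(ps.two_by_two(r)) for r in cohorts]
        assert ps.heterogeneity(effects).i2 > 50
        assert ps.pool_auto(effects).model == ps.PoolModel.RANDOM

    def test_two_identical_effects_stay_fixed(self):
        eff = ps.odds_ratio(ps.TwoByTwo(30, 70, 20, 80))
        assert ps.pool_auto([eff, eff]).model == ps.PoolModel.FIXED


class TestMantelHaenszel:
    def test_close_to_inverse_variance_on_published_cohorts(self, by_group):
        tables = [ps.two_by_two(r) for r in by_group["european"]]
        mh = ps.pool_mantel_haenszel(tables)
        ivw = ps.pool_fixed([ps.odds_ratio(t) for t in tables])
        assert mh.or_ == pytest.approx(ivw.or_, abs=0.02)

    def test_agrees_with_statsmodels_stratified_table(self, by_group):
        from statsmodels.stats.contingency_tables import StratifiedTable

        tables = [ps.two_by_two(r) for r in by_group["european"]]
        strat = StratifiedTable(
            [np.array([[t.a, t.b], [t.c, t.d]]) for t in tables]
        )
        mh = ps.pool_mantel_haenszel(tables)
        assert mh.or_ == pytest.approx(strat.oddsratio_pooled, abs=1e-10)
        assert mh.se == pytest.approx(strat.logodds_pooled_se, abs=1e-10)
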