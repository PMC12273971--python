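import logging

import numpy as np
import pandas as pd
import pytest

from ncdcra import (
    CONDITION_CHAPTER,
    RISK_FACTORS,
    Condition,
    DiscountSpec,
    GeneratorConfig,
    RampFunction,
    Scenario,
    ValidationError,
    annual_policy_impact,
    cumulative_savings,
    daly_reduction,
    default_condition_table,
    discount_factor,
    generate_inputs,
    ramp_factor,
    run_scenario,
)
from conftest import make_che, make_daly, make_paf

CONDITIONS = default_condition_table()


def eq1_nested_loops(che, conditions, paf, scenario):
    """Independent brute-force implementation of the policy-impact product.

    Pure Python loops over every key; returns {(country, rf, cond, year):
    (undiscounted, discounted)}.  Kept deliberately free of the engine's
    vectorised code path.
    """
    shares = {c.name: c.share_within_chapter for c in conditions}
    chapters = {c.name: c.chapter for c in conditions}
    out = {}
    for year in range(scenario.start_year, scenario.horizon_end + 1):
        if scenario.ramp_years == 0:
            ramp = 1.0
        else:
            ramp = min(max((year - scenario.start_year) / scenario.ramp_years, 0.0), 1.0)
        disc = (1.0 + scenario.discount_rate) ** -(year - scenario.base_year)
        for key, frac in paf.data.items():
            country, age, cond, rf, y = key
            if y != year or rf not in scenario.reductions or cond not in shares:
                continue
            che_val = che.data[(country, age, chapters[cond], year)]
            impact = (
                che_val * shares[cond] * scenario.reductions[rf] * frac * ramp
            )
            cell = (country, rf, cond, year)
            undisc, disc_total = out.get(cell, (0.0, 0.0))
            out[cell] = (undisc + impact, disc_total + impact * disc)
    return out


class TestRamp:
    @pytest.mark.parametrize(
        "year,expected",
        [(2020, 0.0), (2030, 1.0), (2025, 0.5), (2010, 0.0), (2045, 1.0)],
    )
    def test_linear_phase_in(self, year, expected):
        assert ramp_factor(year, RampFunction(2020, 10)) == expected

    def test_zero_ramp_is_step(self):
        ramp = RampFunction(2020, 0)
        assert ramp_factor(2019, ramp) == 0.0
        assert ramp_factor(2020, ramp) == 1.0

    def test_vectorised(self):
        years = np.arange(2020, 2032)
        vals = ramp_factor(years, RampFunction(2020, 10))
        assert vals[0] == 0.0 and vals[10] == 1.0 and vals[5] == 0.5
        assert (np.diff(vals) >= 0).all()


class TestDiscount:
    def test_base_year_is_one(self):
        assert discount_factor(2020, DiscountSpec(0.03, 2020)) == 1.0

    def test_zero_rate(self):
        assert discount_factor(2045, DiscountSpec(0.0, 2020)) == 1.0

    def test_two_years_at_three_percent(self):
        # (1.03)^2 = 1.0609
        assert discount_factor(2022, DiscountSpec(0.03, 2020)) == pytest.approx(
            1 / 1.0609, rel=1e-12
        )

    def test_before_base_year_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(2019, DiscountSpec(0.03, 2020))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            DiscountSpec(-0.01, 2020)


class TestAnnualPolicyImpact:
    def test_worked_product(self):
        """1000 x 0.9191 (CVD within circulatory) x 0.10 x 0.5 = 45.955."""
        che = make_che(chapters=("IX",), years=[2035], value=1000.0)
        paf = make_paf(pairs=[("cvd", "tobacco")], years=[2035], value=0.5)
        scenario = Scenario(reductions={"tobacco": 0.10}, start_year=2020)
        cvd = [c for c in CONDITIONS if c.name == "cvd"]
        impact = annual_policy_impact(che, cvd, paf, scenario, 2035)
        assert impact[("AA", "tobacco", "cvd")] == pytest.approx(45.955, rel=1e-12)

    def test_zero_reduction_zero_everywhere(self):
        che = make_che(chapters=("IX",), years=[2035])
        paf = make_paf(pairs=[("cvd", "tobacco")], years=[2035], value=0.5)
        scenario = Scenario(reductions={"tobacco": 0.0})
        cvd = [c for c in CONDITIONS if c.name == "cvd"]
        impact = annual_policy_impact(che, cvd, paf, scenario, 2035)
        assert (impact == 0.0).all()

    def test_degenerate_factors(self):
        """PAF=1, share=1 (cancer), reduction 0.25, full ramp -> 0.25 x CHE."""
        X = 3210.0
        che = make_che(chapters=("II",), years=[2035], value=X)
        paf = make_paf(pairs=[("cancer", "high_glucose")], years=[2035], value=1.0)
        scenario = Scenario(reductions={"high_glucose": 0.25})
        cancer = [c for c in CONDITIONS if c.name == "cancer"]
        impact = annual_policy_impact(che, cancer, paf, scenario, 2035)
        assert impact[("AA", "high_glucose", "cancer")] == pytest.approx(0.25 * X)

    def test_missing_chapter_rejected(self):
        che = make_che(chapters=("IX",), years=[2035])
        paf = make_paf(pairs=[("cancer", "tobacco")], years=[2035], value=0.5)
        scenario = Scenario(reductions={"tobacco": 0.1})
        with pytest.raises(ValidationError, match="chapter"):
            annual_policy_impact(che, CONDITIONS, paf, scenario, 2035)

    def test_sums_over_ages(self):
        che = make_che(ages=(30, 40), chapters=("IX",), years=[2035], value=1000.0)
        paf = make_paf(ages=(30, 40), pairs=[("cvd", "tobacco")], years=[2035], value=0.5)
        scenario = Scenario(reductions={"tobacco": 0.10})
        cvd = [c for c in CONDITIONS if c.name == "cvd"]
        impact = annual_policy_impact(che, cvd, paf, scenario, 2035)
        assert impact[("AA", "tobacco", "cvd")] == pytest.approx(2 * 45.955)


class TestRunScenario:
    def small_world(self):
        years = range(2020, 2023)
        che = make_che(
            countries=("AA", "BB"),
            ages=(30, 40),
            chapters=tuple(CONDITION_CHAPTER.values()),
            years=years,
            value=500.0,
        )
        pairs = [("cvd", "tobacco"), ("copd", "tobacco"), ("cvd", "high_sbp"),
                 ("ckd", "high_sbp"), ("cancer", "alcohol")]
        paf = make_paf(
            countries=("AA", "BB"), ages=(30, 40), pairs=pairs, years=years, value=0.3
        )
        return che, paf

    def test_one_year_horizon_reduces_to_annual(self):
        che, paf = self.small_world()
        scenario = Scenario(
            reductions={"tobacco": 0.1}, start_year=2022, horizon_end=2022,
            ramp_years=0, base_year=2022,
        )
        table = run_scenario(che, CONDITIONS, paf, scenario)
        annual = annual_policy_impact(che, CONDITIONS, paf, scenario, 2022)
        got = table.data["undiscounted"].droplevel("year")
        pd.testing.assert_series_equal(
            got.sort_index(), annual.sort_index(), check_names=False
        )

    def test_additivity_across_risk_factors(self):
        che, paf = self.small_world()
        joint = Scenario(
            reductions={"tobacco": 0.1, "alcohol": 0.1}, horizon_end=2022
        )
        combined = run_scenario(che, CONDITIONS, paf, joint)
        t = run_scenario(che, CONDITIONS, paf, joint.single_factor("tobacco"))
        a = run_scenario(che, CONDITIONS, paf, joint.single_factor("alcohol"))
        summed = (t + a).data
        pd.testing.assert_frame_equal(combined.data, summed)

    def test_linearity_in_reduction(self, tiny_world):
        """25% scenario equals 5 x the 5% scenario, cellwise, to 1e-12 relative."""
        _, che, paf, _, _ = tiny_world
        s5 = Scenario(reductions={rf: 0.05 for rf in RISK_FACTORS})
        s25 = Scenario(reductions={rf: 0.25 for rf in RISK_FACTORS})
        i5 = run_scenario(che, CONDITIONS, paf, s5)
        i25 = run_scenario(che, CONDITIONS, paf, s25)
        np.testing.assert_allclose(
            i25.data.to_numpy(), 5.0 * i5.data.to_numpy(), rtol=1e-12
        )

    def test_oracle_equivalence(self):
        """Vectorised engine matches an independent nested-loop implementation
        on a 2 countries x 2 ages x 5 conditions x 3 years instance."""
        rng = np.random.default_rng(7)
        years = range(2020, 2023)
        countries, ages = ("AA", "BB"), (30, 40)
        che_frame = make_che(
            countries, ages, tuple(CONDITION_CHAPTER.values()), years
        ).to_frame()
        che_frame["value_musd2018"] = rng.uniform(100, 2000, len(che_frame))
        from ncdcra import CheSeries, PafSeries

        che = CheSeries.from_frame(che_frame)
        pairs = [("cvd", "tobacco"), ("cancer", "tobacco"), ("copd", "tobacco"),
                 ("diabetes_t2", "tobacco"), ("cvd", "high_sbp"), ("ckd", "high_sbp"),
                 ("cvd", "high_glucose"), ("cancer", "high_glucose"),
                 ("diabetes_t2", "high_glucose"), ("ckd", "high_glucose"),
                 ("cvd", "alcohol"), ("cancer", "alcohol")]
        paf_frame = make_paf(countries, ages, pairs, years).to_frame()
        paf_frame["fraction"] = rng.uniform(0, 1, len(paf_frame))
        paf = PafSeries.from_frame(paf_frame)
        scenario = Scenario(
            reductions={"tobacco": 0.1, "high_sbp": 0.25, "alcohol": 0.05},
            start_year=2020, horizon_end=2022, ramp_years=10,
        )
        table = run_scenario(che, CONDITIONS, paf, scenario)
        oracle = eq1_nested_loops(che, CONDITIONS, paf, scenario)
        assert set(table.data.index) == set(oracle)
        for cell, (undisc, disc) in oracle.items():
            np.testing.assert_allclose(
                table.data.loc[cell].to_numpy(), [undisc, disc], rtol=1e-12
            )

    def test_discounted_leq_undiscounted(self, tiny_world):
        _, che, paf, _, _ = tiny_world
        scenario = Scenario(reductions={"tobacco": 0.1})
        table = run_scenario(che, CONDITIONS, paf, scenario)
        after_base = table.data.index.get_level_values("year") > scenario.base_year
        assert (
            table.data.loc[after_base, "discounted"]
            <= table.data.loc[after_base, "undiscounted"]
        ).all()
        zero_rate = run_scenario(
            che, CONDITIONS, paf, scenario.model_copy(update={"discount_rate": 0.0})
        )
        pd.testing.assert_series_equal(
            zero_rate.data["discounted"], zero_rate.data["undiscounted"],
            check_names=False,
        )

    def test_monotonic_in_che_and_reduction(self):
        che, paf = self.small_world()
        base = Scenario(reductions={"tobacco": 0.1}, horizon_end=2022)
        ref = run_scenario(che, CONDITIONS, paf, base).data["undiscounted"]
        more_che = run_scenario(che.scale(1.5), CONDITIONS, paf, base).data["undiscounted"]
        more_red = run_scenario(
            che, CONDITIONS, paf, base.model_copy(update={"reductions": {"tobacco": 0.2}})
        ).data["undiscounted"]
        assert (more_che >= ref).all() and (more_red >= ref).all()

    def test_ramp_conservation_against_year_loop(self):
        """On constant inputs, the ramp forgoes exactly (ramp_years + 1)/2
        annual full-effect amounts relative to an instant-effect run —
        cross-checked against the brute-force year loop."""
        years = range(2020, 2051)
        che = make_che(chapters=("IX",), years=years, value=1000.0)
        paf = make_paf(pairs=[("cvd", "tobacco")], years=years, value=0.5)
        cvd = [c for c in CONDITIONS if c.name == "cvd"]
        ramped = Scenario(reductions={"tobacco": 0.1}, ramp_years=10)
        instant = ramped.model_copy(update={"ramp_years": 0})
        total_ramped = run_scenario(che, cvd, paf, ramped).data["undiscounted"].sum()
        total_instant = run_scenario(che, cvd, paf, instant).data["undiscounted"].sum()
        annual_full = 1000.0 * 0.9191 * 0.1 * 0.5
        assert total_instant - total_ramped == pytest.approx(
            (10 + 1) / 2 * annual_full, rel=1e-12
        )
        oracle = eq1_nested_loops(che, cvd, paf, ramped)
        assert total_ramped == pytest.approx(
            sum(v[0] for v in oracle.values()), rel=1e-12
        )


class TestCumulativeSavings:
    def test_simple_sum_no_discount(self):
        years = range(2020, 2023)
        che = make_che(chapters=("IX",), years=years, value=1000.0)
        paf = make_paf(pairs=[("cvd", "tobacco")], years=years, value=0.5)
        cvd = [c for c in CONDITIONS if c.name == "cvd"]
        scenario = Scenario(
            reductions={"tobacco": 1.0 / (0.9191 * 0.5 * 100)},  # 10 M US$/yr
            ramp_years=0, horizon_end=2022, discount_rate=0.0,
        )
        impact = run_scenario(che, cvd, paf, scenario)
        summary = cumulative_savings(impact, che, DiscountSpec(0.0, 2020))
        assert summary.loc[("AA", "tobacco"), "undiscounted"] == pytest.approx(30.0)
        assert summary.loc[("AA", "tobacco"), "discounted"] == pytest.approx(30.0)

    def test_zero_impact_zero_percent(self):
        years = range(2020, 2023)
        che = make_che(chapters=("IX",), years=years)
        paf = make_paf(pairs=[("cvd", "tobacco")], years=years, value=0.5)
        cvd = [c for c in CONDITIONS if c.name == "cvd"]
        scenario = Scenario(reductions={"tobacco": 0.0}, horizon_end=2022)
        impact = run_scenario(che, cvd, paf, scenario)
        summary = cumulative_savings(impact, che, DiscountSpec())
        assert (summary[["undiscounted", "discounted", "percent"]] == 0.0).all().all()

    def test_percent_invariant_to_currency_rescale(self, tiny_world):
        _, che, paf, _, _ = tiny_world
        scenario = Scenario(reductions={"tobacco": 0.1})
        spec = DiscountSpec()
        s1 = cumulative_savings(run_scenario(che, CONDITIONS, paf, scenario), che, spec)
        che2 = che.scale(7.5)
        s2 = cumulative_savings(run_scenario(che2, CONDITIONS, paf, scenario), che2, spec)
        np.testing.assert_allclose(
            s1["percent"].to_numpy(), s2["percent"].to_numpy(), rtol=1e-12
        )


class TestDalyReduction:
    def test_uniform_paf_exact_product(self):
        """s x PAF x 100 exactly when PAFs are uniform across the world."""
        countries = ("AA", "BB", "CC")
        paf = make_paf(countries=countries, pairs=[("copd", "tobacco")], value=0.458)
        daly = make_daly(countries=countries, conditions=("copd",))
        out = daly_reduction(paf, daly, [0.05, 0.10, 0.25])
        assert out.loc[("copd", "tobacco"), 0.25] == pytest.approx(11.45)
        assert out.loc[("copd", "tobacco"), 0.10] == pytest.approx(4.58)

    def test_zero_level(self):
        paf = make_paf(pairs=[("cvd", "tobacco")], value=0.3)
        daly = make_daly()
        out = daly_reduction(paf, daly, [0.0])
        assert (out[0.0] == 0.0).all()

    def test_daly_weighted_within_country(self):
        """Within-country averaging weights age bands by their DALY burden."""
        paf_frame = make_paf(ages=(30, 40), pairs=[("cvd", "high_sbp")]).to_frame()
        paf_frame.loc[paf_frame.age_group == 30, "fraction"] = 0.2
        paf_frame.loc[paf_frame.age_group == 40, "fraction"] = 0.6
        from ncdcra import PafSeries, DalySeries

        paf = PafSeries.from_frame(paf_frame)
        daly_frame = make_daly(ages=(30, 40)).to_frame()
        daly_frame.loc[daly_frame.age_group == 30, "dalys"] = 1000.0
        daly_frame.loc[daly_frame.age_group == 40, "dalys"] = 3000.0
        daly = DalySeries.from_frame(daly_frame)
        out = daly_reduction(paf, daly, [0.10])
        expected = 0.10 * (0.2 * 1000 + 0.6 * 3000) / 4000 * 100
        assert out.loc[("cvd", "high_sbp"), 0.10] == pytest.approx(expected)

    def test_zero_daly_country_excluded_with_warning(self, caplog):
        paf = make_paf(countries=("AA", "BB"), pairs=[("cvd", "tobacco")], value=0.4)
        daly_frame = make_daly(countries=("AA", "BB")).to_frame()
        daly_frame.loc[daly_frame.country == "BB", "dalys"] = 0.0
        from ncdcra import DalySeries

        daly = DalySeries.from_frame(daly_frame)
        with caplog.at_level(logging.WARNING):
            out = daly_reduction(paf, daly, [0.10])
        assert out.loc[("cvd", "tobacco"), 0.10] == pytest.approx(4.0)
        assert any("BB" in rec.message for rec in caplog.records)

    def test_across_country_weighting_option(self):
        paf_frame = make_paf(countries=("AA", "BB"), pairs=[("cvd", "tobacco")]).to_frame()
        paf_frame.loc[paf_frame.country == "AA", "fraction"] = 0.2
        paf_frame.loc[paf_frame.country == "BB", "fraction"] = 0.6
        from ncdcra import PafSeries, DalySeries

        paf = PafSeries.from_frame(paf_frame)
        daly_frame = make_daly(countries=("AA", "BB")).to_frame()
        daly_frame.loc[daly_frame.country == "BB", "dalys"] = 3e5
        daly = DalySeries.from_frame(daly_frame)
        unweighted = daly_reduction(paf, daly, [0.10])
        weighted = daly_reduction(paf, daly, [0.10], across_country="daly_weighted")
        assert unweighted.loc[("cvd", "tobacco"), 0.10] == pytest.approx(4.0)
        assert weighted.loc[("cvd", "tobacco"), 0.10] == pytest.approx(
            0.10 * (0.2 * 1e5 + 0.6 * 3e5) / 4e5 * 100
        )
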