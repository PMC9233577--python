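"""Descriptive statistics: proportions, cross-tabs, incidence windows,
standardized differences."""

import datetime
import math

import numpy as np
import pandas as pd
import pytest

from aghdstrat.claims_model import CodedEvent, CodeSystem, CohortWindow, EventKind, Person, Sex
from aghdstrat.cohort_stats import (
    NEGLIGIBLE_SD,
    age_sex_table,
    comorbidity_incidence,
    diagnostic_test_usage,
    effect_size_table,
    standardized_difference,
    tier_proportions,
)
from aghdstrat.errors import EmptyCohortError, InputDataError

D = datetime.date


def _results(rows):
    return pd.DataFrame(rows, columns=["person_id", "tier", "reason", "excluded_paths"])


class TestTierProportions:
    def test_simple_arithmetic(self):
        out = tier_proportions(
            _results(
                [
                    ("a", "high", "GROUP_A", ""),
                    ("b", "moderate", "TEST_GHD", ""),
                    ("c", "low", "NONE", ""),
                    ("d", "low", "NONE", ""),
                ]
            )
        )
        assert out.tiers == {"high": 0.25, "moderate": 0.25, "low": 0.5}
        assert out.reason_shares["high"] == {"GROUP_A": 1.0}

    def test_all_low(self):
        out = tier_proportions(_results([("a", "low", "NONE", ""), ("b", "low", "NONE", "")]))
        assert out.tiers == {"high": 0.0, "moderate": 0.0, "low": 1.0}

    def test_sum_exactly_one_and_order_invariant(self):
        rows = [(f"p{i}", t, "NONE" if t == "low" else "GROUP_A", "") for i, t in
                enumerate(["high"] * 3 + ["low"] * 5 + ["moderate"] * 0)]
        rows = [
            (pid, tier, "GROUP_A" if tier == "high" else "NONE", "")
            for pid, tier, _, _ in rows
        ]
        frame = _results(rows)
        out = tier_proportions(frame)
        shuffled = tier_proportions(frame.sample(frac=1.0, random_state=5))
        assert out.tiers == shuffled.tiers
        assert abs(sum(out.tiers.values()) - 1.0) < 1e-12

    def test_empty_cohort_is_explicit_error(self):
        with pytest.raises(EmptyCohortError):
            tier_proportions(_results([]))


class TestAgeSexTable:
    WINDOW = CohortWindow()

    def test_single_person_lands_in_one_cell(self):
        persons = [Person("a", Sex.FEMALE, 1992, D(2010, 1, 1), D(2017, 12, 31))]
        table = age_sex_table(persons, _results([("a", "low", "NONE", "")]), self.WINDOW)
        assert table.loc["All", "low"] == 100.0
        assert table.loc["female", "low"] == 100.0
        assert table.loc["18-30", "low"] == 100.0
        assert table.loc["male", "low"] == 0.0

    def test_tier_columns_sum_to_cohort_column(self):
        persons = [
            Person(f"p{i}", Sex.FEMALE if i % 2 else Sex.MALE, 1990 - 7 * i, D(2010, 1, 1), D(2017, 12, 31))
            for i in range(9)
        ]
        tiers = ["high", "moderate", "low"] * 3
        table = age_sex_table(
            persons,
            _results([(f"p{i}", tiers[i], "GROUP_A" if tiers[i] == "high" else
                       ("TEST_GHD" if tiers[i] == "moderate" else "NONE"), "") for i in range(9)]),
            self.WINDOW,
        )
        for row in table.index:
            assert table.loc[row, ["high", "moderate", "low"]].sum() == pytest.approx(
                table.loc[row, "cohort"]
            )
        assert table.loc["All", "cohort"] == pytest.approx(100.0)
        # band rows partition the cohort column
        bands = [r for r in table.index if r not in ("All", "female", "male")]
        assert table.loc[bands, "cohort"].sum() == pytest.approx(100.0)

    def test_unjoinable_result_names_the_person(self):
        with pytest.raises(InputDataError, match="ghost"):
            age_sex_table([], _results([("ghost", "low", "NONE", "")]), self.WINDOW)


class TestComorbidityIncidence:
    WINDOW = CohortWindow()

    def _cohort(self):
        person = Person("a", Sex.FEMALE, 1970, D(2010, 1, 1), D(2017, 12, 31))
        results = _results([("a", "high", "GROUP_A", "")])
        return [person], results

    def _hyp(self, date):
        return CodedEvent("a", date, CodeSystem.ICD10CM, "I10", EventKind.DIAGNOSIS)

    def test_event_outside_last_year_not_counted(self, registry):
        persons, results = self._cohort()
        stale = self._hyp(D(2017, 12, 31) - datetime.timedelta(days=400))
        table = comorbidity_incidence(persons, [stale], results, registry, self.WINDOW)
        assert table.loc["hypertensive_disorder", "high"] == 0.0

    def test_window_boundary_day_counted(self, registry):
        persons, results = self._cohort()
        edge = self._hyp(D(2017, 12, 31) - datetime.timedelta(days=364))
        table = comorbidity_incidence(persons, [edge], results, registry, self.WINDOW)
        assert table.loc["hypertensive_disorder", "high"] == 1.0

    def test_person_counted_once_despite_repeat_claims(self, registry):
        persons, results = self._cohort()
        events = [self._hyp(D(2017, 3, 1)), self._hyp(D(2017, 9, 1))]
        table = comorbidity_incidence(persons, events, results, registry, self.WINDOW)
        assert table.loc["hypertensive_disorder", "high"] == 1.0

    def test_invariant_to_duplication_and_order(self, registry):
        persons, results = self._cohort()
        events = [self._hyp(D(2017, 3, 1)), self._hyp(D(2017, 9, 1))]
        a = comorbidity_incidence(persons, events, results, registry, self.WINDOW)
        b = comorbidity_incidence(persons, events[::-1] * 3, results, registry, self.WINDOW)
        assert a.equals(b)

    def test_last_year_anchored_to_each_persons_observation_end(self, registry):
        # enrollment ends mid-2015, so a 2015 claim counts and a 2013 one does not
        person = Person("a", Sex.FEMALE, 1970, D(2010, 1, 1), D(2015, 6, 30))
        results = _results([("a", "high", "GROUP_A", "")])
        inside = self._hyp(D(2015, 3, 1))
        outside = self._hyp(D(2013, 3, 1))
        table = comorbidity_incidence([person], [inside, outside], results, registry, self.WINDOW)
        assert table.loc["hypertensive_disorder", "high"] == 1.0
        table2 = comorbidity_incidence([person], [outside], results, registry, self.WINDOW)
        assert table2.loc["hypertensive_disorder", "high"] == 0.0


class TestStandardizedDifference:
    def test_equal_proportions_give_zero(self):
        assert standardized_difference(0.3, 0.3) == 0.0

    def test_closed_form_example(self):
        # 23.9% vs 2.5% under the pooled two-proportion formula
        assert standardized_difference(0.239, 0.025) == pytest.approx(-0.666, abs=5e-4)

    def test_antisymmetry_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.random(), rng.random()
            assert standardized_difference(a, b) == pytest.approx(
                -standardized_difference(b, a), abs=1e-12
            )

    def test_degenerate_denominators_return_zero(self):
        assert standardized_difference(0.0, 0.0) == 0.0
        assert standardized_difference(1.0, 1.0) == 0.0

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            standardized_difference(-0.1, 0.5)
        with pytest.raises(ValueError):
            standardized_difference(0.5, 1.2)

    def test_agrees_with_brute_force_on_planted_binary_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n1, n2 = int(rng.integers(2, 50)), int(rng.integers(2, 50))
            x1 = rng.integers(0, 2, size=n1)
            x2 = rng.integers(0, 2, size=n2)
            p1, p2 = float(x1.mean()), float(x2.mean())
            denom_sq = (p1 * (1 - p1) + p2 * (1 - p2)) / 2
            expected = 0.0 if denom_sq == 0 else (p2 - p1) / math.sqrt(denom_sq)
            assert standardized_difference(p1, p2) == pytest.approx(expected, abs=1e-12)


class TestEffectSizeTable:
    def test_negligible_flag_iff_small_sd(self):
        incidence = pd.DataFrame(
            {
                "high": [0.30, 0.11, 0.0],
                "moderate": [0.28, 0.10, 0.0],
                "low": [0.10, 0.095, 0.0],
            },
            index=pd.Index(["big_gap", "small_gap", "absent"], name="comorbidity"),
        )
        for row in effect_size_table(incidence):
            assert row.negligible_high_low == (abs(row.sd_high_low) <= NEGLIGIBLE_SD)
            assert row.negligible_high_mod == (abs(row.sd_high_mod) <= NEGLIGIBLE_SD)
            assert row.negligible_mod_low == (abs(row.sd_mod_low) <= NEGLIGIBLE_SD)
        rows = {r.comorbidity: r for r in effect_size_table(incidence)}
        assert not rows["big_gap"].negligible_high_low
        assert rows["absent"].sd_high_low == 0.0 and rows["absent"].negligible_high_low

    def test_sign_negative_when_first_group_larger(self):
        incidence = pd.DataFrame(
            {"high": [0.3], "moderate": [0.2], "low": [0.1]},
            index=pd.Index(["c"], name="comorbidity"),
        )
        row = effect_size_table(incidence)[0]
        assert row.sd_high_low < 0 and row.sd_mod_low < 0


class TestDiagnosticTestUsage:
    def test_moderate_test_ghd_person_counted_and_low_omitted(self, registry):
        persons = [
            Person("m", Sex.FEMALE, 1970, D(2010, 1, 1), D(2017, 12, 31)),
            Person("l", Sex.MALE, 1970, D(2010, 1, 1), D(2017, 12, 31)),
        ]
        events = [
            CodedEvent("m", D(2016, 5, 1), CodeSystem.CPT, "84305", EventKind.PROCEDURE),
            CodedEvent("l", D(2016, 5, 1), CodeSystem.CPT, "84305", EventKind.PROCEDURE),
        ]
        results = _results([("m", "moderate", "TEST_GHD", ""), ("l", "low", "NONE", "")])
        table = diagnostic_test_usage(persons, events, results, registry)
        assert list(table.columns) == ["high", "moderate"]
        assert table.loc["igf1_serum", "moderate"] == 1.0

    def test_empty_tier_gives_zero_row_not_error(self, registry):
        persons = [Person("m", Sex.FEMALE, 1970, D(2010, 1, 1), D(2017, 12, 31))]
        results = _results([("m", "moderate", "TEST_AXIS_3", "")])
        table = diagnostic_test_usage(persons, [], results, registry)
        assert (table["high"] == 0.0).all()
        assert (table["moderate"] == 0.0).all()
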