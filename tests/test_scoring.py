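"""Unit and property tests for the core scoring engine."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cescore import (
    ConfigError,
    CountryYearRecord,
    InputError,
    IndicatorDefinition,
    MissingPolicy,
    SeverityLevel,
    classify_indicator,
    dimension_sum,
    level_weight,
    need_score,
    score_country,
    severity_score,
)
from conftest import record_from_levels

LM, HI, EX = SeverityLevel.LOW_MEDIUM, SeverityLevel.HIGH, SeverityLevel.EXTREME

HIGHER = IndicatorDefinition(
    name="underweight", dimension="vulnerability", direction="higher_is_worse",
    cutoff_lo=10, cutoff_hi=25,
)
LOWER = IndicatorDefinition(
    name="literacy", dimension="vulnerability", direction="lower_is_worse",
    cutoff_lo=70, cutoff_hi=50,
)

levels_st = st.sampled_from([LM, HI, EX])
assignment_st = st.tuples(*[levels_st] * 8)


class TestLevels:
    def test_weights(self):
        assert level_weight(LM) == 0.5
        assert level_weight(HI) == 1.0
        assert level_weight(EX) == 1.5

    def test_total_order(self):
        assert LM < HI < EX
        assert max([HI, EX, LM]) is EX

    def test_weight_is_order_isomorphic(self):
        assert sorted([EX, LM, HI]) == sorted([EX, LM, HI], key=level_weight)

    def test_from_label(self):
        assert SeverityLevel.from_label("Extreme") is EX
        with pytest.raises(ValueError, match="unknown severity level"):
            SeverityLevel.from_label("catastrophic")


class TestClassifyIndicator:
    @pytest.mark.parametrize(
        "value,expected",
        [(None, None), (5, LM), (9.999, LM), (10, HI), (24.999, HI), (25, EX), (40, EX)],
    )
    def test_higher_is_worse(self, value, expected):
        assert classify_indicator(value, HIGHER) is expected

    @pytest.mark.parametrize(
        "value,expected",
        [(None, None), (90, LM), (70.001, LM), (70, HI), (50.001, HI), (50, EX), (20, EX)],
    )
    def test_lower_is_worse_mirrored(self, value, expected):
        assert classify_indicator(value, LOWER) is expected

    def test_boundary_goes_to_severer_level_both_directions(self):
        assert classify_indicator(HIGHER.cutoff_hi, HIGHER) is EX
        assert classify_indicator(HIGHER.cutoff_lo, HIGHER) is HI
        assert classify_indicator(LOWER.cutoff_hi, LOWER) is EX
        assert classify_indicator(LOWER.cutoff_lo, LOWER) is HI

    def test_nan_is_na(self):
        assert classify_indicator(float("nan"), HIGHER) is None

    @pytest.mark.parametrize("bad", [float("inf"), float("-inf")])
    def test_non_finite_raises_naming_indicator(self, bad):
        with pytest.raises(InputError, match="underweight"):
            classify_indicator(bad, HIGHER)

    def test_non_numeric_raises(self):
        with pytest.raises(InputError, match="literacy"):
            classify_indicator("high", LOWER)


class TestDimensionSum:
    def test_extremes_of_range(self):
        assert dimension_sum([LM] * 4) == 2.0
        assert dimension_sum([EX] * 4) == 6.0

    def test_strict_propagates_missing(self):
        assert dimension_sum([EX, EX, EX, None]) is None

    def test_impute_extreme_fills_gap(self):
        assert dimension_sum([EX, EX, EX, None], MissingPolicy.impute_extreme()) == 6.0

    def test_impute_level_equivalence(self):
        explicit = MissingPolicy.impute(SeverityLevel.EXTREME)
        shorthand = MissingPolicy.impute_extreme()
        levels = [HI, None, LM, None]
        assert dimension_sum(levels, explicit) == dimension_sum(levels, shorthand)

    def test_requires_exactly_four_slots(self):
        with pytest.raises(InputError, match="4"):
            dimension_sum([LM, HI, EX])

    @given(levels=st.tuples(*[levels_st] * 4))
    @settings(derandomize=True)
    def test_sum_always_in_range(self, levels):
        s = dimension_sum(list(levels))
        assert 2.0 <= s <= 6.0


class TestSeverityAndNeed:
    @pytest.mark.parametrize("v,e,expected", [(2.0, 2.0, 4.0), (6.0, 6.0, 36.0), (6.0, 5.5, 33.0)])
    def test_products(self, v, e, expected):
        assert severity_score(v, e) == expected

    def test_out_of_range_sum_rejected(self):
        with pytest.raises(InputError, match="vulnerability_sum"):
            severity_score(1.0, 4.0)
        with pytest.raises(InputError, match="exposure_sum"):
            severity_score(4.0, 6.5)

    @pytest.mark.parametrize("sev,pin,expected", [(4, 0, 0), (10, 2.5, 25), (36, 1, 36)])
    def test_need_products(self, sev, pin, expected):
        assert need_score(sev, pin) == expected

    def test_negative_millions_rejected(self):
        with pytest.raises(InputError, match=">= 0"):
            need_score(10, -1)


class TestScoreCountry:
    def test_all_low_medium_scores_minimum(self, config):
        rec = record_from_levels(config, [LM] * 8, pin=1.0)
        s = score_country(rec, config)
        assert s.vulnerability_sum == 2.0 and s.exposure_sum == 2.0
        assert s.severity_score == 4.0
        assert s.need_score == 4.0
        assert s.missing_indicators == () and s.imputed_indicators == ()

    def test_missing_gni_imputed_extreme_gives_thirty_three(self, config):
        # 3 observed extreme vulnerability values + 1 na imputed extreme;
        # exposure 3 extreme + 1 high
        rec = record_from_levels(
            config,
            dict(zip(config.names, [EX, EX, EX, EX, EX, EX, EX, HI])),
            missing=("gni_per_capita_ppp",),
        )
        s = score_country(rec, config, MissingPolicy.impute_extreme())
        assert s.vulnerability_sum == 6.0 and s.exposure_sum == 5.5
        assert s.severity_score == 33.0
        assert s.imputed_indicators == ("gni_per_capita_ppp",)
        assert s.levels["gni_per_capita_ppp"] is None  # heat map stays blank

    def test_strict_policy_leaves_severity_unresolved(self, config):
        rec = CountryYearRecord("X", "2015", {n: None for n in config.names})
        s = score_country(rec, config)
        assert s.severity_score is None and s.need_score is None
        assert set(s.missing_indicators) == set(config.names)
        assert s.imputed_indicators == ()

    def test_missing_people_in_need_leaves_need_unresolved(self, config):
        s = score_country(record_from_levels(config, [HI] * 8, pin=None), config)
        assert s.severity_score == 16.0
        assert s.need_score is None

    def test_unknown_indicator_name_is_config_error(self, config):
        rec = CountryYearRecord("X", "2015", {"made_up_indicator": 3.0})
        with pytest.raises(ConfigError, match="made_up_indicator"):
            score_country(rec, config)

    def test_negative_people_in_need_rejected(self):
        with pytest.raises(InputError, match=">= 0"):
            CountryYearRecord("X", "2015", {}, people_in_need_millions=-0.5)


def brute_force_severity(levels8):
    """Independent recomputation: direct weight sums and product."""
    w = {LM: 0.5, HI: 1.0, EX: 1.5}
    return sum(w[l] for l in levels8[:4]) * sum(w[l] for l in levels8[4:])


class TestScoreLaws:
    def test_exhaustive_range_is_4_to_36(self):
        scores = [
            brute_force_severity(a)
            for a in itertools.product([LM, HI, EX], repeat=8)
        ]
        assert len(scores) == 6561
        assert min(scores) == 4.0
        assert max(scores) == 36.0

    @given(assignment=assignment_st)
    @settings(derandomize=True)
    def test_multiplicative_symmetry(self, assignment):
        swapped = assignment[4:] + assignment[:4]
        assert brute_force_severity(assignment) == brute_force_severity(swapped)

    @given(assignment=assignment_st, pos=st.integers(0, 7))
    @settings(derandomize=True)
    def test_single_level_escalation_strictly_increases(self, assignment, pos):
        if assignment[pos] is EX:
            return
        order = [LM, HI, EX]
        raised = list(assignment)
        raised[pos] = order[order.index(assignment[pos]) + 1]
        assert brute_force_severity(tuple(raised)) > brute_force_severity(assignment)

    @given(assignment=assignment_st, gaps=st.sets(st.integers(0, 7), min_size=1))
    @settings(derandomize=True)
    def test_imputation_dominance(self, config, assignment, gaps):
        """Imputing extreme never yields less severity than imputing low/medium."""
        missing = tuple(config.names[i] for i in gaps)
        rec = record_from_levels(config, dict(zip(config.names, assignment)), missing=missing)
        hi = score_country(rec, config, MissingPolicy.impute_extreme()).severity_score
        lo = score_country(
            rec, config, MissingPolicy.impute(SeverityLevel.LOW_MEDIUM)
        ).severity_score
        assert hi >= lo

    @given(assignment=assignment_st, pin=st.floats(0, 20, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_oracle_equivalence_random_records(self, config, assignment, pin):
        """score_country agrees with the direct sum/product recomputation."""
        s = score_country(record_from_levels(config, assignment, pin=pin), config)
        expected = brute_force_severity(assignment)
        assert s.severity_score == expected
        assert s.need_score == pytest.approx(expected * pin)
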