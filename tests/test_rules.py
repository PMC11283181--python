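import math

import numpy as np
import pytest

from obsdq.rules import (
    Rule,
    RuleConfigError,
    default_rules,
    evaluate_rules,
    load_rules,
    rule_subscores,
)


def clean_record(**overrides):
    base = {
        "record_id": "r1",
        "hospital_id": "H1",
        "maternal_dob": "3/4/1990",
        "maternal_age": 30.0,
        "maternal_height": 165.0,
        "maternal_weight": 64.0,
        "bmi": 23.5,
        "parity": 1.0,
        "n_pregnancies": 2.0,
        "n_prev_eutocic": 1.0,
        "n_prev_csections": 0.0,
        "n_prenatal_visits": 8.0,
        "gestational_age_admission": 39.0,
        "gestational_age_delivery": 39.3,
        "pregnancy_type": "single",
        "fetal_position_admission": "cephalic",
        "fetal_position_delivery": "cephalic",
        "labor_onset": "spontaneous",
        "robson_group": "3",
        "delivery_type": "eutocic",
        "bishop_score": np.nan,
        "blood_group": "O+",
        "efw_week25": 700.0,
        "efw_week30": 1300.0,
        "efw_week35": 2400.0,
        "birth_weight": 3300.0,
        "n_deliveries_vacuum": np.nan,
    }
    base.update(overrides)
    return base


@pytest.fixture(scope="module")
def book():
    return default_rules()


class TestRulebook:
    def test_default_book_has_exactly_17_rules(self, book):
        assert len(book) == 17

    def test_covers_both_dimensions(self, book):
        dims = {r.dimension for r in book}
        assert dims == {"conformance", "plausibility"}

    def test_unknown_predicate_kind_is_config_error(self):
        with pytest.raises(RuleConfigError, match="R99"):
            Rule("R99", "conformance", "", "telepathy", {})

    def test_missing_field_is_config_error(self):
        with pytest.raises(RuleConfigError):
            load_rules([{"id": "R1", "dimension": "conformance"}])

    def test_empty_config_gives_empty_book_and_perfect_scores(self):
        rules = load_rules({"rules": []})
        assert rules == []
        assert rule_subscores(evaluate_rules(rules, clean_record())) == {
            "conformance": 1.0,
            "rule_plausibility": 1.0,
        }


class TestEvaluation:
    def test_clean_record_passes_every_rule(self, book):
        res = evaluate_rules(book, clean_record())
        assert not [r for r in res if r.status == "fail"]

    @pytest.mark.parametrize(
        "overrides, failing_rule",
        [
            ({"gestational_age_delivery": 45.0}, "P09_gestational_age_delivery"),
            ({"gestational_age_admission": 15.0}, "P10_gestational_age_admission"),
            ({"maternal_weight": 300.0}, "P11_maternal_weight_range"),
            ({"bmi": 80.0}, "P12_bmi_range"),
            ({"maternal_age": 65.0}, "P13_maternal_age_range"),
            ({"parity": 5.0}, "P14_parity_consistency"),
            ({"efw_week25": 2600.0, "efw_week30": 2700.0}, "P15_efw_week35_gt_week25"),
            ({"gestational_age_admission": 41.0}, "P17_admission_before_delivery"),
            ({"robson_group": "11"}, "R02_robson_value_set"),
            ({"blood_group": "XX"}, "R06_blood_group_value_set"),
            ({"maternal_dob": "1990-04-03"}, "R01_dob_format"),
            ({"bishop_score": 14.0}, "R03_bishop_value_set"),
            ({"parity": 1.5, "n_pregnancies": 3.0}, "R08_count_columns_numeric"),
        ],
    )
    def test_targeted_defect_fails_exactly_that_rule(self, book, overrides, failing_rule):
        res = evaluate_rules(book, clean_record(**overrides))
        failed = {r.rule_id for r in res if r.status == "fail"}
        assert failing_rule in failed
        # and no unrelated rule fails (P15/P16 share the same pair check)
        allowed = {failing_rule}
        if failing_rule == "P15_efw_week35_gt_week25":
            allowed.add("P16_efw_series_increasing")
        assert failed <= allowed

    def test_weight_series_violation_fails_both_series_rules(self, book):
        res = evaluate_rules(book, clean_record(efw_week25=2600.0, efw_week30=2500.0,
                                                efw_week35=2400.0))
        failed = {r.rule_id for r in res if r.status == "fail"}
        assert {"P15_efw_week35_gt_week25", "P16_efw_series_increasing"} <= failed

    def test_robson_7_passes_value_set(self, book):
        res = evaluate_rules(book, clean_record(robson_group="7"))
        assert all(r.status != "fail" for r in res if r.rule_id == "R02_robson_value_set")

    def test_malformed_count_cell_fails_type_conformance(self, book):
        res = evaluate_rules(book, clean_record(parity="two"))
        r08 = next(r for r in res if r.rule_id == "R08_count_columns_numeric")
        assert r08.status == "fail"
        assert "parity" in r08.message

    def test_null_operand_makes_cross_rule_not_applicable(self, book):
        res = evaluate_rules(book, clean_record(gestational_age_admission=np.nan))
        r17 = next(r for r in res if r.rule_id == "P17_admission_before_delivery")
        assert r17.status == "not_applicable"

    def test_fail_messages_name_rule_and_offending_value(self, book):
        res = evaluate_rules(book, clean_record(gestational_age_delivery=45.0))
        msg = next(r.message for r in res if r.status == "fail")
        assert "P09" in msg and "45" in msg

    def test_rule_referencing_absent_column_is_skipped_with_warning(self):
        rules = load_rules([{"id": "X", "dimension": "plausibility", "kind": "numeric_range",
                             "columns": ["ghost"], "min": 0}])
        with pytest.warns(UserWarning, match="ghost"):
            res = evaluate_rules(rules, {"a": 1})
        assert res == []

    def test_pure_function_of_inputs(self, book):
        rec = clean_record(robson_group="11", maternal_weight=np.nan)
        assert evaluate_rules(book, rec) == evaluate_rules(book, rec)


class TestSubscores:
    def test_pass_ratio(self, book):
        res = evaluate_rules(book, clean_record(gestational_age_delivery=45.0))
        plaus = [r for r in res if r.dimension == "plausibility"
                 and r.status != "not_applicable"]
        expected = sum(1 for r in plaus if r.status == "pass") / len(plaus)
        assert rule_subscores(res)["rule_plausibility"] == pytest.approx(expected)
        assert rule_subscores(res)["conformance"] == 1.0

    def test_all_not_applicable_scores_one(self, book):
        empty = {k: np.nan for k in clean_record()}
        scores = rule_subscores(evaluate_rules(book, empty))
        assert scores == {"conformance": 1.0, "rule_plausibility": 1.0}

    def test_extra_failure_never_raises_either_subscore(self, book):
        base = clean_record(gestational_age_delivery=45.0)
        worse = dict(base, maternal_weight=300.0)
        s0 = rule_subscores(evaluate_rules(book, base))
        s1 = rule_subscores(evaluate_rules(book, worse))
        assert s1["rule_plausibility"] <= s0["rule_plausibility"] + 1e-12
        assert s1["conformance"] <= s0["conformance"] + 1e-12
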