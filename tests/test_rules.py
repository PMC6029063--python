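"""Patient-level rule engine: diagnosis, GOLD typing, regimens, comorbidity indexes."""

import itertools

import pytest
from conftest import correctly_diagnosed_record, make_record, spiro
from hypothesis import given, settings
from hypothesis import strategies as st

from coach_audit.rules import (
    RuleInputError,
    charlson_index,
    classify_regimen,
    comorbidity_groups,
    cote_index,
    evaluate_diagnosis,
    gold_group,
    has_duplicate_components,
    has_obstruction,
    incorrect_prescription,
    select_spirometry,
)


class TestObstruction:
    @pytest.mark.parametrize(
        "ratio,threshold,expected",
        [
            (62.3, 70.0, True),   # the cohort-average ratio is obstructive
            (70.0, 70.0, False),  # strict inequality at the boundary
            (69.9, 70.0, True),
            (55.0, 60.0, True),
        ],
    )
    def test_threshold_is_strict(self, ratio, threshold, expected):
        assert has_obstruction(spiro(ratio=ratio), threshold) is expected

    def test_ratio_recomputed_from_volumes(self):
        s = spiro(ratio=None, fev1_ml=2000, fvc_ml=4000)
        assert has_obstruction(s, 70.0) is True

    def test_missing_everything_is_indeterminate_not_false(self):
        assert has_obstruction(spiro(ratio=None), 70.0) is None


class TestSelectSpirometry:
    def test_post_bd_preferred(self):
        record = make_record(
            spirometries=(spiro(phase="pre_BD", ratio=66.0), spiro(phase="post_BD", ratio=72.0))
        )
        chosen, source = select_spirometry(record, "audited_last")
        assert source == "post_BD" and chosen.ratio_pct == 72.0

    def test_pre_bd_fallback(self):
        record = make_record(spirometries=(spiro(phase="pre_BD", ratio=66.0),))
        chosen, source = select_spirometry(record, "audited_last")
        assert source == "pre_BD_fallback" and chosen.ratio_pct == 66.0

    def test_absence_is_a_valid_return(self):
        chosen, source = select_spirometry(make_record(), "audited_last")
        assert chosen is None and source == "none"

    def test_visits_are_independent(self):
        record = make_record(spirometries=(spiro(visit="diagnostic", ratio=55.0),))
        assert select_spirometry(record, "audited_last") == (None, "none")


class TestDiagnosis:
    def test_active_smoker_with_obstruction_is_correct(self):
        verdict = evaluate_diagnosis(correctly_diagnosed_record())
        assert verdict.correct_basic and verdict.spirometry_source == "post_BD"

    def test_obstruction_must_persist_at_audited_visit(self):
        # obstructive at diagnosis only; audited visit is non-obstructive
        record = make_record(
            exposure_flags=frozenset({"biomass"}),
            spirometries=(spiro(visit="diagnostic", ratio=55.0), spiro(ratio=75.0)),
        )
        assert not evaluate_diagnosis(record).correct_basic

    def test_exposure_required(self):
        record = make_record(smoking_status="never", spirometries=(spiro(ratio=50.0),))
        verdict = evaluate_diagnosis(record)
        assert verdict.obstruction_ok and not verdict.exposure_ok and not verdict.correct_basic

    def test_missing_spirometry_fails_obstruction_with_source_none(self):
        verdict = evaluate_diagnosis(make_record(exposure_flags=frozenset({"occupational"})))
        assert not verdict.obstruction_ok and verdict.spirometry_source == "none"

    def test_symptoms_tighten_the_verdict(self):
        base = correctly_diagnosed_record()
        assert not evaluate_diagnosis(base).correct_with_symptoms
        with_symptoms = base.replace(symptom_registration=frozenset({"cough_sputum"}))
        assert evaluate_diagnosis(with_symptoms).correct_with_symptoms
        # asthma-symptom registration alone does not count as COPD symptoms
        asthma_only = base.replace(symptom_registration=frozenset({"asthma_symptoms"}))
        assert not evaluate_diagnosis(asthma_only).correct_with_symptoms

    def test_verdict_implication(self):
        v = evaluate_diagnosis(correctly_diagnosed_record(symptom_registration=frozenset({"dyspnea_any"})))
        assert v.correct_with_symptoms and v.correct_basic

    @given(
        ratio=st.floats(min_value=20.0, max_value=95.0),
        extra_exposure=st.sampled_from(["passive_smoking", "occupational", "biomass", "other"]),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotonicity(self, ratio, extra_exposure):
        """Adding exposure or lowering the audited-visit ratio never breaks a correct verdict."""
        record = make_record(
            exposure_flags=frozenset({"occupational"}), spirometries=(spiro(ratio=ratio),)
        )
        before = evaluate_diagnosis(record).correct_basic
        more_exposed = record.replace(exposure_flags=record.exposure_flags | {extra_exposure})
        lower = record.replace(spirometries=(spiro(ratio=max(20.0, ratio - 10)),))
        if before:
            assert evaluate_diagnosis(more_exposed).correct_basic
            assert evaluate_diagnosis(lower).correct_basic


REGIMEN_BY_SET = {
    frozenset(): "none",
    frozenset({"LABA"}): "one_LABD",
    frozenset({"LAMA"}): "one_LABD",
    frozenset({"LABA", "LAMA"}): "LABA_LAMA",
    frozenset({"ICS"}): "ICS_alone",
    frozenset({"ICS", "LABA"}): "ICS_plus_one_LABD",
    frozenset({"ICS", "LAMA"}): "LAMA_ICS_other",
    frozenset({"ICS", "LABA", "LAMA"}): "triple",
}


class TestRegimen:
    @pytest.mark.parametrize("components,expected", sorted(REGIMEN_BY_SET.items(), key=str))
    def test_all_component_sets(self, components, expected):
        record = make_record(inhaled_lines=tuple((c,) for c in sorted(components)))
        assert classify_regimen(record) == expected

    def test_unknown_component_rejected(self):
        record = make_record()
        object.__setattr__(record, "inhaled_lines", (("SABA",),))
        with pytest.raises(RuleInputError):
            classify_regimen(record)

    @given(
        lines=st.lists(
            st.lists(st.sampled_from(["LABA", "LAMA", "ICS"]), min_size=1, max_size=3).map(tuple),
            max_size=4,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_exhaustive_and_order_invariant(self, lines):
        """Every multiset maps to exactly one category, independent of line order."""
        record = make_record(inhaled_lines=tuple(lines))
        category = classify_regimen(record)
        flat = frozenset(c for line in lines for c in line)
        assert category == REGIMEN_BY_SET[flat]
        for perm in itertools.islice(itertools.permutations(lines), 6):
            assert classify_regimen(make_record(inhaled_lines=tuple(perm))) == category

    def test_duplicates_seen_before_deduplication(self):
        combo_plus_single = make_record(inhaled_lines=(("LABA", "ICS"), ("LABA",)))
        assert has_duplicate_components(combo_plus_single)
        assert classify_regimen(combo_plus_single) == "ICS_plus_one_LABD"
        clean_triple = make_record(inhaled_lines=(("LABA", "ICS"), ("LAMA",)))
        assert not has_duplicate_components(clean_triple)


class TestGoldGroup:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(mmrc=1, exacerbations_prev_year=0, hospitalizations_prev_year=0), "A"),
            (dict(mmrc=3, exacerbations_prev_year=0, hospitalizations_prev_year=0), "B"),
            (dict(mmrc=1, exacerbations_prev_year=2, hospitalizations_prev_year=0), "C"),
            (dict(mmrc=3, exacerbations_prev_year=2), "D"),
            (dict(mmrc=0, cat=15, exacerbations_prev_year=0), "B"),   # CAT >= 10 is high-symptom
            (dict(mmrc=1, exacerbations_prev_year=1, hospitalizations_prev_year=1), "C"),
            (dict(), "unclassifiable"),                                # both axes unknown
            (dict(mmrc=2), "unclassifiable"),                          # exacerbation history unknown
            (dict(exacerbations_prev_year=3), "unclassifiable"),       # symptoms unknown
        ],
    )
    def test_grouping(self, kwargs, expected):
        assert gold_group(make_record(**kwargs)) == expected


class TestIncorrectPrescription:
    def test_untreated_high_risk_patient_fires(self):
        fired, reasons = incorrect_prescription(make_record(), group="B", regimen="none")
        assert fired and reasons == ["untreated_BD"]

    def test_ics_monotherapy_fires_for_any_group(self):
        record = make_record(inhaled_lines=(("ICS",),))
        fired, reasons = incorrect_prescription(record, group="A", regimen="ICS_alone")
        assert fired and reasons == ["ics_monotherapy"]

    def test_untreated_group_a_does_not_fire(self):
        fired, reasons = incorrect_prescription(make_record(), group="A", regimen="none")
        assert not fired and reasons == []

    def test_duplication_fires(self):
        record = make_record(inhaled_lines=(("LABA", "ICS"), ("LABA",), ("LAMA",)))
        fired, reasons = incorrect_prescription(record)
        assert fired and "duplicate_therapy" in reasons

    def test_group_a_with_clean_regimen_never_fires(self):
        for lines in [(("LABA",),), (("LABA", "LAMA"),), (("LABA", "ICS"), ("LAMA",))]:
            record = make_record(inhaled_lines=lines, mmrc=0, exacerbations_prev_year=0)
            assert gold_group(record) == "A"
            assert not incorrect_prescription(record)[0]


class TestComorbidityIndexes:
    def test_empty_set_scores_zero(self):
        assert charlson_index(make_record()) == 0
        assert cote_index(make_record()) == 0

    def test_single_condition_scores_its_weight(self):
        record = make_record(comorbidities=frozenset({"renal_disease"}))
        assert charlson_index(record) == 2
        record = make_record(comorbidities=frozenset({"liver_cirrhosis"}))
        assert cote_index(record) == 4

    def test_multi_condition_hand_summed(self):
        # Charlson: CAD 1 + renal 2 + lung cancer 2 + chronic pulmonary 1 = 6
        conditions = frozenset(
            {"coronary_artery_disease", "renal_disease", "lung_cancer", "chronic_pulmonary_disease"}
        )
        assert charlson_index(make_record(comorbidities=conditions)) == 6
        # COTE: CAD 1 + lung cancer 6 = 7 (renal and chronic pulmonary unweighted)
        assert cote_index(make_record(comorbidities=conditions)) == 7

    def test_cote_anxiety_is_scored_in_women_only(self):
        conditions = frozenset({"coronary_artery_disease", "lung_cancer", "anxiety"})
        assert cote_index(make_record(sex="male", comorbidities=conditions)) == 7
        assert cote_index(make_record(sex="female", comorbidities=conditions)) == 13

    def test_unrecognized_condition_listed_in_error(self):
        with pytest.raises(RuleInputError, match="scurvy"):
            charlson_index(make_record(comorbidities=frozenset({"scurvy"})))

    @given(
        split=st.integers(min_value=0, max_value=6),
        sex=st.sampled_from(["male", "female"]),
    )
    @settings(derandomize=True, max_examples=20)
    def test_additivity_over_disjoint_sets(self, split, sex):
        pool = sorted(
            ["diabetes", "dementia", "lymphoma", "anxiety", "liver_cirrhosis", "atrial_fibrillation"]
        )
        s1, s2 = frozenset(pool[:split]), frozenset(pool[split:])
        for index in (charlson_index, cote_index):
            total = index(make_record(sex=sex, comorbidities=s1 | s2))
            assert total == index(make_record(sex=sex, comorbidities=s1)) + index(
                make_record(sex=sex, comorbidities=s2)
            )


class TestComorbidityGroups:
    def test_coronary_artery_disease_is_cardiac_and_vascular(self):
        flags = comorbidity_groups(make_record(comorbidities=frozenset({"coronary_artery_disease"})))
        assert flags["cardiac"] and flags["vascular"]

    def test_peripheral_vascular_disease_is_vascular_only(self):
        flags = comorbidity_groups(make_record(comorbidities=frozenset({"peripheral_vascular_disease"})))
        assert flags["vascular"] and not flags["cardiac"]

    def test_psychiatric_follows_medication_use(self):
        assert comorbidity_groups(make_record(psychiatric_drugs=True))["psychiatric"]
        assert not comorbidity_groups(make_record())["psychiatric"]

    def test_eyedrops_marker(self):
        assert comorbidity_groups(make_record(eyedrops=True))["eyedrops"]
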