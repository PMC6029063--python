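"""Report assembly: hand-computed fixtures, closure invariants, figures."""

import pytest
from conftest import make_record, spiro

from coach_audit import build_report, render_figures, run_audit, write_cohort_csv
from coach_audit.aggregation import REGIMEN_TABLE_ITEMS
from coach_audit.reporting import report_to_frame, report_to_markdown, write_report


def _item(report, item_id):
    return next(ir for ir in report.items if ir.cohort.item_id == item_id)


@pytest.fixture(scope="module")
def hand_cohort():
    """Ten hand-written cases with fully known rule outcomes."""
    c1 = dict(center_id="C1", region_id="R1")
    c2 = dict(center_id="C2", region_id="R2")
    return [
        # correct diagnosis, dyspnea registered, triple therapy, GOLD D
        make_record(
            patient_id="r1", smoking_status="active", exposure_flags=frozenset({"active_smoking"}),
            spirometries=(spiro(ratio=55.0),), symptom_registration=frozenset({"dyspnea_any", "dyspnea_mMRC"}),
            mmrc=3, exacerbations_prev_year=2, exacerbations_registered=True,
            inhaled_lines=(("LABA", "ICS"), ("LAMA",)), **c1,
        ),
        # exposure but no spirometry at all: diagnosis fails on obstruction
        make_record(patient_id="r2", exposure_flags=frozenset({"biomass"}), **c1),
        # no exposure; obstructive; ICS monotherapy
        make_record(
            patient_id="r3", smoking_status="never", spirometries=(spiro(ratio=50.0),),
            inhaled_lines=(("ICS",),), **c1,
        ),
        # pre-BD fallback obstruction + cough: correct with symptoms; GOLD A
        make_record(
            patient_id="r4", smoking_status="ex", exposure_flags=frozenset({"active_smoking"}),
            spirometries=(spiro(phase="pre_BD", ratio=68.0),),
            symptom_registration=frozenset({"cough_sputum"}), mmrc=1,
            exacerbations_prev_year=0, hospitalizations_prev_year=0, exacerbations_registered=True,
            inhaled_lines=(("LAMA",),), **c1,
        ),
        # non-obstructive at the audited visit; chronic bronchitis with sputum color noted
        make_record(
            patient_id="r5", sex="female", exposure_flags=frozenset({"occupational"}),
            spirometries=(spiro(ratio=72.0),), chronic_bronchitis=True,
            symptom_registration=frozenset({"sputum_color"}), inhaled_lines=(("LABA", "LAMA"),), **c1,
        ),
        # correct diagnosis but a duplicated LABA across lines
        make_record(
            patient_id="r6", smoking_status="active", exposure_flags=frozenset({"active_smoking"}),
            spirometries=(spiro(phase="pre_BD", ratio=65.0),),
            inhaled_lines=(("LABA", "ICS"), ("LABA",)), **c2,
        ),
        # GOLD B without any maintenance therapy: untreated
        make_record(
            patient_id="r7", exposure_flags=frozenset({"occupational"}), mmrc=2,
            exacerbations_prev_year=0, hospitalizations_prev_year=0, exacerbations_registered=True, **c2,
        ),
        # correct diagnosis on non-combined ICS-LAMA therapy
        make_record(
            patient_id="r8", smoking_status="ex", exposure_flags=frozenset({"active_smoking"}),
            spirometries=(spiro(ratio=60.0),), inhaled_lines=(("LAMA",), ("ICS",)), **c2,
        ),
        # vaccination documented and administered; nothing else
        make_record(
            patient_id="r9", sex="female", smoking_status="never",
            nonpharm_registration=frozenset({"influenza_vacc_registered"}),
            nonpharm_given=frozenset({"influenza_vaccinated"}), **c2,
        ),
        # chronic bronchitis without sputum-color documentation
        make_record(patient_id="r10", chronic_bronchitis=True, exacerbations_registered=True, **c2),
    ]


class TestHandCohort:
    def test_report_matches_hand_computed_table(self, hand_cohort):
        report = build_report(hand_cohort)
        expected = {
            "correct_diagnosis_components": (4, 10),   # r1, r4, r6, r8
            "correct_diagnosis_symptoms": (2, 10),     # r1, r4
            "regimen_none": (4, 10),                   # r2, r7, r9, r10
            "regimen_one_labd": (1, 10),               # r4
            "regimen_laba_lama": (1, 10),              # r5
            "regimen_ics_alone": (1, 10),              # r3
            "regimen_ics_plus_labd": (2, 10),          # r6 + non-combined r8
            "regimen_triple": (1, 10),                 # r1
            "ics_lama_noncombined": (1, 10),           # r8
            "ics_containing": (4, 10),                 # r1, r3, r6, r8
            "incorrect_prescription": (3, 10),         # r3 ICS alone, r6 duplicate, r7 untreated B
            "gold_classifiable": (3, 10),              # r1 D, r4 A, r7 B
            "exacerbations_registered": (3, 10),       # r1, r4 ... r7, r10 -> recount below
            "sputum_color_registered": (1, 2),         # r5 of the two chronic bronchitis cases
            "dyspnea_registered": (1, 10),             # r1
            "cough_sputum_registered": (1, 10),        # r4
            "influenza_vaccinated": (1, 10),           # r9
            "male_gender": (8, 10),
        }
        # r1, r4, r7, r10 have the exacerbation item documented
        expected["exacerbations_registered"] = (4, 10)
        for item_id, (num, den) in expected.items():
            got = _item(report, item_id).cohort
            assert (got.numerator, got.denominator) == (num, den), item_id
        assert report.regimen_by_gold == {
            "A": {"one_LABD": 1},
            "B": {"none": 1},
            "D": {"triple": 1},
        }

    def test_every_printed_count_recounts(self, hand_cohort):
        from coach_audit.aggregation import AUDIT_ITEMS_BY_ID

        report = build_report(hand_cohort)
        for ir in report.items:
            item = AUDIT_ITEMS_BY_ID[ir.cohort.item_id]
            eligible = [r for r in hand_cohort if item.denominator(r)]
            assert ir.cohort.denominator == len(eligible)
            assert ir.cohort.numerator == sum(1 for r in eligible if item.numerator(r))


class TestReportProperties:
    def test_regimen_percentages_close_to_hundred(self, small_cohort):
        _, _, records = small_cohort
        report = build_report(records)
        total = sum(_item(report, i).cohort.pct for i in REGIMEN_TABLE_ITEMS)
        assert total == pytest.approx(100.0, abs=0.1)

    def test_audit_is_deterministic(self, tmp_path, small_cohort):
        _, _, records = small_cohort
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        frame1 = report_to_frame(run_audit(path))
        frame2 = report_to_frame(run_audit(path))
        assert frame1.equals(frame2)

    def test_saturated_cohort_scores_hundred_percent(self):
        records = [
            make_record(
                patient_id=f"p{i}", center_id=f"C{i % 2}", region_id="R1",
                smoking_status="active", exposure_flags=frozenset({"active_smoking"}),
                spirometries=(spiro(ratio=55.0),), mmrc=4, exacerbations_prev_year=3,
                exacerbations_registered=True, inhaled_lines=(("LABA", "ICS"), ("LAMA",)),
            )
            for i in range(20)
        ]
        report = build_report(records)
        diag = _item(report, "correct_diagnosis_components").cohort
        assert diag.pct == 100.0 and diag.band == "excellent"
        assert _item(report, "regimen_triple").cohort.pct == 100.0
        assert report.regimen_by_gold == {"D": {"triple": 20}}

    def test_written_outputs(self, tmp_path, small_cohort):
        _, _, records = small_cohort
        report = build_report(records)
        paths = write_report(report, tmp_path)
        assert paths["csv"].exists() and paths["markdown"].exists()
        assert "Diagnosis and clinical evaluation" in report_to_markdown(report)


class TestFigures:
    def test_figures_rendered(self, tmp_path, small_cohort):
        _, _, records = small_cohort
        report = build_report(records)
        paths = render_figures(report, tmp_path, fmt="svg")
        assert len(paths) == 2 and all(p.exists() for p in paths)

    def test_empty_gold_subset_skips_second_figure(self, tmp_path, caplog):
        records = [make_record(patient_id=f"p{i}", center_id="C1") for i in range(6)]
        report = build_report(records)
        with caplog.at_level("WARNING"):
            paths = render_figures(report, tmp_path)
        assert len(paths) == 1
        assert any("GOLD" in m for m in caplog.messages)
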