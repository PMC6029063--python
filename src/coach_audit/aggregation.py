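"""Aggregation of patient-level rule outputs into audit-item rates.

Each audit item is a pair of predicates: one selecting the eligible
denominator (usually the whole cohort, sometimes restricted, e.g. sputum
color among cases with chronic bronchitis) and one selecting the numerator.
Rates are computed at cohort, center and region level, graded into five
adequacy bands

    excellent (> 80%), good (60-80%), adequate (40-59%),
    inadequate (20-39%), highly inadequate (< 20%),

and summarized by the inter-center and inter-regional range (lowest and
highest unit-level percentage).  Centers contributing fewer than a minimum
number of audited cases (default 10) are excluded from the inter-center
range; regions below a region-level minimum (default 30) from the
inter-regional range.

Banding always uses the unrounded percentage; rounding (half-up, 1 decimal)
is applied for reporting only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

from . import rules
from .records import PatientRecord

BANDS = ("highly_inadequate", "inadequate", "adequate", "good", "excellent")

DEFAULT_MIN_CENTER_CASES = 10
DEFAULT_MIN_REGION_CASES = 30


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3), as used for reported rates."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float | None:
    """Unrounded percentage; ``None`` marks an undefined rate (0 denominator)."""
    if denominator == 0:
        return None
    if not 0 <= numerator <= denominator:
        raise ValueError(f"need 0 <= numerator <= denominator, got {numerator}/{denominator}")
    return 100.0 * numerator / denominator


def adequacy_band(pct: float) -> str:
    """Grade a compliance percentage into the five adequacy bands.

    Half-open convention: [0,20) highly_inadequate, [20,40) inadequate,
    [40,60) adequate, [60,80] good, (80,100] excellent — the top band is
    printed strictly "> 80%", so 80.0 grades as good.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage out of range: {pct}")
    if pct < 20.0:
        return "highly_inadequate"
    if pct < 40.0:
        return "inadequate"
    if pct < 60.0:
        return "adequate"
    if pct <= 80.0:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class AuditItem:
    """Definition of one audit item: eligibility and success predicates."""

    item_id: str
    label: str
    block: str
    numerator: Callable[[PatientRecord], bool]
    denominator: Callable[[PatientRecord], bool] = lambda r: True


@dataclass(frozen=True)
class AuditItemResult:
    """Numerator/denominator/percentage/band for one item at one level."""

    item_id: str
    level: str  # "cohort" | "center" | "region"
    unit_id: str | None
    numerator: int
    denominator: int
    unit_n_cases: int | None = None  # audited cases at the unit (for exclusion rules)

    @property
    def pct(self) -> float | None:
        return percentage(self.numerator, self.denominator)

    @property
    def pct_reported(self) -> float | None:
        p = self.pct
        return None if p is None else round_half_up(p)

    @property
    def band(self) -> str | None:
        p = self.pct
        return None if p is None else adequacy_band(p)


@dataclass(frozen=True)
class RangeResult:
    """Inter-center / inter-regional range for one item, with exclusions."""

    item_id: str
    inter_center: tuple[float, float] | None
    inter_regional: tuple[float, float] | None
    excluded_centers: tuple[str, ...] = ()
    excluded_regions: tuple[str, ...] = ()


def item_rate(
    records: Sequence[PatientRecord],
    item: AuditItem,
    level: str = "cohort",
    unit_id: str | None = None,
) -> AuditItemResult:
    eligible = [r for r in records if item.denominator(r)]
    num = sum(1 for r in eligible if item.numerator(r))
    return AuditItemResult(
        item_id=item.item_id,
        level=level,
        unit_id=unit_id,
        numerator=num,
        denominator=len(eligible),
        unit_n_cases=len(records) if level != "cohort" else None,
    )


def _group_by(records: Sequence[PatientRecord], attr: str) -> dict[str, list[PatientRecord]]:
    groups: dict[str, list[PatientRecord]] = {}
    for r in records:
        groups.setdefault(getattr(r, attr), []).append(r)
    return groups


def per_unit_rates(
    records: Sequence[PatientRecord], item: AuditItem, level: str
) -> list[AuditItemResult]:
    attr = {"center": "center_id", "region": "region_id"}[level]
    return [
        item_rate(unit_records, item, level=level, unit_id=uid)
        for uid, unit_records in sorted(_group_by(records, attr).items())
    ]


def _bounded_range(
    results: Sequence[AuditItemResult], min_cases: int
) -> tuple[tuple[float, float] | None, tuple[str, ...]]:
    excluded = tuple(
        r.unit_id for r in results if (r.unit_n_cases or 0) < min_cases and r.unit_id is not None
    )
    pcts = [r.pct for r in results if (r.unit_n_cases or 0) >= min_cases and r.pct is not None]
    if not pcts:
        return None, excluded
    return (min(pcts), max(pcts)), excluded


def inter_center_range(
    per_center: Sequence[AuditItemResult], min_cases: int = DEFAULT_MIN_CENTER_CASES
) -> tuple[float, float] | None:
    """Lowest and highest center percentage, skipping small centers.

    Returns ``None`` (undefined-range marker) when no center is eligible.
    """
    ids = {r.item_id for r in per_center}
    if len(ids) > 1:
        raise ValueError(f"mixed items in range computation: {sorted(ids)}")
    bounds, _ = _bounded_range(per_center, min_cases)
    return bounds


def inter_regional_range(
    per_region: Sequence[AuditItemResult], min_region_cases: int = DEFAULT_MIN_REGION_CASES
) -> tuple[float, float] | None:
    ids = {r.item_id for r in per_region}
    if len(ids) > 1:
        raise ValueError(f"mixed items in range computation: {sorted(ids)}")
    bounds, _ = _bounded_range(per_region, min_region_cases)
    return bounds


def compute_ranges(
    records: Sequence[PatientRecord],
    item: AuditItem,
    min_center_cases: int = DEFAULT_MIN_CENTER_CASES,
    min_region_cases: int = DEFAULT_MIN_REGION_CASES,
) -> RangeResult:
    per_center = per_unit_rates(records, item, "center")
    per_region = per_unit_rates(records, item, "region")
    center_bounds, excluded_centers = _bounded_range(per_center, min_center_cases)
    region_bounds, excluded_regions = _bounded_range(per_region, min_region_cases)
    return RangeResult(
        item_id=item.item_id,
        inter_center=center_bounds,
        inter_regional=region_bounds,
        excluded_centers=excluded_centers,
        excluded_regions=excluded_regions,
    )


# ---------------------------------------------------------------------------
# The audit's item registry (report surface)
# ---------------------------------------------------------------------------

def _diag(r: PatientRecord) -> rules.DiagnosisVerdict:
    return rules.evaluate_diagnosis(r)


def _regimen_is(category: str) -> Callable[[PatientRecord], bool]:
    return lambda r: rules.classify_regimen(r) == category


def _reg_flag(flag: str) -> Callable[[PatientRecord], bool]:
    return lambda r: flag in r.nonpharm_registration


def _given_flag(flag: str) -> Callable[[PatientRecord], bool]:
    return lambda r: flag in r.nonpharm_given


def _symptom(flag: str) -> Callable[[PatientRecord], bool]:
    return lambda r: flag in r.symptom_registration


def _comorbidity_group(group: str) -> Callable[[PatientRecord], bool]:
    return lambda r: rules.comorbidity_groups(r)[group]


AUDIT_ITEMS: tuple[AuditItem, ...] = (
    # -- cohort characteristics (demographics / comorbidity groups) ---------
    AuditItem("male_gender", "Male gender", "characteristics", lambda r: r.sex == "male"),
    AuditItem("active_smoker", "Active smoker", "characteristics", lambda r: r.smoking_status == "active"),
    AuditItem("ex_smoker", "Ex-smoker", "characteristics", lambda r: r.smoking_status == "ex"),
    AuditItem("never_smoker", "Life-long never smoker", "characteristics", lambda r: r.smoking_status == "never"),
    AuditItem("smoking_unknown", "Previous smoking status unknown", "characteristics", lambda r: r.smoking_status == "unknown"),
    AuditItem("comorbidity_cardiac", "Comorbidities: cardiac", "characteristics", _comorbidity_group("cardiac")),
    AuditItem("comorbidity_vascular", "Comorbidities: vascular", "characteristics", _comorbidity_group("vascular")),
    AuditItem("comorbidity_neoplasm", "Comorbidities: neoplasms", "characteristics", _comorbidity_group("neoplasm")),
    AuditItem("comorbidity_sleep_apnea", "Comorbidities: sleep apnea", "characteristics", _comorbidity_group("sleep_apnea")),
    AuditItem("comorbidity_eyedrops", "Comorbidities: eyedrops use", "characteristics", _comorbidity_group("eyedrops")),
    AuditItem("comorbidity_psychiatric", "Comorbidities: psychiatric drugs", "characteristics", _comorbidity_group("psychiatric")),
    AuditItem("comorbidity_prostatic", "Comorbidities: prostatic hyperplasia", "characteristics", _comorbidity_group("prostatic_hyperplasia")),
    # -- diagnosis and clinical evaluation -----------------------------------
    AuditItem("correct_diagnosis_components", "Final diagnosis correct: exposure + obstruction", "diagnosis", lambda r: _diag(r).correct_basic),
    AuditItem("correct_diagnosis_symptoms", "Final diagnosis correct: exposure + obstruction + symptoms", "diagnosis", lambda r: _diag(r).correct_with_symptoms),
    AuditItem("dyspnea_registered", "Dyspnea registered", "diagnosis", _symptom("dyspnea_any")),
    AuditItem("dyspnea_mmrc_registered", "Dyspnea registered by mMRC", "diagnosis", _symptom("dyspnea_mMRC")),
    AuditItem("cough_sputum_registered", "Cough and sputum registered", "diagnosis", _symptom("cough_sputum")),
    AuditItem("sputum_color_registered", "Sputum color registered (chronic bronchitis only)", "diagnosis", _symptom("sputum_color"), denominator=lambda r: r.chronic_bronchitis),
    AuditItem("asthma_symptoms_registered", "Asthma symptoms registered", "diagnosis", _symptom("asthma_symptoms")),
    AuditItem("exacerbations_registered", "Exacerbations in the previous year registered", "diagnosis", lambda r: r.exacerbations_registered),
    AuditItem("smoking_status_registered", "Current smoking status registered", "diagnosis", _reg_flag("smoking_status_registered")),
    AuditItem("exercise_registered", "Exercise registered", "diagnosis", _reg_flag("exercise_registered")),
    AuditItem("influenza_vacc_registered", "Influenza vaccination registered", "diagnosis", _reg_flag("influenza_vacc_registered")),
    AuditItem("pneumococcal_vacc_registered", "Pneumococcal vaccination registered", "diagnosis", _reg_flag("pneumococcal_vacc_registered")),
    AuditItem("adverse_effects_registered", "Adverse effects registered", "diagnosis", _reg_flag("adverse_effects_registered")),
    AuditItem("adherence_registered", "Treatment adherence registered", "diagnosis", _reg_flag("adherence_registered")),
    AuditItem("inhaler_satisfaction_registered", "Inhaler satisfaction registered", "diagnosis", _reg_flag("inhaler_satisfaction_registered")),
    # -- treatments ----------------------------------------------------------
    AuditItem("quit_advice", "Recommendations about not smoking", "treatment", _given_flag("quit_advice")),
    AuditItem("exercise_advice", "Perform some exercise", "treatment", _given_flag("exercise_advice")),
    AuditItem("influenza_vaccinated", "Influenza vaccination administered", "treatment", _given_flag("influenza_vaccinated")),
    AuditItem("pneumococcal_vaccinated", "Pneumococcal vaccination administered", "treatment", _given_flag("pneumococcal_vaccinated")),
    AuditItem("regimen_none", "No inhaled treatment/not available", "treatment", _regimen_is("none")),
    AuditItem("regimen_one_labd", "One long-acting bronchodilator", "treatment", _regimen_is("one_LABD")),
    AuditItem("regimen_laba_lama", "LAMA + LABA", "treatment", _regimen_is("LABA_LAMA")),
    AuditItem("regimen_ics_alone", "ICS alone", "treatment", _regimen_is("ICS_alone")),
    AuditItem(
        "regimen_ics_plus_labd",
        "ICS + one long-acting bronchodilator",
        "treatment",
        lambda r: rules.classify_regimen(r) in ("ICS_plus_one_LABD", "LAMA_ICS_other"),
    ),
    AuditItem("regimen_triple", "Triple therapy", "treatment", _regimen_is("triple")),
    AuditItem("ics_lama_noncombined", "Non-combined ICS-LAMA therapy", "treatment", _regimen_is("LAMA_ICS_other")),
    AuditItem(
        "ics_containing",
        "ICS-containing regimens",
        "treatment",
        lambda r: "ICS" in {c for line in r.inhaled_lines for c in line},
    ),
    AuditItem("incorrect_prescription", "Incorrect prescription", "treatment", lambda r: rules.incorrect_prescription(r)[0]),
    AuditItem("oral_roflumilast", "Roflumilast", "treatment", lambda r: "roflumilast" in r.oral_therapies),
    AuditItem("oral_mucolytic", "Mucolytics", "treatment", lambda r: "mucolytic" in r.oral_therapies),
    AuditItem("oral_antibiotic", "Antibiotics", "treatment", lambda r: "antibiotic" in r.oral_therapies),
    AuditItem("oral_methylxanthine", "Methylxanthines", "treatment", lambda r: "methylxanthine" in r.oral_therapies),
    AuditItem("home_ltot", "Long-term oxygen therapy", "treatment", lambda r: "LTOT" in r.home_therapies),
    AuditItem("home_hmv", "Home mechanical ventilation", "treatment", lambda r: "HMV" in r.home_therapies),
    AuditItem("home_nebulized", "Nebulized therapy", "treatment", lambda r: "nebulized" in r.home_therapies),
    AuditItem("gold_classifiable", "GOLD 2017 patient type assessable", "treatment", lambda r: rules.gold_group(r) != "unclassifiable"),
)

AUDIT_ITEMS_BY_ID: dict[str, AuditItem] = {item.item_id: item for item in AUDIT_ITEMS}

#: the mutually exclusive regimen rows of the treatment table (closure: sums to 100%)
REGIMEN_TABLE_ITEMS = (
    "regimen_none",
    "regimen_one_labd",
    "regimen_laba_lama",
    "regimen_ics_alone",
    "regimen_ics_plus_labd",
    "regimen_triple",
)


def regimen_distribution(records: Sequence[PatientRecord]) -> Counter:
    """Counts of the 7 fine-grained regimen categories."""
    return Counter(rules.classify_regimen(r) for r in records)
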