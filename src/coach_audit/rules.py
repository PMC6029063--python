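"""Patient-level adequacy rules for the COPD audit.

Implements every criterion applied to an individual audited case:

* diagnosis correctness — documented exposure to inhalational irritants plus a
  non-reversible airflow obstruction, i.e. an obstructive spirometry at the
  last recorded (audited) visit, preferring post-bronchodilator values and
  falling back to pre-bronchodilator ones when no post-BD test exists;
* GOLD 2017 ABCD typing from symptom burden (mMRC/CAT) and exacerbation risk;
* classification of the inhaled maintenance regimen into the audit's
  mutually exclusive categories;
* detection of incorrect prescriptions (untreated GOLD B–D, ICS monotherapy,
  duplicated drugs across combined and single therapies);
* Charlson and COTE comorbidity indexes and the audit's comorbidity groups.

The obstruction cutoff is a fixed FEV1/FVC ratio below 70% (strict), the GOLD
convention; it is a parameter wherever it is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .records import INHALED_COMPONENTS, PatientRecord, SpirometryResult

OBSTRUCTION_RATIO_THRESHOLD = 70.0

REGIMEN_CATEGORIES = (
    "none",
    "one_LABD",
    "LABA_LAMA",
    "ICS_alone",
    "ICS_plus_one_LABD",
    "LAMA_ICS_other",
    "triple",
)
GOLD_GROUPS = ("A", "B", "C", "D", "unclassifiable")
COMORBIDITY_GROUPS = (
    "cardiac",
    "vascular",
    "neoplasm",
    "psychiatric",
    "sleep_apnea",
    "eyedrops",
    "prostatic_hyperplasia",
)


class RuleInputError(ValueError):
    """Inputs outside the supported vocabulary."""


@dataclass(frozen=True)
class DiagnosisVerdict:
    """Outcome of the diagnosis-adequacy rule for one case."""

    exposure_ok: bool
    obstruction_ok: bool
    symptoms_ok: bool
    spirometry_source: str  # "post_BD" | "pre_BD_fallback" | "none"

    @property
    def correct_basic(self) -> bool:
        return self.exposure_ok and self.obstruction_ok

    @property
    def correct_with_symptoms(self) -> bool:
        return self.correct_basic and self.symptoms_ok


# ---------------------------------------------------------------------------
# Spirometry
# ---------------------------------------------------------------------------

def effective_ratio(spiro: SpirometryResult) -> float | None:
    """FEV1/FVC x 100, recomputed from volumes when the ratio is not recorded."""
    if spiro.ratio_pct is not None:
        return spiro.ratio_pct
    if spiro.fev1_ml is not None and spiro.fvc_ml is not None:
        return 100.0 * spiro.fev1_ml / spiro.fvc_ml
    return None


def has_obstruction(
    spiro: SpirometryResult, ratio_threshold_pct: float = OBSTRUCTION_RATIO_THRESHOLD
) -> bool | None:
    """True iff the FEV1/FVC ratio is strictly below the threshold.

    Returns ``None`` (indeterminate, distinct from False) when neither the
    ratio nor both volumes are available.
    """
    ratio = effective_ratio(spiro)
    if ratio is None:
        return None
    return ratio < ratio_threshold_pct


def select_spirometry(record: PatientRecord, visit: str) -> tuple[SpirometryResult | None, str]:
    """Pick the spirometry for a visit: post-BD if present, else pre-BD.

    Returns ``(result, source)`` with source one of ``post_BD``,
    ``pre_BD_fallback`` or ``none``; absence is a valid outcome.
    """
    by_phase = {s.phase: s for s in record.spirometries if s.visit == visit}
    if "post_BD" in by_phase:
        return by_phase["post_BD"], "post_BD"
    if "pre_BD" in by_phase:
        return by_phase["pre_BD"], "pre_BD_fallback"
    return None, "none"


def evaluate_diagnosis(
    record: PatientRecord, ratio_threshold_pct: float = OBSTRUCTION_RATIO_THRESHOLD
) -> DiagnosisVerdict:
    """Apply the diagnosis-adequacy rule.

    Exposure is any documented inhalational exposure; obstruction must be
    present at the last recorded (audited) visit to count as non-reversible;
    symptoms means a registered evaluation of dyspnea or chronic
    cough/sputum.  A case without any audited-visit spirometry fails the
    obstruction component (source ``none``).
    """
    exposure_ok = bool(record.exposure_flags)
    spiro, source = select_spirometry(record, "audited_last")
    obstruction_ok = False
    if spiro is not None:
        obstruction_ok = has_obstruction(spiro, ratio_threshold_pct) is True
    symptoms_ok = bool({"dyspnea_any", "cough_sputum"} & record.symptom_registration)
    return DiagnosisVerdict(
        exposure_ok=exposure_ok,
        obstruction_ok=obstruction_ok,
        symptoms_ok=symptoms_ok,
        spirometry_source=source,
    )


# ---------------------------------------------------------------------------
# Inhaled regimen
# ---------------------------------------------------------------------------

def _component_multiset(record: PatientRecord) -> Counter:
    counts: Counter = Counter()
    for line in record.inhaled_lines:
        for component in line:
            if component not in INHALED_COMPONENTS:
                raise RuleInputError(f"unknown inhaled component {component!r}")
            counts[component] += 1
    return counts


def classify_regimen(record: PatientRecord) -> str:
    """Map the de-duplicated component set to one regimen category.

    Categories are mutually exclusive and exhaustive over the 8 possible
    subsets of {LABA, LAMA, ICS}; the non-combined-convention pair
    {ICS, LAMA} is tracked separately (``LAMA_ICS_other``).
    """
    present = frozenset(_component_multiset(record))
    mapping = {
        frozenset(): "none",
        frozenset({"LABA"}): "one_LABD",
        frozenset({"LAMA"}): "one_LABD",
        frozenset({"LABA", "LAMA"}): "LABA_LAMA",
        frozenset({"ICS"}): "ICS_alone",
        frozenset({"ICS", "LABA"}): "ICS_plus_one_LABD",
        frozenset({"ICS", "LAMA"}): "LAMA_ICS_other",
        frozenset({"ICS", "LABA", "LAMA"}): "triple",
    }
    return mapping[present]


def has_duplicate_components(record: PatientRecord) -> bool:
    """True iff any component appears more than once across prescription lines.

    Operates on the multiset *before* de-duplication; a fixed-dose combination
    contributes each of its components once per line.
    """
    return any(n > 1 for n in _component_multiset(record).values())


# ---------------------------------------------------------------------------
# GOLD 2017 typing
# ---------------------------------------------------------------------------

def gold_group(record: PatientRecord) -> str:
    """GOLD 2017 ABCD group from symptoms and exacerbation history.

    High symptom burden: mMRC >= 2 or CAT >= 10.  High risk: >= 2
    exacerbations or >= 1 hospitalization in the previous year.  The case is
    unclassifiable when both symptom scores are unknown or when the
    exacerbation count is unknown (an unknown hospitalization count alone
    contributes no risk).
    """
    if (record.mmrc is None and record.cat is None) or record.exacerbations_prev_year is None:
        return "unclassifiable"
    high_symptom = (record.mmrc is not None and record.mmrc >= 2) or (
        record.cat is not None and record.cat >= 10
    )
    hosp = record.hospitalizations_prev_year or 0
    high_risk = record.exacerbations_prev_year >= 2 or hosp >= 1
    if high_risk:
        return "D" if high_symptom else "C"
    return "B" if high_symptom else "A"


def incorrect_prescription(
    record: PatientRecord, group: str | None = None, regimen: str | None = None
) -> tuple[bool, list[str]]:
    """Detect the audit's incorrect-prescription scenarios.

    Fires (with reason codes) for: GOLD B–D patients without any inhaled
    maintenance medication (``untreated_BD``), any patient on inhaled
    corticosteroids alone (``ics_monotherapy``), and treatment plans that
    duplicate a drug across combined and single therapies
    (``duplicate_therapy``).
    """
    group = gold_group(record) if group is None else group
    regimen = classify_regimen(record) if regimen is None else regimen
    if group not in GOLD_GROUPS:
        raise RuleInputError(f"unknown GOLD group {group!r}")
    if regimen not in REGIMEN_CATEGORIES:
        raise RuleInputError(f"unknown regimen category {regimen!r}")
    reasons = []
    if group in ("B", "C", "D") and regimen == "none":
        reasons.append("untreated_BD")
    if regimen == "ICS_alone":
        reasons.append("ics_monotherapy")
    if has_duplicate_components(record):
        reasons.append("duplicate_therapy")
    return bool(reasons), reasons


# ---------------------------------------------------------------------------
# Comorbidity indexes and groups
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def comorbidity_vocabulary() -> dict:
    """The shipped condition vocabulary with Charlson/COTE weights and groups."""
    text = resources.files("coach_audit.data").joinpath("comorbidity_vocab.yaml").read_text()
    vocab = yaml.safe_load(text)
    if vocab.get("version") != 1:
        raise RuleInputError(f"unsupported comorbidity vocabulary version {vocab.get('version')!r}")
    return vocab["conditions"]


def _check_conditions(record: PatientRecord) -> dict:
    vocab = comorbidity_vocabulary()
    unknown = sorted(set(record.comorbidities) - set(vocab))
    if unknown:
        raise RuleInputError(f"unrecognized condition codes: {unknown}")
    return vocab


def charlson_index(record: PatientRecord) -> int:
    """Charlson comorbidity index with the original (non-age-adjusted) weights."""
    vocab = _check_conditions(record)
    return sum(int(vocab[c]["charlson"]) for c in record.comorbidities)


def cote_index(record: PatientRecord) -> int:
    """COPD-specific comorbidity (COTE) index; anxiety is scored in women only."""
    vocab = _check_conditions(record)
    total = 0
    for c in record.comorbidities:
        entry = vocab[c]
        if entry.get("cote_sex") and entry["cote_sex"] != record.sex:
            continue
        total += int(entry["cote"])
    return total


def comorbidity_groups(record: PatientRecord) -> dict[str, bool]:
    """The audit's comorbidity groupings for one case.

    Cardiac/vascular/neoplasm/sleep-apnea/prostatic-hyperplasia flags follow
    the vocabulary's group memberships (coronary artery disease counts as both
    cardiac and vascular); psychiatric reflects psychotropic medication use;
    eyedrops use is a marker of eye conditions.
    """
    vocab = _check_conditions(record)
    flags = {g: False for g in COMORBIDITY_GROUPS}
    for c in record.comorbidities:
        for g in vocab[c].get("groups") or ():
            flags[g] = True
    flags["psychiatric"] = record.psychiatric_drugs
    flags["eyedrops"] = record.eyedrops
    return flags
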