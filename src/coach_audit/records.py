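"""Domain types for audited COPD cases and their on-disk representation.

A :class:`PatientRecord` is one audited case from a primary care center:
demographics, exposure history, spirometry at the diagnostic and at the last
audited visit, symptom/therapy *registration* flags (the audit measures
documentation, not biology), current treatments and coded comorbidities.
Missingness is always explicit — an item that was not documented is carried
as an unknown value or an unset registration flag, never as an absent field.

Cohorts are written as flat CSV (one row per patient, fixed header, UTF-8,
"." decimal separator), as JSON lines, and accompanied by a centers CSV.
The schema is versioned; readers reject unknown versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SCHEMA_VERSION = "1"

SEXES = ("male", "female")
SMOKING_STATUSES = ("active", "ex", "never", "unknown")
EXPOSURE_FLAGS = ("active_smoking", "passive_smoking", "occupational", "biomass", "other")
SYMPTOM_FLAGS = ("dyspnea_any", "dyspnea_mMRC", "cough_sputum", "sputum_color", "asthma_symptoms")
INHALED_COMPONENTS = ("LABA", "LAMA", "ICS")
ORAL_THERAPIES = ("roflumilast", "mucolytic", "antibiotic", "methylxanthine")
HOME_THERAPIES = ("LTOT", "HMV", "nebulized")
NONPHARM_REGISTRATION_FLAGS = (
    "smoking_status_registered",
    "exercise_registered",
    "influenza_vacc_registered",
    "pneumococcal_vacc_registered",
    "adverse_effects_registered",
    "adherence_registered",
    "inhaler_satisfaction_registered",
)
NONPHARM_GIVEN_FLAGS = (
    "quit_advice",
    "exercise_advice",
    "influenza_vaccinated",
    "pneumococcal_vaccinated",
)
VISITS = ("diagnostic", "audited_last")
PHASES = ("pre_BD", "post_BD")


class RecordError(ValueError):
    """An invalid patient record or cohort file."""


@dataclass(frozen=True)
class SpirometryResult:
    """One spirometry measurement with its bronchodilator phase and visit tag."""

    visit: str
    phase: str
    fev1_ml: float | None = None
    fev1_pct: float | None = None
    fvc_ml: float | None = None
    ratio_pct: float | None = None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise RecordError(f"unknown visit tag {self.visit!r}")
        if self.phase not in PHASES:
            raise RecordError(f"unknown bronchodilator phase {self.phase!r}")
        for name in ("fev1_ml", "fvc_ml"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise RecordError(f"{name} must be positive, got {v}")
        if self.fev1_ml is not None and self.fvc_ml is not None and self.ratio_pct is not None:
            implied = 100.0 * self.fev1_ml / self.fvc_ml
            if abs(implied - self.ratio_pct) > 0.5:
                raise RecordError(
                    f"ratio_pct={self.ratio_pct} inconsistent with volumes (implies {implied:.2f})"
                )


@dataclass(frozen=True)
class PatientRecord:
    """One audited case."""

    patient_id: str
    center_id: str
    region_id: str
    sex: str = "male"
    age_at_audit: float | None = None
    age_at_diagnosis: float | None = None
    smoking_status: str = "unknown"
    pack_years: float | None = None
    exposure_flags: frozenset[str] = frozenset()
    spirometries: tuple[SpirometryResult, ...] = ()
    symptom_registration: frozenset[str] = frozenset()
    chronic_bronchitis: bool = False
    mmrc: int | None = None
    cat: int | None = None
    exacerbations_prev_year: int | None = None
    hospitalizations_prev_year: int | None = None
    exacerbations_registered: bool = False
    inhaled_lines: tuple[tuple[str, ...], ...] = ()
    oral_therapies: frozenset[str] = frozenset()
    home_therapies: frozenset[str] = frozenset()
    nonpharm_registration: frozenset[str] = frozenset()
    nonpharm_given: frozenset[str] = frozenset()
    comorbidities: frozenset[str] = frozenset()
    psychiatric_drugs: bool = False
    eyedrops: bool = False
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RecordError(f"unknown sex {self.sex!r}")
        if self.smoking_status not in SMOKING_STATUSES:
            raise RecordError(f"unknown smoking status {self.smoking_status!r}")
        if self.mmrc is not None and self.mmrc not in range(5):
            raise RecordError(f"mMRC must be 0-4, got {self.mmrc}")
        if self.cat is not None and self.cat not in range(41):
            raise RecordError(f"CAT must be 0-40, got {self.cat}")
        for name in ("exacerbations_prev_year", "hospitalizations_prev_year"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, int) or v < 0):
                raise RecordError(f"{name} must be a non-negative integer, got {v!r}")
        if self.pack_years is not None and self.pack_years < 0:
            raise RecordError(f"pack_years must be non-negative, got {self.pack_years}")
        if unknown := set(self.exposure_flags) - set(EXPOSURE_FLAGS):
            raise RecordError(f"unknown exposure flags {sorted(unknown)}")
        if unknown := set(self.symptom_registration) - set(SYMPTOM_FLAGS):
            raise RecordError(f"unknown symptom flags {sorted(unknown)}")
        if self.smoking_status == "active" and "active_smoking" not in self.exposure_flags:
            raise RecordError("active smoker must carry the active_smoking exposure flag")
        for line in self.inhaled_lines:
            if unknown := set(line) - set(INHALED_COMPONENTS):
                raise RecordError(f"unknown inhaled components {sorted(unknown)}")
        # canonical spirometry order (visit, then phase); at most one per slot
        order = {(v, p): i for i, (v, p) in enumerate((v, p) for v in VISITS for p in PHASES)}
        slots = [(s.visit, s.phase) for s in self.spirometries]
        if len(slots) != len(set(slots)):
            raise RecordError("duplicate spirometry for the same visit and phase")
        object.__setattr__(
            self, "spirometries", tuple(sorted(self.spirometries, key=lambda s: order[(s.visit, s.phase)]))
        )

    def replace(self, **changes) -> "PatientRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class CenterProfile:
    """A participating primary care center; rural means catchment < 25,000 inhabitants."""

    center_id: str
    region_id: str
    population: int
    n_cases: int
    rural_population_cutoff: int = 25_000

    @property
    def rural(self) -> bool:
        return self.population < self.rural_population_cutoff

    def __post_init__(self) -> None:
        if self.population < 0 or self.n_cases < 0:
            raise RecordError("population and n_cases must be non-negative")


# ---------------------------------------------------------------------------
# Flat (CSV / JSON-lines) serialization
# ---------------------------------------------------------------------------

_SET_SEP = ";"
_LINE_SEP = ";"
_COMPONENT_SEP = "+"


def _join(values: Iterable[str]) -> str:
    return _SET_SEP.join(sorted(values))


def _split(cell) -> frozenset[str]:
    if cell is None or cell == "" or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    return frozenset(str(cell).split(_SET_SEP))


def _spiro_columns() -> list[str]:
    cols = []
    for visit in VISITS:
        for phase in PHASES:
            for metric in ("fev1_ml", "fev1_pct", "fvc_ml", "ratio_pct"):
                cols.append(f"spiro_{visit}_{phase}_{metric}")
    return cols


COHORT_COLUMNS: tuple[str, ...] = tuple(
    [
        "schema_version",
        "patient_id",
        "center_id",
        "region_id",
        "sex",
        "age_at_audit",
        "age_at_diagnosis",
        "smoking_status",
        "pack_years",
        "exposure_flags",
    ]
    + _spiro_columns()
    + [
        "symptom_registration",
        "chronic_bronchitis",
        "mmrc",
        "cat",
        "exacerbations_prev_year",
        "hospitalizations_prev_year",
        "exacerbations_registered",
        "inhaled_lines",
        "oral_therapies",
        "home_therapies",
        "nonpharm_registration",
        "nonpharm_given",
        "comorbidities",
        "psychiatric_drugs",
        "eyedrops",
        "bmi",
    ]
)


def record_to_row(record: PatientRecord) -> dict:
    row: dict = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": record.patient_id,
        "center_id": record.center_id,
        "region_id": record.region_id,
        "sex": record.sex,
        "age_at_audit": record.age_at_audit,
        "age_at_diagnosis": record.age_at_diagnosis,
        "smoking_status": record.smoking_status,
        "pack_years": record.pack_years,
        "exposure_flags": _join(record.exposure_flags),
        "symptom_registration": _join(record.symptom_registration),
        "chronic_bronchitis": record.chronic_bronchitis,
        "mmrc": record.mmrc,
        "cat": record.cat,
        "exacerbations_prev_year": record.exacerbations_prev_year,
        "hospitalizations_prev_year": record.hospitalizations_prev_year,
        "exacerbations_registered": record.exacerbations_registered,
        "inhaled_lines": _LINE_SEP.join(
            _COMPONENT_SEP.join(line) for line in record.inhaled_lines
        ),
        "oral_therapies": _join(record.oral_therapies),
        "home_therapies": _join(record.home_therapies),
        "nonpharm_registration": _join(record.nonpharm_registration),
        "nonpharm_given": _join(record.nonpharm_given),
        "comorbidities": _join(record.comorbidities),
        "psychiatric_drugs": record.psychiatric_drugs,
        "eyedrops": record.eyedrops,
        "bmi": record.bmi,
    }
    for col in _spiro_columns():
        row[col] = None
    for s in record.spirometries:
        prefix = f"spiro_{s.visit}_{s.phase}_"
        row[prefix + "fev1_ml"] = s.fev1_ml
        row[prefix + "fev1_pct"] = s.fev1_pct
        row[prefix + "fvc_ml"] = s.fvc_ml
        row[prefix + "ratio_pct"] = s.ratio_pct
    return row


def _opt_float(v) -> float | None:
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def row_to_record(row: dict) -> PatientRecord:
    version = str(row.get("schema_version", "")).strip()
    if version != SCHEMA_VERSION:
        raise RecordError(
            f"unsupported cohort schema version {version!r}; this reader supports {SCHEMA_VERSION!r}"
        )
    spirometries = []
    for visit in VISITS:
        for phase in PHASES:
            prefix = f"spiro_{visit}_{phase}_"
            values = {m: _opt_float(row.get(prefix + m)) for m in ("fev1_ml", "fev1_pct", "fvc_ml", "ratio_pct")}
            if any(v is not None for v in values.values()):
                spirometries.append(SpirometryResult(visit=visit, phase=phase, **values))
    raw_lines = row.get("inhaled_lines")
    if raw_lines is None or (isinstance(raw_lines, float) and pd.isna(raw_lines)):
        raw_lines = ""
    lines = tuple(
        tuple(part.split(_COMPONENT_SEP)) for part in str(raw_lines).split(_LINE_SEP) if part
    )
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        center_id=str(row["center_id"]),
        region_id=str(row["region_id"]),
        sex=str(row["sex"]),
        age_at_audit=_opt_float(row.get("age_at_audit")),
        age_at_diagnosis=_opt_float(row.get("age_at_diagnosis")),
        smoking_status=str(row["smoking_status"]),
        pack_years=_opt_float(row.get("pack_years")),
        exposure_flags=_split(row.get("exposure_flags")),
        spirometries=tuple(spirometries),
        symptom_registration=_split(row.get("symptom_registration")),
        chronic_bronchitis=_as_bool(row.get("chronic_bronchitis", False)),
        mmrc=_opt_int(row.get("mmrc")),
        cat=_opt_int(row.get("cat")),
        exacerbations_prev_year=_opt_int(row.get("exacerbations_prev_year")),
        hospitalizations_prev_year=_opt_int(row.get("hospitalizations_prev_year")),
        exacerbations_registered=_as_bool(row.get("exacerbations_registered", False)),
        inhaled_lines=lines,
        oral_therapies=_split(row.get("oral_therapies")),
        home_therapies=_split(row.get("home_therapies")),
        nonpharm_registration=_split(row.get("nonpharm_registration")),
        nonpharm_given=_split(row.get("nonpharm_given")),
        comorbidities=_split(row.get("comorbidities")),
        psychiatric_drugs=_as_bool(row.get("psychiatric_drugs", False)),
        eyedrops=_as_bool(row.get("eyedrops", False)),
        bmi=_opt_float(row.get("bmi")),
    )


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([record_to_row(r) for r in records], columns=list(COHORT_COLUMNS))


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def write_cohort_jsonl(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(record_to_row(r), sort_keys=True) + "\n")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV or JSON-lines file, reporting offending row numbers."""
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
    else:
        frame = pd.read_csv(path, dtype={"schema_version": str})
        rows = frame.to_dict("records")
    records, bad = [], []
    for i, row in enumerate(rows, start=2 if path.suffix == ".csv" else 1):
        try:
            records.append(row_to_record(row))
        except RecordError as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise RecordError("malformed cohort rows:\n" + "\n".join(bad[:20]))
    return records


def write_centers_csv(centers: Sequence[CenterProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "schema_version": SCHEMA_VERSION,
                "center_id": c.center_id,
                "region_id": c.region_id,
                "population": c.population,
                "rural": c.rural,
                "n_cases": c.n_cases,
            }
            for c in centers
        ]
    ).to_csv(path, index=False)


def read_centers(path: str | Path) -> list[CenterProfile]:
    frame = pd.read_csv(path, dtype={"schema_version": str})
    centers = []
    for _, row in frame.iterrows():
        if str(row["schema_version"]) != SCHEMA_VERSION:
            raise RecordError(f"unsupported centers schema version {row['schema_version']!r}")
        centers.append(
            CenterProfile(
                center_id=str(row["center_id"]),
                region_id=str(row["region_id"]),
                population=int(row["population"]),
                n_cases=int(row["n_cases"]),
            )
        )
    return centers
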