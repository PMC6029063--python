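"""Hierarchical synthetic cohort generator for the clinical audit.

Emulates the statistical structure of a nationwide primary-care COPD audit
database: regions contain centers, centers contain audited cases, and every
documentation item carries a per-center and per-region random effect on the
logit scale (the "cluster effect" that makes cases within a center more alike
than across centers).  For a binary item with base prevalence ``p`` a patient
in center ``c`` of region ``r`` is drawn

    Bernoulli( expit( logit(p) + u_c + v_r ) ),
    u_c ~ N(0, center_effect_sd^2),  v_r ~ N(0, region_effect_sd^2),

with independent offsets per (item, center) and (item, region).  Continuous
variables receive a location shift ``u * SD * kappa`` (``kappa`` configurable
per variable, 0 for the FEV1 variables) and are truncated to physiologic
ranges by resampling.  Records are *constructed to realize* drawn outcomes —
e.g. a case drawn "correctly diagnosed" is given documented exposure plus an
obstructive audited-visit spirometry — so the downstream rule engine recovers
the configured prevalences.

The global seed is expanded into independent per-center substreams
(:class:`numpy.random.SeedSequence`), so the cohort is byte-identical for a
fixed (config, seed) regardless of how centers are iterated.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator
from scipy.special import expit, logit

from .records import CenterProfile, PatientRecord, SpirometryResult

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "sample_center_effects",
    "generate_cohort",
    "generate_item_counts",
    "generate_continuous_values",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: physiologic truncation ranges; out-of-range draws are resampled
TRUNCATION_RANGES: dict[str, tuple[float, float]] = {
    "age_years": (35.0, 100.0),
    "fev1_ml": (300.0, 5000.0),
    "fev1_pct": (15.0, 130.0),
    "fev1_fvc_pct": (20.0, 95.0),
    "bmi": (14.0, 55.0),
    "pack_years": (0.0, 150.0),
}

#: marginal distributions used for values that are documented in isolation
_MMRC_MARGINAL = (0.25, 0.30, 0.25, 0.15, 0.05)
_EXAC_MARGINAL = (0.60, 0.25, 0.10, 0.05)
_HOSP_MARGINAL = (0.85, 0.12, 0.03)


class ContinuousParam(BaseModel):
    model_config = ConfigDict(frozen=True)
    mean: float
    sd: float = Field(ge=0)


class GeneratorConfig(BaseModel):
    """All prevalences, effect sizes, hierarchy sizes and the seed."""

    model_config = ConfigDict(frozen=True)

    n_regions: int = Field(default=6, ge=1)
    centers_per_region: int = Field(default=10, ge=1)
    cases_per_center: int = Field(default=80, ge=1)
    center_effect_sd: float = Field(default=0.4, ge=0)
    region_effect_sd: float = Field(default=0.2, ge=0)
    gold_classifiable_fraction: float = Field(default=0.101, ge=0, le=1)
    rural_population_range: tuple[int, int] = (2000, 600_000)
    seed: int = 0
    item_prevalences: dict[str, float] = Field(default_factory=dict)
    categorical_prevalences: dict[str, dict[str, float]] = Field(default_factory=dict)
    condition_prevalences: dict[str, float] = Field(default_factory=dict)
    continuous_params: dict[str, ContinuousParam] = Field(default_factory=dict)
    continuous_kappa: dict[str, float] = Field(default_factory=lambda: {"default": 0.25})

    @field_validator("item_prevalences", "condition_prevalences")
    @classmethod
    def _probabilities(cls, v: dict[str, float], info) -> dict[str, float]:
        for key, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{info.field_name}[{key}]={p} is not a probability")
        return v

    @field_validator("categorical_prevalences")
    @classmethod
    def _distributions(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        for name, dist in v.items():
            if any(not 0.0 <= p <= 1.0 for p in dist.values()):
                raise ValueError(f"categorical_prevalences[{name}] has values outside [0,1]")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"categorical_prevalences[{name}] sums to {total}, not 1")
        return v

    @field_validator("rural_population_range")
    @classmethod
    def _pop_range(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo <= 0 or hi < lo:
            raise ValueError(f"rural_population_range={v} must satisfy 0 < min <= max")
        return v

    @model_validator(mode="after")
    def _consistent_nesting(self) -> "GeneratorConfig":
        items = self.item_prevalences
        p_exac = items.get("exacerbations_registered")
        p_mmrc = items.get("dyspnea_mmrc_registered")
        gcf = self.gold_classifiable_fraction
        if p_exac is not None and p_mmrc is not None:
            if p_exac > 0 and gcf / p_exac > 1 + 1e-9:
                raise ValueError(
                    "gold_classifiable_fraction exceeds exacerbations_registered prevalence"
                )
            if p_exac < 1 and (p_mmrc - gcf) / (1 - p_exac) > 1 + 1e-9:
                raise ValueError("gold_classifiable_fraction incompatible with mMRC prevalence")
            if p_mmrc < gcf - 1e-9:
                raise ValueError("dyspnea_mmrc_registered prevalence below classifiable fraction")
        p_dysp = items.get("dyspnea_registered")
        if p_dysp is not None and p_mmrc is not None and p_dysp < p_mmrc - 1e-9:
            raise ValueError("dyspnea_registered prevalence below dyspnea_mmrc_registered")
        return self

    @property
    def n_centers(self) -> int:
        return self.n_regions * self.centers_per_region

    def kappa(self, variable: str) -> float:
        return self.continuous_kappa.get(variable, self.continuous_kappa.get("default", 0.25))

    def resized(self, **changes) -> "GeneratorConfig":
        """A re-validated copy with the given fields replaced."""
        raw = self.model_dump()
        raw.update(changes)
        return GeneratorConfig(**raw)


def default_config(**overrides) -> GeneratorConfig:
    """The shipped configuration, calibrated to the audit's published marginals."""
    text = resources.files("coach_audit.data").joinpath("default_config.yaml").read_text()
    raw = yaml.safe_load(text)
    raw.pop("schema", None)
    raw.update(overrides)
    return GeneratorConfig(**raw)


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a YAML generator config on top of the shipped defaults.

    Scalar fields replace the defaults; the prevalence mappings are merged
    key-wise, so a config file only needs to list what it changes.  Raises
    :class:`ConfigError` on any defect.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    raw.pop("schema", None)
    base = default_config().model_dump()
    for key, value in raw.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            base[key] = {**base[key], **value}
        else:
            base[key] = value
    try:
        return GeneratorConfig(**base)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Random-effect plumbing
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@lru_cache(maxsize=8192)
def _calibrated_intercept(p: float, sigma: float) -> float:
    """Logit intercept a such that E[expit(a + sigma Z)] = p for Z ~ N(0,1).

    Mean-preserving cluster effects: with the naive intercept logit(p) the
    marginal prevalence drifts away from p (Jensen bias, worst far from 0.5),
    so the intercept is solved by Newton iteration on Gauss-Hermite
    quadrature.  Reduces exactly to logit(p) when sigma = 0.
    """
    a = float(logit(p))
    if sigma == 0.0:
        return a
    z = sigma * _GH_NODES
    for _ in range(60):
        q = expit(a + z)
        mean = float(_GH_WEIGHTS @ q)
        slope = float(_GH_WEIGHTS @ (q * (1.0 - q)))
        step = (p - mean) / max(slope, 1e-300)
        a += step
        if abs(step) < 1e-12:
            break
    return a


def _shifted_prob(p: float, offset: float, sigma: float = 0.0) -> float:
    """Center/region-shifted probability; degenerate probabilities pass through.

    ``sigma`` is the total SD of the random effect the offset was drawn from;
    the intercept is calibrated so the configured ``p`` stays the marginal
    prevalence across clusters.
    """
    if p <= 0.0 or p >= 1.0:
        return p
    if offset == 0.0 and sigma == 0.0:
        return p
    return float(expit(_calibrated_intercept(p, sigma) + offset))


def sample_center_effects(
    config: GeneratorConfig, n_centers: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n_centers`` center offsets from N(0, center_effect_sd^2)."""
    if n_centers < 1:
        raise ConfigError(f"n_centers must be >= 1, got {n_centers}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return rng.normal(0.0, config.center_effect_sd, size=n_centers)


def _effect_keys(config: GeneratorConfig) -> list[str]:
    keys = list(config.item_prevalences)
    keys += [f"cond:{c}" for c in config.condition_prevalences]
    keys += [f"cont:{v}" for v in config.continuous_params]
    for name, dist in config.categorical_prevalences.items():
        keys += [f"cat:{name}:{level}" for level in dist]
    return keys


def _draw_effects(rng: np.random.Generator, keys: Sequence[str], sd: float) -> dict[str, float]:
    values = rng.normal(0.0, sd, size=len(keys)) if sd > 0 else np.zeros(len(keys))
    return dict(zip(keys, values))


def _hierarchy_streams(config: GeneratorConfig):
    root = np.random.SeedSequence(config.seed)
    region_ss, center_parent = root.spawn(2)
    center_seeds = center_parent.spawn(config.n_centers)
    return np.random.default_rng(region_ss), center_seeds


def _draw_trunc(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))  # pathological parameters: clamp


# ---------------------------------------------------------------------------
# Patient construction
# ---------------------------------------------------------------------------

class _CenterSampler:
    """Draws for one center, with that center's (and region's) offsets baked in."""

    def __init__(self, config: GeneratorConfig, rng, u: dict, v: dict):
        self.config = config
        self.rng = rng
        self.u = u
        self.v = v
        self.sigma = math.hypot(config.center_effect_sd, config.region_effect_sd)

    def offset(self, key: str) -> float:
        return self.u.get(key, 0.0) + self.v.get(key, 0.0)

    def bern(self, key: str, p: float | None = None) -> bool:
        base = self.config.item_prevalences[key] if p is None else p
        return bool(self.rng.random() < _shifted_prob(base, self.offset(key), self.sigma))

    def bern_cond(self, key: str) -> bool:
        return self.bern(f"cond:{key}", self.config.condition_prevalences[key])

    def categorical(self, name: str) -> str:
        dist = self.config.categorical_prevalences[name]
        levels = list(dist)
        logits = np.array(
            [math.log(max(dist[l], 1e-12)) + self.offset(f"cat:{name}:{l}") for l in levels]
        )
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        return str(levels[self.rng.choice(len(levels), p=probs)])

    def continuous(self, variable: str, lo: float | None = None, hi: float | None = None) -> float:
        param = self.config.continuous_params[variable]
        rlo, rhi = TRUNCATION_RANGES.get(variable, (-math.inf, math.inf))
        lo = rlo if lo is None else lo
        hi = rhi if hi is None else hi
        shift = self.offset(f"cont:{variable}") * param.sd * self.config.kappa(variable)
        return _draw_trunc(self.rng, param.mean + shift, param.sd, lo, hi)


def _make_spirometry(sampler: _CenterSampler, visit: str, phase: str, ratio: float) -> SpirometryResult:
    fev1 = sampler.continuous("fev1_ml")
    fev1_pct = sampler.continuous("fev1_pct")
    return SpirometryResult(
        visit=visit,
        phase=phase,
        fev1_ml=round(fev1, 1),
        fev1_pct=round(fev1_pct, 1),
        fvc_ml=round(100.0 * fev1 / ratio, 1),
        ratio_pct=round(ratio, 1),
    )


def _regimen_lines(sampler: _CenterSampler, regimen: str) -> tuple[tuple[str, ...], ...]:
    rng = sampler.rng
    if regimen == "none":
        return ()
    if regimen == "one_LABD":
        return ((("LABA",) if rng.random() < 0.5 else ("LAMA",)),)
    if regimen == "LABA_LAMA":
        return (("LABA", "LAMA"),) if rng.random() < 0.5 else (("LABA",), ("LAMA",))
    if regimen == "ICS_alone":
        return (("ICS",),)
    if regimen == "ICS_plus_one_LABD":
        return (("LABA", "ICS"),) if rng.random() < 0.8 else (("LABA",), ("ICS",))
    if regimen == "LAMA_ICS_other":
        return (("LAMA",), ("ICS",))  # never a combined inhaler, by convention
    if regimen == "triple":
        return (("LABA", "ICS"), ("LAMA",)) if rng.random() < 0.8 else (("LABA",), ("LAMA",), ("ICS",))
    raise ConfigError(f"unknown regimen category {regimen!r}")


def _generate_patient(sampler: _CenterSampler, patient_id: str, center_id: str, region_id: str) -> PatientRecord:
    cfg = sampler.config
    rng = sampler.rng
    items = cfg.item_prevalences

    sex = sampler.categorical("sex")
    age = sampler.continuous("age_years")
    age_dx = max(30.0, age - float(np.clip(rng.normal(6.0, 4.0), 0.0, 30.0)))
    smoking = sampler.categorical("smoking_status")

    pack_years: float | None
    if smoking in ("active", "ex"):
        pack_years = sampler.continuous("pack_years") if sampler.bern("pack_years_registered") else None
    elif smoking == "never":
        pack_years = 0.0
    else:
        pack_years = None

    exposure = set()
    if smoking in ("active", "ex"):
        exposure.add("active_smoking")
    if sampler.bern("exposure_passive"):
        exposure.add("passive_smoking")
    if sampler.bern("exposure_occupational"):
        exposure.add("occupational")
    if sampler.bern("exposure_biomass"):
        exposure.add("biomass")

    # --- diagnosis outcome drives exposure + audited-visit spirometry -------
    correct = sampler.bern("correct_diagnosis_components")
    spirometries: list[SpirometryResult] = []
    if sampler.bern("spiro_diagnostic_present"):
        phase = "post_BD" if sampler.bern("spiro_diagnostic_post_bd") else "pre_BD"
        spirometries.append(_make_spirometry(sampler, "diagnostic", phase, sampler.continuous("fev1_fvc_pct")))
    if correct:
        if not exposure:
            exposure.add(str(rng.choice(["occupational", "biomass", "other"])))
        phase = "post_BD" if sampler.bern("spiro_audited_post_bd") else "pre_BD"
        ratio = sampler.continuous("fev1_fvc_pct", hi=69.4)
        spirometries.append(_make_spirometry(sampler, "audited_last", phase, ratio))
    elif exposure:
        # exposure is documented, so obstruction must fail: either no
        # audited-visit spirometry at all, or a non-obstructive one
        if rng.random() < 0.5:
            phase = "post_BD" if sampler.bern("spiro_audited_post_bd") else "pre_BD"
            spirometries.append(_make_spirometry(sampler, "audited_last", phase, sampler.continuous("fev1_fvc_pct", lo=70.5)))
    else:
        if rng.random() < 0.45:
            phase = "post_BD" if sampler.bern("spiro_audited_post_bd") else "pre_BD"
            spirometries.append(_make_spirometry(sampler, "audited_last", phase, sampler.continuous("fev1_fvc_pct")))

    # --- symptom and exacerbation documentation ----------------------------
    p_exac = items["exacerbations_registered"]
    p_mmrc = items["dyspnea_mmrc_registered"]
    gcf = cfg.gold_classifiable_fraction
    exac_reg = sampler.bern("exacerbations_registered")
    if p_exac in (0.0, 1.0):
        p_mmrc_cond = p_mmrc
    elif exac_reg:
        p_mmrc_cond = min(1.0, gcf / p_exac)
    else:
        p_mmrc_cond = min(1.0, max(0.0, (p_mmrc - gcf) / (1.0 - p_exac)))
    mmrc_reg = sampler.bern("dyspnea_mmrc_registered", p_mmrc_cond)
    p_dysp = items["dyspnea_registered"]
    if mmrc_reg:
        dysp_reg = True
    else:
        q = (p_dysp - p_mmrc) / (1.0 - p_mmrc) if p_mmrc < 1.0 else 0.0
        dysp_reg = sampler.bern("dyspnea_registered", min(1.0, max(0.0, q)))
    cough_reg = sampler.bern("cough_sputum_registered")
    cb = sampler.bern("chronic_bronchitis")
    sputum_color = cb and sampler.bern("sputum_color_given_cb")
    asthma_reg = sampler.bern("asthma_symptoms_registered")

    symptoms = set()
    if dysp_reg:
        symptoms.add("dyspnea_any")
    if mmrc_reg:
        symptoms.add("dyspnea_mMRC")
    if cough_reg:
        symptoms.add("cough_sputum")
    if sputum_color:
        symptoms.add("sputum_color")
    if asthma_reg:
        symptoms.add("asthma_symptoms")

    # --- GOLD 2017 inputs ---------------------------------------------------
    cat_reg = mmrc_reg and sampler.bern("cat_registered", min(1.0, items["cat_registered"] / max(p_mmrc, 1e-12)))
    mmrc = cat_score = exac = hosp = None
    if mmrc_reg and exac_reg:
        group = sampler.categorical("gold_group")
        high_symptom = group in ("B", "D")
        high_risk = group in ("C", "D")
        mmrc = int(rng.integers(2, 5)) if high_symptom else int(rng.integers(0, 2))
        if cat_reg:
            cat_score = int(rng.integers(10, 41)) if high_symptom else int(rng.integers(0, 10))
        if high_risk:
            if rng.random() < 0.7:
                exac = int(rng.integers(2, 6))
                hosp = int(rng.integers(0, 3))
            else:
                exac = int(rng.integers(0, 2))
                hosp = int(rng.integers(1, 3))
        else:
            exac = int(rng.integers(0, 2))
            hosp = 0
    elif mmrc_reg:
        mmrc = int(rng.choice(5, p=_MMRC_MARGINAL))
        if cat_reg:
            cat_score = int(rng.integers(10, 41)) if mmrc >= 2 else int(rng.integers(0, 10))
    elif exac_reg:
        exac = int(rng.choice(4, p=_EXAC_MARGINAL))
        hosp = int(rng.choice(3, p=_HOSP_MARGINAL))

    # --- therapies ----------------------------------------------------------
    regimen = sampler.categorical("regimen")
    lines = list(_regimen_lines(sampler, regimen))
    if lines and sampler.bern("duplicate_prescription"):
        components = [c for line in lines for c in line]
        lines.append((str(rng.choice(components)),))

    oral = {t for t in ("roflumilast", "mucolytic", "antibiotic", "methylxanthine") if sampler.bern(t)}
    home_map = {"ltot": "LTOT", "hmv": "HMV", "nebulized": "nebulized"}
    home = {label for key, label in home_map.items() if sampler.bern(key)}

    registration = set()
    for flag in (
        "smoking_status_registered",
        "exercise_registered",
        "influenza_vacc_registered",
        "pneumococcal_vacc_registered",
        "adverse_effects_registered",
        "adherence_registered",
        "inhaler_satisfaction_registered",
    ):
        if sampler.bern(flag):
            registration.add(flag)

    def _given(flag: str, registered_flag: str) -> bool:
        if registered_flag not in registration:
            return False
        p_reg = items[registered_flag]
        cond = min(1.0, items[flag] / p_reg) if p_reg > 0 else 0.0
        return sampler.bern(flag, cond)

    given = set()
    if _given("quit_advice", "smoking_status_registered"):
        given.add("quit_advice")
    if _given("exercise_advice", "exercise_registered"):
        given.add("exercise_advice")
    if _given("influenza_vaccinated", "influenza_vacc_registered"):
        given.add("influenza_vaccinated")
    if _given("pneumococcal_vaccinated", "pneumococcal_vacc_registered"):
        given.add("pneumococcal_vaccinated")

    # --- comorbidities ------------------------------------------------------
    comorbidities = set()
    p_male = cfg.categorical_prevalences["sex"].get("male", 0.5)
    for cond_name, p in cfg.condition_prevalences.items():
        if cond_name == "prostatic_hyperplasia":
            if sex != "male":
                continue
            p = min(1.0, p / max(p_male, 1e-12))
            if sampler.bern(f"cond:{cond_name}", p):
                comorbidities.add(cond_name)
        elif sampler.bern_cond(cond_name):
            comorbidities.add(cond_name)

    return PatientRecord(
        patient_id=patient_id,
        center_id=center_id,
        region_id=region_id,
        sex=sex,
        age_at_audit=round(age, 1),
        age_at_diagnosis=round(age_dx, 1),
        smoking_status=smoking,
        pack_years=None if pack_years is None else round(pack_years, 1),
        exposure_flags=frozenset(exposure),
        spirometries=tuple(spirometries),
        symptom_registration=frozenset(symptoms),
        chronic_bronchitis=cb,
        mmrc=mmrc,
        cat=cat_score,
        exacerbations_prev_year=exac,
        hospitalizations_prev_year=hosp,
        exacerbations_registered=exac_reg,
        inhaled_lines=tuple(lines),
        oral_therapies=frozenset(oral),
        home_therapies=frozenset(home),
        nonpharm_registration=frozenset(registration),
        nonpharm_given=frozenset(given),
        comorbidities=frozenset(comorbidities),
        psychiatric_drugs=sampler.bern("psychiatric_drugs"),
        eyedrops=sampler.bern("eyedrops"),
        bmi=round(sampler.continuous("bmi"), 1),
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

#: item/categorical/continuous keys the patient constructor requires
REQUIRED_ITEM_KEYS = (
    "correct_diagnosis_components", "spiro_audited_post_bd", "spiro_diagnostic_present",
    "spiro_diagnostic_post_bd", "dyspnea_registered", "dyspnea_mmrc_registered",
    "cat_registered", "cough_sputum_registered", "chronic_bronchitis", "sputum_color_given_cb",
    "asthma_symptoms_registered", "exacerbations_registered", "smoking_status_registered",
    "exercise_registered", "influenza_vacc_registered", "pneumococcal_vacc_registered",
    "adverse_effects_registered", "adherence_registered", "inhaler_satisfaction_registered",
    "quit_advice", "exercise_advice", "influenza_vaccinated", "pneumococcal_vaccinated",
    "duplicate_prescription", "exposure_passive", "exposure_occupational", "exposure_biomass",
    "pack_years_registered", "psychiatric_drugs", "eyedrops", "roflumilast", "mucolytic",
    "antibiotic", "methylxanthine", "ltot", "hmv", "nebulized",
)
REQUIRED_CATEGORICALS = ("sex", "smoking_status", "regimen", "gold_group")
REQUIRED_CONTINUOUS = ("age_years", "fev1_ml", "fev1_pct", "fev1_fvc_pct", "bmi", "pack_years")


def _check_complete(config: GeneratorConfig) -> None:
    missing = [k for k in REQUIRED_ITEM_KEYS if k not in config.item_prevalences]
    missing += [f"categorical_prevalences.{k}" for k in REQUIRED_CATEGORICALS if k not in config.categorical_prevalences]
    missing += [f"continuous_params.{k}" for k in REQUIRED_CONTINUOUS if k not in config.continuous_params]
    if missing:
        raise ConfigError(f"config incomplete for cohort generation; missing: {missing}")


def generate_cohort(config: GeneratorConfig) -> tuple[list[CenterProfile], list[PatientRecord]]:
    """Generate the full hierarchical cohort: region -> center -> patient."""
    _check_complete(config)
    keys = _effect_keys(config)
    region_rng, center_seeds = _hierarchy_streams(config)
    region_ids = [f"R{i + 1:02d}" for i in range(config.n_regions)]
    region_effects = {rid: _draw_effects(region_rng, keys, config.region_effect_sd) for rid in region_ids}

    centers: list[CenterProfile] = []
    records: list[PatientRecord] = []
    lo, hi = config.rural_population_range
    idx = 0
    for r, region_id in enumerate(region_ids):
        for _ in range(config.centers_per_region):
            center_id = f"C{idx + 1:03d}"
            rng = np.random.default_rng(center_seeds[idx])
            population = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
            u = _draw_effects(rng, keys, config.center_effect_sd)
            sampler = _CenterSampler(config, rng, u, region_effects[region_id])
            for i in range(config.cases_per_center):
                records.append(
                    _generate_patient(sampler, f"{center_id}-P{i + 1:03d}", center_id, region_id)
                )
            centers.append(
                CenterProfile(
                    center_id=center_id,
                    region_id=region_id,
                    population=population,
                    n_cases=config.cases_per_center,
                )
            )
            idx += 1
    return centers, records


def generate_item_counts(config: GeneratorConfig, item_id: str) -> pd.DataFrame:
    """Per-center success counts for a single binary item.

    Follows the same hierarchy and substream layout as
    :func:`generate_cohort` but samples only the one item, which makes
    replicate-heavy calibration studies cheap.  Columns: ``center_id``,
    ``region_id``, ``n``, ``successes``.
    """
    p = config.item_prevalences[item_id]
    region_rng, center_seeds = _hierarchy_streams(config)
    region_ids = [f"R{i + 1:02d}" for i in range(config.n_regions)]
    v = {rid: (region_rng.normal(0.0, config.region_effect_sd) if config.region_effect_sd > 0 else 0.0) for rid in region_ids}
    rows = []
    idx = 0
    for region_id in region_ids:
        for _ in range(config.centers_per_region):
            rng = np.random.default_rng(center_seeds[idx])
            u = rng.normal(0.0, config.center_effect_sd) if config.center_effect_sd > 0 else 0.0
            p_c = _shifted_prob(p, u + v[region_id], math.hypot(config.center_effect_sd, config.region_effect_sd))
            successes = int(rng.binomial(config.cases_per_center, p_c))
            rows.append(
                {
                    "center_id": f"C{idx + 1:03d}",
                    "region_id": region_id,
                    "n": config.cases_per_center,
                    "successes": successes,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def generate_continuous_values(config: GeneratorConfig, variable: str) -> list[np.ndarray]:
    """Per-center samples of one continuous variable (truncated by resampling)."""
    param = config.continuous_params[variable]
    lo, hi = TRUNCATION_RANGES.get(variable, (-math.inf, math.inf))
    kappa = config.kappa(variable)
    region_rng, center_seeds = _hierarchy_streams(config)
    region_ids = [f"R{i + 1:02d}" for i in range(config.n_regions)]
    v = {rid: (region_rng.normal(0.0, config.region_effect_sd) if config.region_effect_sd > 0 else 0.0) for rid in region_ids}
    groups = []
    idx = 0
    for region_id in region_ids:
        for _ in range(config.centers_per_region):
            rng = np.random.default_rng(center_seeds[idx])
            u = rng.normal(0.0, config.center_effect_sd) if config.center_effect_sd > 0 else 0.0
            shift = (u + v[region_id]) * param.sd * kappa
            values = rng.normal(param.mean + shift, param.sd, size=config.cases_per_center)
            bad = (values < lo) | (values > hi)
            while bad.any():
                values[bad] = rng.normal(param.mean + shift, param.sd, size=int(bad.sum()))
                bad = (values < lo) | (values > hi)
            groups.append(values)
            idx += 1
    return groups
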