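"""Heterogeneity tests across centers and regions.

Quantitative variables: the Levene test (classic, group-mean centered)
checks homoscedasticity first; if variances are judged equal the one-way
ANOVA F test is used, otherwise Welch's heteroscedastic one-way test.
Categorical variables: Pearson chi-square test of homogeneity on the
groups x categories contingency table, without continuity correction.
Alpha is 0.05, two-tailed, and no multiple-testing correction is applied
across items.

Degenerate inputs follow one policy: groups with no variance anywhere carry
no evidence of heterogeneity and return statistic 0, p = 1 rather than
raising, so that pathological synthetic fixtures cannot crash the dispatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

from . import rules
from .records import PatientRecord

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class StatInputError(ValueError):
    """Degenerate or malformed inputs to a variability test."""


@dataclass(frozen=True)
class VariabilityResult:
    """Outcome of one heterogeneity test."""

    variable_id: str
    grouping: str  # "center" | "region"
    test_used: str  # "anova" | "welch" | "chi_square"
    statistic: float
    p_value: float
    levene_p: float | None
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _validated_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatInputError(f"need >= 2 groups, got {len(arrays)}")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise StatInputError(f"group {i} has fewer than 2 observations")
        if not np.isfinite(a).all():
            raise StatInputError(f"group {i} contains non-finite values")
    return arrays


def levene_test(
    groups: Sequence[Sequence[float]], center: str = "mean"
) -> tuple[float, float]:
    """Levene's test for equality of variances (classic, mean-centered).

    All-constant groups (zero within-group deviation everywhere) return
    ``(0.0, 1.0)``: no evidence of variance inequality.
    """
    arrays = _validated_groups(groups)
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, 1.0
    stat, p = stats.levene(*arrays, center=center)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def anova_or_welch(
    groups: Sequence[Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    variable_id: str = "",
    grouping: str = "center",
) -> VariabilityResult:
    """Levene-gated dispatch between one-way ANOVA and Welch's test."""
    arrays = _validated_groups(groups)
    _, levene_p = levene_test(arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all observations identical
        return VariabilityResult(variable_id, grouping, "anova", 0.0, 1.0, levene_p, alpha)
    if levene_p < alpha:
        res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        return VariabilityResult(
            variable_id, grouping, "welch", float(res.statistic), float(res.pvalue), levene_p, alpha
        )
    stat, p = stats.f_oneway(*arrays)
    if not np.isfinite(stat):  # identical group means with zero within-variance
        stat, p = 0.0, 1.0
    return VariabilityResult(variable_id, grouping, "anova", float(stat), float(p), levene_p, alpha)


def chi_square_homogeneity(table) -> tuple[float, float]:
    """Pearson chi-square of homogeneity with (r-1)(c-1) degrees of freedom.

    ``table`` is a groups x categories count matrix; a zero row or column
    margin is rejected as an input error.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise StatInputError(f"need at least a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise StatInputError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise StatInputError("zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass(frozen=True)
class VariableSpec:
    """A variable to test: quantitative (accessor -> float) or categorical."""

    variable_id: str
    kind: str  # "quantitative" | "categorical"
    accessor: Callable[[PatientRecord], object]


def _contingency(
    records: Sequence[PatientRecord], spec: VariableSpec, attr: str
) -> np.ndarray:
    units = sorted({getattr(r, attr) for r in records})
    values = sorted({str(spec.accessor(r)) for r in records})
    table = np.zeros((len(units), len(values)))
    unit_ix = {u: i for i, u in enumerate(units)}
    value_ix = {v: j for j, v in enumerate(values)}
    for r in records:
        table[unit_ix[getattr(r, attr)], value_ix[str(spec.accessor(r))]] += 1
    # unused categories and empty units carry no information
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def variability_table(
    records: Sequence[PatientRecord],
    variables: Sequence[VariableSpec],
    grouping: str = "center",
    alpha: float = DEFAULT_ALPHA,
) -> list[VariabilityResult]:
    """Run the per-variable heterogeneity tests for the report's p-value column."""
    attr = {"center": "center_id", "region": "region_id"}[grouping]
    results: list[VariabilityResult] = []
    for spec in variables:
        if spec.kind == "quantitative":
            by_unit: dict[str, list[float]] = {}
            for r in records:
                v = spec.accessor(r)
                if v is not None:
                    by_unit.setdefault(getattr(r, attr), []).append(float(v))
            groups = [g for g in by_unit.values() if len(g) >= 2]
            if len(groups) < 2:
                logger.warning("variable %s: fewer than 2 usable groups; skipped", spec.variable_id)
                results.append(VariabilityResult(spec.variable_id, grouping, "anova", 0.0, 1.0, None, alpha))
                continue
            res = anova_or_welch(groups, alpha, spec.variable_id, grouping)
            results.append(res)
        elif spec.kind == "categorical":
            table = _contingency(records, spec, attr)
            if table.shape[0] < 2 or table.shape[1] < 2:  # no variation left to test
                results.append(
                    VariabilityResult(spec.variable_id, grouping, "chi_square", 0.0, 1.0, None, alpha)
                )
                continue
            stat, p = chi_square_homogeneity(table)
            results.append(VariabilityResult(spec.variable_id, grouping, "chi_square", stat, p, None, alpha))
        else:
            raise StatInputError(f"variable {spec.variable_id!r} has unknown kind {spec.kind!r}")
    return results


# ---------------------------------------------------------------------------
# Standard quantitative variables of the report
# ---------------------------------------------------------------------------

def _current_spiro_value(metric: str) -> Callable[[PatientRecord], float | None]:
    def accessor(record: PatientRecord) -> float | None:
        spiro, _ = rules.select_spirometry(record, "audited_last")
        return None if spiro is None else getattr(spiro, metric)

    return accessor


QUANTITATIVE_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("age_years", "quantitative", lambda r: r.age_at_audit),
    VariableSpec("pack_years", "quantitative", lambda r: r.pack_years),
    VariableSpec("charlson_index", "quantitative", rules.charlson_index),
    VariableSpec("cote_index", "quantitative", rules.cote_index),
    VariableSpec("bmi", "quantitative", lambda r: r.bmi),
    VariableSpec("fev1_ml", "quantitative", _current_spiro_value("fev1_ml")),
    VariableSpec("fev1_pct", "quantitative", _current_spiro_value("fev1_pct")),
    VariableSpec("fev1_fvc_pct", "quantitative", _current_spiro_value("ratio_pct")),
)
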