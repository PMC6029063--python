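"""Report assembly: the audit's tables and figures from any cohort file.

:func:`run_audit` reads a cohort (CSV or JSON lines), evaluates every audit
item at cohort/center/region level, attaches the inter-center and
inter-regional ranges (with the small-unit exclusions) and the heterogeneity
p-values, and returns an :class:`AuditReport`.  The report renders to a tidy
CSV (one row per item and level) and to Markdown; :func:`render_figures`
draws the regimen-distribution bar chart and its breakdown by GOLD 2017
group, skipping the latter with a warning when no case is classifiable.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .aggregation import (
    AUDIT_ITEMS,
    DEFAULT_MIN_CENTER_CASES,
    DEFAULT_MIN_REGION_CASES,
    AuditItemResult,
    RangeResult,
    compute_ranges,
    item_rate,
    regimen_distribution,
    round_half_up,
)
from .records import PatientRecord, read_cohort
from .rules import REGIMEN_CATEGORIES, classify_regimen, gold_group
from .variability import (
    DEFAULT_ALPHA,
    QUANTITATIVE_VARIABLES,
    VariabilityResult,
    VariableSpec,
    variability_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ItemReport:
    """One audit item with its cohort rate, ranges and heterogeneity tests."""

    cohort: AuditItemResult
    ranges: RangeResult
    center_test: VariabilityResult
    region_test: VariabilityResult


@dataclass(frozen=True)
class AuditReport:
    """The full report: item blocks, regimen distributions, metadata."""

    items: tuple[ItemReport, ...]
    quantitative: tuple[VariabilityResult, ...]
    quantitative_region: tuple[VariabilityResult, ...]
    regimen_counts: dict[str, int]
    regimen_by_gold: dict[str, dict[str, int]]
    n_cases: int
    metadata: dict = field(default_factory=dict)

    def block(self, name: str) -> list[ItemReport]:
        from .aggregation import AUDIT_ITEMS_BY_ID

        return [ir for ir in self.items if AUDIT_ITEMS_BY_ID[ir.cohort.item_id].block == name]


def _item_spec(item) -> VariableSpec:
    return VariableSpec(item.item_id, "categorical", item.numerator)


def build_report(
    records: Sequence[PatientRecord],
    alpha: float = DEFAULT_ALPHA,
    min_center_cases: int = DEFAULT_MIN_CENTER_CASES,
    min_region_cases: int = DEFAULT_MIN_REGION_CASES,
    metadata: dict | None = None,
) -> AuditReport:
    if not records:
        raise ValueError("empty cohort")
    items = []
    for item in AUDIT_ITEMS:
        eligible = [r for r in records if item.denominator(r)]
        cohort = item_rate(records, item)
        ranges = compute_ranges(records, item, min_center_cases, min_region_cases)
        spec = _item_spec(item)
        center_test = variability_table(eligible, [spec], "center", alpha)[0]
        region_test = variability_table(eligible, [spec], "region", alpha)[0]
        items.append(ItemReport(cohort, ranges, center_test, region_test))

    quantitative = tuple(variability_table(records, QUANTITATIVE_VARIABLES, "center", alpha))
    quantitative_region = tuple(variability_table(records, QUANTITATIVE_VARIABLES, "region", alpha))

    regimen_counts = dict(regimen_distribution(records))
    by_gold: dict[str, dict[str, int]] = {}
    for r in records:
        g = gold_group(r)
        if g == "unclassifiable":
            continue
        by_gold.setdefault(g, Counter())[classify_regimen(r)] += 1
    regimen_by_gold = {g: dict(c) for g, c in sorted(by_gold.items())}

    return AuditReport(
        items=tuple(items),
        quantitative=quantitative,
        quantitative_region=quantitative_region,
        regimen_counts=regimen_counts,
        regimen_by_gold=regimen_by_gold,
        n_cases=len(records),
        metadata=metadata or {},
    )


def run_audit(cohort_path: str | Path, config_path: str | Path | None = None, alpha: float = DEFAULT_ALPHA) -> AuditReport:
    """Audit a cohort file end to end (deterministic for fixed inputs)."""
    records = read_cohort(cohort_path)
    metadata = {
        "cohort_path": str(cohort_path),
        "cohort_sha256": hashlib.sha256(Path(cohort_path).read_bytes()).hexdigest(),
        "tool_version": __version__,
        "alpha": alpha,
    }
    if config_path is not None:
        metadata["config_path"] = str(config_path)
        metadata["config_sha256"] = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    return build_report(records, alpha=alpha, metadata=metadata)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def report_to_frame(report: AuditReport) -> pd.DataFrame:
    """Tidy results table: item_id, level, numerator, denominator, pct, band, ranges, p-values."""
    rows = []
    for ir in report.items:
        c = ir.cohort
        rows.append(
            {
                "item_id": c.item_id,
                "level": "cohort",
                "unit_id": "",
                "numerator": c.numerator,
                "denominator": c.denominator,
                "percentage": c.pct_reported,
                "band": c.band or "",
                "inter_center_low": None if ir.ranges.inter_center is None else round_half_up(ir.ranges.inter_center[0]),
                "inter_center_high": None if ir.ranges.inter_center is None else round_half_up(ir.ranges.inter_center[1]),
                "inter_regional_low": None if ir.ranges.inter_regional is None else round_half_up(ir.ranges.inter_regional[0]),
                "inter_regional_high": None if ir.ranges.inter_regional is None else round_half_up(ir.ranges.inter_regional[1]),
                "center_test": ir.center_test.test_used,
                "center_p": ir.center_test.p_value,
                "region_test": ir.region_test.test_used,
                "region_p": ir.region_test.p_value,
            }
        )
    for res, res_r in zip(report.quantitative, report.quantitative_region):
        rows.append(
            {
                "item_id": res.variable_id,
                "level": "cohort",
                "unit_id": "",
                "numerator": None,
                "denominator": None,
                "percentage": None,
                "band": "",
                "inter_center_low": None,
                "inter_center_high": None,
                "inter_regional_low": None,
                "inter_regional_high": None,
                "center_test": res.test_used,
                "center_p": res.p_value,
                "region_test": res_r.test_used,
                "region_p": res_r.p_value,
            }
        )
    return pd.DataFrame(rows)


def report_to_markdown(report: AuditReport) -> str:
    from .aggregation import AUDIT_ITEMS_BY_ID

    lines = [
        "# COPD primary-care audit report",
        "",
        f"Cases audited: {report.n_cases}",
        "",
    ]
    for key, value in sorted(report.metadata.items()):
        lines.append(f"- {key}: {value}")
    for block, title in (
        ("characteristics", "Cohort characteristics"),
        ("diagnosis", "Diagnosis and clinical evaluation"),
        ("treatment", "Treatments"),
    ):
        lines += ["", f"## {title}", ""]
        lines.append("| item | n/N | % | band | inter-center range | inter-regional range | P (centers) |")
        lines.append("|---|---|---|---|---|---|---|")
        for ir in report.block(block):
            c = ir.cohort
            label = AUDIT_ITEMS_BY_ID[c.item_id].label
            pct = "-" if c.pct_reported is None else f"{c.pct_reported:.1f}"
            rng = (
                "-"
                if ir.ranges.inter_center is None
                else f"{round_half_up(ir.ranges.inter_center[0]):.1f}-{round_half_up(ir.ranges.inter_center[1]):.1f}"
            )
            rng_r = (
                "-"
                if ir.ranges.inter_regional is None
                else f"{round_half_up(ir.ranges.inter_regional[0]):.1f}-{round_half_up(ir.ranges.inter_regional[1]):.1f}"
            )
            lines.append(
                f"| {label} | {c.numerator}/{c.denominator} | {pct} | {c.band or '-'} | {rng} | {rng_r} | {ir.center_test.p_value:.3g} |"
            )
    lines += [
        "",
        "_No multiple-testing correction is applied across items; p-values are per-item._",
        "",
    ]
    return "\n".join(lines)


def write_report(report: AuditReport, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "audit_results.csv"
    md_path = out / "audit_report.md"
    report_to_frame(report).to_csv(csv_path, index=False)
    md_path.write_text(report_to_markdown(report), encoding="utf-8")
    return {"csv": csv_path, "markdown": md_path}


def render_figures(report: AuditReport, out_dir: str | Path, fmt: str = "svg") -> list[Path]:
    """Bar charts of the regimen distribution, overall and by GOLD group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    total = sum(report.regimen_counts.values())
    categories = [c for c in REGIMEN_CATEGORIES]
    pcts = [100.0 * report.regimen_counts.get(c, 0) / total for c in categories]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(categories, pcts, color="#4878a8")
    ax.set_ylabel("% of audited cases")
    ax.set_title("Distribution of maintenance inhaled therapies")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    path = out / f"regimen_distribution.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    paths.append(path)

    if not report.regimen_by_gold:
        logger.warning("no GOLD-classifiable cases; skipping the by-group figure")
        return paths

    groups = sorted(report.regimen_by_gold)
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / len(categories)
    for j, cat in enumerate(categories):
        values = []
        for g in groups:
            n = sum(report.regimen_by_gold[g].values())
            values.append(100.0 * report.regimen_by_gold[g].get(cat, 0) / n if n else 0.0)
        ax.bar([i + j * width for i in range(len(groups))], values, width=width, label=cat)
    ax.set_xticks([i + 0.4 for i in range(len(groups))])
    ax.set_xticklabels([f"GOLD {g}" for g in groups])
    ax.set_ylabel("% within group")
    ax.set_title("Maintenance inhaled therapies by GOLD 2017 group")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = out / f"regimen_by_gold.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    paths.append(path)
    return paths
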