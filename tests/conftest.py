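"""Shared fixtures and record-building helpers."""

from __future__ import annotations

import pytest

from coach_audit.records import PatientRecord, SpirometryResult


def spiro(visit: str = "audited_last", phase: str = "post_BD", ratio: float | None = 55.0,
          fev1_ml: float | None = None, fvc_ml: float | None = None) -> SpirometryResult:
    return SpirometryResult(visit=visit, phase=phase, ratio_pct=ratio, fev1_ml=fev1_ml, fvc_ml=fvc_ml)


def make_record(**kwargs) -> PatientRecord:
    """A minimal valid audited case; override any field via keyword."""
    defaults = dict(
        patient_id="P1",
        center_id="C001",
        region_id="R01",
        sex="male",
        smoking_status="unknown",
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


def correctly_diagnosed_record(**kwargs) -> PatientRecord:
    """An active smoker with an obstructive post-BD audited-visit spirometry."""
    defaults = dict(
        smoking_status="active",
        exposure_flags=frozenset({"active_smoking"}),
        spirometries=(spiro(ratio=55.0),),
    )
    defaults.update(kwargs)
    return make_record(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured synthetic cohort (2 regions x 3 centers x 40)."""
    from coach_audit import default_config, generate_cohort

    config = default_config(n_regions=2, centers_per_region=3, cases_per_center=40, seed=3)
    centers, records = generate_cohort(config)
    return config, centers, records
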