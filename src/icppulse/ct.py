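"""Validation and binarization of per-patient CT assessments.

Midline shift is flagged present when it exceeds 5 mm and mass lesions
when the total lesion volume exceeds 25 cm^3 — both strict inequalities,
so values exactly at the threshold are negative cases. Rows with missing
measurements or scores are excluded listwise (never imputed) and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

from .types import CTAssessment

__all__ = ["binarize_ct", "validate_cohort", "ExclusionReport"]


def binarize_ct(assessment: CTAssessment) -> tuple[bool, bool]:
    """Return ``(mls_present, lesion_present)`` using the strict > 5 mm
    and > 25 cm^3 thresholds. Both flags may be true simultaneously."""
    return assessment.mls_present, assessment.lesion_present


@dataclass
class ExclusionReport:
    """Log of rows removed during cohort validation."""

    n_input: int = 0
    n_retained: int = 0
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, reason)

    def add(self, patient_id: str, reason: str) -> None:
        self.exclusions.append((patient_id, reason))


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def validate_cohort(
    table: list[CTAssessment | dict],
) -> tuple[list[CTAssessment], ExclusionReport]:
    """Listwise-exclude incomplete rows and reject duplicate patients.

    Accepts either constructed :class:`CTAssessment` objects or raw dicts
    (so that rows with missing fields, which the dataclass would refuse,
    can still be logged with a reason).
    """
    report = ExclusionReport(n_input=len(table))
    seen: set[str] = set()
    retained: list[CTAssessment] = []
    for row in table:
        if isinstance(row, CTAssessment):
            ct = row
        else:
            pid = str(row.get("patient_id", "?"))
            missing = [
                k
                for k in ("midline_shift_mm", "lesion_volume_cm3", "marshall", "rotterdam")
                if _missing(row.get(k))
            ]
            if missing:
                report.add(pid, f"missing {', '.join(missing)}")
                continue
            try:
                ct = CTAssessment(
                    pid,
                    float(row["midline_shift_mm"]),
                    float(row["lesion_volume_cm3"]),
                    int(row["marshall"]),
                    int(row["rotterdam"]),
                )
            except (ValueError, TypeError) as exc:
                report.add(pid, f"invalid value: {exc}")
                continue
        if ct.patient_id in seen:
            raise ValueError(f"duplicate patient_id {ct.patient_id!r}")
        seen.add(ct.patient_id)
        retained.append(ct)
    report.n_retained = len(retained)
    if not retained:
        raise ValueError("cohort empty after exclusions")
    return retained, report
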