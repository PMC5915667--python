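"""Patient-selection funnel.

Four filters applied in fixed order: (1) at least two HbA1c test results;
(2) no comorbidities or diabetes-related complications (DCSI and CIC counts
both zero); (3) adherence to the band-dependent test schedule, with a
4-month tolerance; (4) a valid normalized study window of 18±8 months.
The retained set of each stage is a subset of the previous one, and the
stage counts are recorded in a :class:`SelectionReport`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .records import (
    HBA1C_GOAL,
    HBA1C_HIGH,
    DataValidationError,
    Hba1cMeasurement,
    PatientRecord,
    StudyWindow,
    months_between,
)

logger = logging.getLogger(__name__)

#: Protocol test schedule in months for each decompensation band.
TEST_SCHEDULE_MONTHS = {"compensated": 12.0, "moderate": 6.0, "high": 3.0}

#: Default tolerance added to every scheduled interval (months).
DEFAULT_TOLERANCE_MONTHS = 4.0

WINDOW_TARGET_MONTHS = 18.0
WINDOW_HALFWIDTH_MONTHS = 8.0


def hba1c_band(value: float) -> str:
    """Decompensation band of a single HbA1c value (< 7 / [7, 9] / > 9)."""
    if value < HBA1C_GOAL:
        return "compensated"
    if value <= HBA1C_HIGH:
        return "moderate"
    return "high"


def group_measurements(
    measurements: list[Hba1cMeasurement],
) -> dict[str, list[Hba1cMeasurement]]:
    """Group by patient, sort by date and deduplicate exact duplicates.

    Two measurements of the same patient on the same date with different
    values violate the strict date ordering required downstream and raise
    :class:`DataValidationError`.
    """
    grouped: dict[str, list[Hba1cMeasurement]] = defaultdict(list)
    for m in measurements:
        grouped[m.patient_id].append(m)
    out: dict[str, list[Hba1cMeasurement]] = {}
    for pid, rows in grouped.items():
        rows = sorted(set(rows), key=lambda m: (m.date, m.value))
        for a, b in zip(rows, rows[1:]):
            if a.date == b.date:
                raise DataValidationError(
                    f"patient {pid}: conflicting HbA1c values {a.value} and "
                    f"{b.value} on {a.date}"
                )
        out[pid] = rows
    return out


def filter_min_measurements(
    measurements: list[Hba1cMeasurement], min_count: int = 2
) -> set[str]:
    """Patients with at least ``min_count`` distinct HbA1c results."""
    grouped = group_measurements(measurements)
    return {pid for pid, rows in grouped.items() if len(rows) >= min_count}


def filter_comorbidity(patients: list[PatientRecord]) -> set[str]:
    """Patients with both DCSI and CIC counts equal to zero.

    Missing flags are an input error: the filter lists the offending
    patient ids rather than silently including or excluding them.
    """
    missing = [p.patient_id for p in patients if p.dcsi_count is None or p.cic_count is None]
    if missing:
        raise DataValidationError(
            f"missing DCSI/CIC flags for patients: {sorted(missing)}"
        )
    return {p.patient_id for p in patients if p.dcsi_count == 0 and p.cic_count == 0}


def allowed_test_gap(
    previous_value: float, tolerance_months: float = DEFAULT_TOLERANCE_MONTHS
) -> float:
    """Maximum acceptable months until the next HbA1c test.

    The protocol schedule depends on the band of the previous result
    (12 months compensated, 6 moderate, 3 high) and every interval gets
    the same tolerance on top.
    """
    return TEST_SCHEDULE_MONTHS[hba1c_band(previous_value)] + tolerance_months


def filter_adherence(
    measurements: list[Hba1cMeasurement],
    tolerance_months: float = DEFAULT_TOLERANCE_MONTHS,
) -> set[str]:
    """Patients whose every inter-test gap respects the allowed interval.

    The gap between consecutive tests (days / 30.44, boundary inclusive)
    is compared against :func:`allowed_test_gap` of the earlier result.
    Patients with fewer than two tests cannot demonstrate adherence and
    are excluded with a logged reason.
    """
    retained: set[str] = set()
    for pid, rows in group_measurements(measurements).items():
        if len(rows) < 2:
            logger.warning("patient %s: fewer than 2 tests, cannot assess adherence", pid)
            continue
        ok = all(
            months_between(a.date, b.date) <= allowed_test_gap(a.value, tolerance_months)
            for a, b in zip(rows, rows[1:])
        )
        if ok:
            retained.add(pid)
    return retained


def define_study_window(
    measurements: list[Hba1cMeasurement],
    target_months: float = WINDOW_TARGET_MONTHS,
    halfwidth_months: float = WINDOW_HALFWIDTH_MONTHS,
) -> StudyWindow | None:
    """Select the normalized study window for one patient.

    ``t0`` is the first measurement; among measurements whose offset from
    ``t0`` lies within ``target ± halfwidth`` months, the end point is the
    one closest to the target (tie broken toward the earlier, i.e. the
    shorter follow-up). Returns ``None`` when no measurement is in range.
    """
    if not measurements:
        return None
    rows = sorted(measurements, key=lambda m: m.date)
    t0 = rows[0].date
    lo, hi = target_months - halfwidth_months, target_months + halfwidth_months
    best: tuple[float, float] | None = None
    best_row = None
    for m in rows[1:]:
        off = months_between(t0, m.date)
        if lo <= off <= hi:
            key = (abs(off - target_months), off)
            if best is None or key < best:
                best, best_row = key, m
    if best_row is None:
        return None
    return StudyWindow(
        patient_id=rows[0].patient_id,
        t0=t0,
        t_end=best_row.date,
        span_months=months_between(t0, best_row.date),
    )


def window_measurements(
    measurements: list[Hba1cMeasurement], window: StudyWindow
) -> list[Hba1cMeasurement]:
    """Measurements inside [t0, t_end], date-sorted; later ones dropped."""
    rows = [m for m in measurements if window.t0 <= m.date <= window.t_end]
    return sorted(rows, key=lambda m: m.date)


@dataclass
class SelectionReport:
    """Stage counts of the selection funnel (non-increasing)."""

    n_total: int = 0
    n_min_tests: int = 0
    n_no_comorbidity: int = 0
    n_adherent: int = 0
    n_windowed: int = 0
    rejected: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, int]:
        return {
            "total": self.n_total,
            "min_tests": self.n_min_tests,
            "no_comorbidity": self.n_no_comorbidity,
            "adherent": self.n_adherent,
            "windowed": self.n_windowed,
        }


def run_funnel(
    patients: list[PatientRecord],
    measurements: list[Hba1cMeasurement],
    *,
    min_count: int = 2,
    tolerance_months: float = DEFAULT_TOLERANCE_MONTHS,
    target_months: float = WINDOW_TARGET_MONTHS,
    halfwidth_months: float = WINDOW_HALFWIDTH_MONTHS,
) -> tuple[dict[str, StudyWindow], SelectionReport]:
    """Apply the four filters in order and report stage counts.

    Returns the eligible patients' study windows keyed by patient id,
    plus the :class:`SelectionReport`.
    """
    report = SelectionReport()
    all_ids = {p.patient_id for p in patients}
    report.n_total = len(all_ids)

    stage1 = filter_min_measurements(measurements, min_count) & all_ids
    report.n_min_tests = len(stage1)
    for pid in all_ids - stage1:
        report.rejected[pid] = "fewer than minimum HbA1c tests"

    comorbid_free = filter_comorbidity([p for p in patients if p.patient_id in stage1])
    stage2 = stage1 & comorbid_free
    report.n_no_comorbidity = len(stage2)
    for pid in stage1 - stage2:
        report.rejected[pid] = "comorbidity or complication present"

    meas2 = [m for m in measurements if m.patient_id in stage2]
    stage3 = filter_adherence(meas2, tolerance_months) & stage2
    report.n_adherent = len(stage3)
    for pid in stage2 - stage3:
        report.rejected[pid] = "test interval beyond protocol + tolerance"

    grouped = group_measurements([m for m in measurements if m.patient_id in stage3])
    windows: dict[str, StudyWindow] = {}
    for pid in sorted(stage3):
        w = define_study_window(grouped[pid], target_months, halfwidth_months)
        if w is None:
            report.rejected[pid] = "no measurement in the study-window range"
        else:
            windows[pid] = w
    report.n_windowed = len(windows)
    return windows, report
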