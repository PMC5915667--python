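"""Core record types and shared constants.

The pipeline consumes two event streams extracted from an electronic
clinical record: cardiovascular periodic appointments (CVPAs), each
attended by one of the three disciplines of the primary-care triad
(physician ``P``, nurse ``N``, dietitian ``D``), and HbA1c laboratory
results in percent. An optional patient table carries demographics and
precomputed comorbidity/complication counts used only as exclusion flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

#: Canonical discipline codes, in the fixed tie-break order P < N < D.
DISCIPLINES: tuple[str, ...] = ("P", "N", "D")

DISCIPLINE_NAMES = {"P": "physician", "N": "nurse", "D": "dietitian"}

_SYNONYMS = {
    "p": "P", "physician": "P", "doctor": "P", "medic": "P",
    "n": "N", "nurse": "N",
    "d": "D", "dietitian": "D", "dietician": "D", "nutritionist": "D",
}

#: Days per month used throughout the package (mean Gregorian month).
MONTH_DAYS = 30.44

#: HbA1c decompensation bands (percent): < 7 compensated,
#: [7, 9] moderate (inclusive at both ends), > 9 high.
HBA1C_GOAL = 7.0
HBA1C_HIGH = 9.0


class DataValidationError(ValueError):
    """Raised when an input record violates the documented schema."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its documented range."""


def normalize_discipline(token: str) -> str:
    """Map a discipline token (case-insensitive synonym) to P/N/D."""
    code = _SYNONYMS.get(str(token).strip().lower())
    if code is None:
        raise DataValidationError(
            f"unknown discipline {token!r}: expected one of "
            f"{sorted(set(_SYNONYMS))} (triad disciplines only)"
        )
    return code


def months_between(start: date, end: date) -> float:
    """Elapsed time in months (days / 30.44) between two dates."""
    return (end - start).days / MONTH_DAYS


@dataclass(frozen=True, slots=True)
class EncounterRecord:
    """One CVPA: patient, date and attending discipline.

    ``next_discipline``/``next_date`` optionally carry the appointment
    prescribed at the visit; they are used only for descriptive adherence
    reporting, never to build referral arcs.
    """

    patient_id: str
    date: date
    discipline: str
    next_discipline: str | None = None
    next_date: date | None = None

    def __post_init__(self) -> None:
        if self.discipline not in DISCIPLINES:
            raise DataValidationError(
                f"discipline must be one of {DISCIPLINES}, got {self.discipline!r}"
            )
        if self.next_discipline is not None and self.next_discipline not in DISCIPLINES:
            raise DataValidationError(
                f"next_discipline must be one of {DISCIPLINES}, got {self.next_discipline!r}"
            )


@dataclass(frozen=True, slots=True)
class Hba1cMeasurement:
    """One HbA1c test result in percent.

    Values outside [3, 25] % are rejected as physiologically implausible;
    values outside [4, 20] % are accepted with a warning.
    """

    patient_id: str
    date: date
    value: float

    def __post_init__(self) -> None:
        v = float(self.value)
        if not 3.0 <= v <= 25.0:
            raise DataValidationError(
                f"HbA1c value {v} for {self.patient_id} outside plausible range [3, 25] %"
            )
        if not 4.0 <= v <= 20.0:
            warnings.warn(
                f"HbA1c value {v} for {self.patient_id} outside usual range [4, 20] %",
                stacklevel=2,
            )


@dataclass(frozen=True, slots=True)
class PatientRecord:
    """Demographics plus precomputed comorbidity/complication counts.

    ``dcsi_count`` (diabetes complication severity index) and ``cic_count``
    (chronic illness with complexity) are inputs, never derived here; a
    ``None`` means the flag is missing and the comorbidity filter will
    refuse to guess.
    """

    patient_id: str
    age: float | None = None
    sex: str | None = None
    years_with_t2dm: float | None = None
    dcsi_count: int | None = None
    cic_count: int | None = None


@dataclass(frozen=True, slots=True)
class StudyWindow:
    """Per-patient normalized observation window.

    ``t0`` is the first HbA1c measurement; ``t_end`` the selected final
    measurement, as close as possible to 18 months after ``t0`` within
    [10, 26] months.
    """

    patient_id: str
    t0: date
    t_end: date
    span_months: float

    def __post_init__(self) -> None:
        if not self.t0 < self.t_end:
            raise DataValidationError(
                f"study window for {self.patient_id}: t0 must precede t_end"
            )
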