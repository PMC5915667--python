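"""CSV interchange formats.

Three flat tables, ISO-8601 dates, strict dialect:

* encounters: ``patient_id,date,discipline[,appointment_type,next_discipline,next_date]``
* measurements: ``patient_id,date,hba1c_percent``
* patients: ``patient_id[,age,sex,years_with_t2dm,dcsi_count,cic_count]``

Discipline tokens accept case-insensitive synonyms (physician/nurse/
dietitian); anything outside the triad is an error with its row number.
Rows whose ``appointment_type`` is present and not CVPA are dropped with a
logged count. Duplicate identical measurement rows are deduplicated with
a warning.
"""

from __future__ import annotations

import csv
import logging
import warnings
from datetime import date
from pathlib import Path

from .records import (
    DataValidationError,
    EncounterRecord,
    Hba1cMeasurement,
    PatientRecord,
    normalize_discipline,
)
from .synthetic import PlantedTruth, SyntheticCohort

logger = logging.getLogger(__name__)


def _parse_date(token: str, path, row_no: int) -> date:
    try:
        return date.fromisoformat(token.strip())
    except ValueError:
        raise DataValidationError(
            f"{path}, row {row_no}: unparseable ISO-8601 date {token!r}"
        ) from None


def _parse_value(token: str, path, row_no: int) -> float:
    try:
        v = float(token)
    except ValueError:
        hint = " (comma decimal separators are not accepted; use a point)" if "," in token else ""
        raise DataValidationError(
            f"{path}, row {row_no}: non-numeric HbA1c value {token!r}{hint}"
        ) from None
    if v < 0:
        raise DataValidationError(f"{path}, row {row_no}: negative HbA1c value {v}")
    return v


def _reader(path: Path, required: set[str]):
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    fields = set(reader.fieldnames or ())
    if not required <= fields:
        handle.close()
        raise DataValidationError(
            f"{path}: missing required columns {sorted(required - fields)}"
        )
    return handle, reader


def read_encounters(path) -> list[EncounterRecord]:
    path = Path(path)
    handle, reader = _reader(path, {"patient_id", "date", "discipline"})
    out: list[EncounterRecord] = []
    dropped = 0
    with handle:
        for row_no, row in enumerate(reader, start=2):
            kind = (row.get("appointment_type") or "").strip()
            if kind and kind.upper() != "CVPA":
                dropped += 1
                continue
            try:
                disc = normalize_discipline(row["discipline"])
            except DataValidationError as exc:
                raise DataValidationError(f"{path}, row {row_no}: {exc}") from None
            nxt = (row.get("next_discipline") or "").strip()
            nxt_date = (row.get("next_date") or "").strip()
            out.append(
                EncounterRecord(
                    patient_id=row["patient_id"].strip(),
                    date=_parse_date(row["date"], path, row_no),
                    discipline=disc,
                    next_discipline=normalize_discipline(nxt) if nxt else None,
                    next_date=_parse_date(nxt_date, path, row_no) if nxt_date else None,
                )
            )
    if dropped:
        logger.info("%s: dropped %d non-CVPA rows", path, dropped)
    return out


def read_measurements(path) -> list[Hba1cMeasurement]:
    path = Path(path)
    handle, reader = _reader(path, {"patient_id", "date", "hba1c_percent"})
    seen: set[tuple] = set()
    out: list[Hba1cMeasurement] = []
    duplicates = 0
    with handle:
        for row_no, row in enumerate(reader, start=2):
            rec = Hba1cMeasurement(
                patient_id=row["patient_id"].strip(),
                date=_parse_date(row["date"], path, row_no),
                value=_parse_value(row["hba1c_percent"], path, row_no),
            )
            key = (rec.patient_id, rec.date, rec.value)
            if key in seen:
                duplicates += 1
                continue
            seen.add(key)
            out.append(rec)
    if duplicates:
        warnings.warn(f"{path}: dropped {duplicates} duplicate measurement rows")
    out.sort(key=lambda m: (m.patient_id, m.date))
    return out


def _opt_float(row, key):
    tok = (row.get(key) or "").strip()
    return float(tok) if tok else None


def _opt_int(row, key):
    tok = (row.get(key) or "").strip()
    return int(tok) if tok else None


def read_patients(path) -> list[PatientRecord]:
    path = Path(path)
    handle, reader = _reader(path, {"patient_id"})
    out: list[PatientRecord] = []
    with handle:
        for row in reader:
            out.append(
                PatientRecord(
                    patient_id=row["patient_id"].strip(),
                    age=_opt_float(row, "age"),
                    sex=(row.get("sex") or "").strip() or None,
                    years_with_t2dm=_opt_float(row, "years_with_t2dm"),
                    dcsi_count=_opt_int(row, "dcsi_count"),
                    cic_count=_opt_int(row, "cic_count"),
                )
            )
    return out


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write encounters/measurements/patients/truth CSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "encounters": directory / "encounters.csv",
        "measurements": directory / "measurements.csv",
        "patients": directory / "patients.csv",
        "truth": directory / "truth.csv",
    }
    with open(paths["encounters"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "discipline", "next_discipline", "next_date"])
        for e in cohort.encounters:
            w.writerow(
                [
                    e.patient_id,
                    e.date.isoformat(),
                    e.discipline,
                    e.next_discipline or "",
                    e.next_date.isoformat() if e.next_date else "",
                ]
            )
    with open(paths["measurements"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "hba1c_percent"])
        for m in cohort.measurements:
            w.writerow([m.patient_id, m.date.isoformat(), repr(m.value)])
    with open(paths["patients"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "age", "sex", "years_with_t2dm", "dcsi_count", "cic_count"])
        for p in cohort.patients:
            w.writerow(
                [p.patient_id, p.age, p.sex, p.years_with_t2dm, p.dcsi_count, p.cic_count]
            )
    with open(paths["truth"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "planted_pattern", "planted_segment", "adherence_violator"])
        for pid in sorted(cohort.truth):
            t = cohort.truth[pid]
            w.writerow([pid, t.pattern, t.segment, int(t.adherence_violator)])
    return paths


def read_truth(path) -> dict[str, PlantedTruth]:
    path = Path(path)
    handle, reader = _reader(
        path, {"patient_id", "planted_pattern", "planted_segment", "adherence_violator"}
    )
    out: dict[str, PlantedTruth] = {}
    with handle:
        for row in reader:
            out[row["patient_id"].strip()] = PlantedTruth(
                pattern=row["planted_pattern"],
                segment=row["planted_segment"],
                adherence_violator=bool(int(row["adherence_violator"])),
            )
    return out
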