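"""Read, validate and write the registry-like flat tables.

Three input tables emulate nationwide administrative registers:

* ``prescriptions`` — one row per redeemed prescription (person, ATC, date);
* ``diagnoses`` — hospital admissions with an ICD-8/ICD-10 code;
* ``persons`` — demographics with optional death/emigration dates.

All files are UTF-8 CSV with a header row and ISO-8601 calendar dates; the
day is the atomic time unit throughout the package.  Validation is strict:
a malformed date or an empty ATC code raises with the offending line number
rather than being silently coerced.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "PrescriptionRecord",
    "DiagnosisRecord",
    "PersonRecord",
    "EpisodeRow",
    "SchemaError",
    "RowValidationError",
    "read_table",
    "write_table",
    "read_episodes",
    "write_episodes",
    "SCHEMAS",
]


class SchemaError(ValueError):
    """A file's header does not match the documented schema."""


class RowValidationError(ValueError):
    """A row violates a type invariant; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclasses.dataclass(frozen=True)
class PrescriptionRecord:
    """One redeemed prescription at a community pharmacy."""

    person_id: str
    atc: str
    redeem_date: dt.date

    def validate(self) -> None:
        if not self.atc:
            raise ValueError("atc must be non-empty")
        if self.atc != self.atc.upper():
            raise ValueError(f"atc must be uppercase, got {self.atc!r}")


@dataclasses.dataclass(frozen=True)
class DiagnosisRecord:
    """One hospitalization / outpatient contact with a diagnosis code."""

    person_id: str
    icd_code: str
    admit_date: dt.date
    discharge_date: dt.date

    def validate(self) -> None:
        if not self.icd_code:
            raise ValueError("icd_code must be non-empty")
        if self.discharge_date < self.admit_date:
            raise ValueError(
                f"discharge_date {self.discharge_date} before admit_date {self.admit_date}"
            )


@dataclasses.dataclass(frozen=True)
class PersonRecord:
    """Demographics: sex, birth date, optional death/emigration dates."""

    person_id: str
    sex: str
    birth_date: dt.date
    death_date: Optional[dt.date] = None
    emigration_date: Optional[dt.date] = None

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("death_date", "emigration_date"):
            value = getattr(self, name)
            if value is not None and value < self.birth_date:
                raise ValueError(f"{name} {value} before birth_date {self.birth_date}")


@dataclasses.dataclass
class EpisodeRow:
    """Flat serialization of one co-exposure episode with its labels.

    Mirrors :class:`rxregimen.coexposure.CoExposureEpisode` plus the labels
    assigned by each classification approach and, when known, the planted
    ground truth.
    """

    person_id: str
    drug_first: str
    drug_second: str
    episode_start: dt.date
    episode_end: dt.date
    coexposure_days: int
    potential_days: int
    N: float
    J: int
    stage: str
    sequence_index: int
    label_approach1: str = ""
    label_approach2: str = ""
    label_approach3: str = ""
    label_truth: str = ""

    def validate(self) -> None:
        if not 0.0 <= self.N <= 1.0:
            raise ValueError(f"N must be in [0, 1], got {self.N}")
        if self.coexposure_days > self.potential_days:
            raise ValueError("coexposure_days exceeds potential_days")
        if self.stage not in ("early", "middle", "late"):
            raise ValueError(f"unknown stage {self.stage!r}")


def _parse_date(text: str, column: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        raise RowValidationError(line, f"column {column!r}: unparseable date {text!r}")


def _parse_opt_date(text: str, column: str, line: int) -> Optional[dt.date]:
    if text == "":
        return None
    return _parse_date(text, column, line)


SCHEMAS = {
    "prescriptions": ["person_id", "atc", "redeem_date"],
    "diagnoses": ["person_id", "icd_code", "admit_date", "discharge_date"],
    "persons": ["person_id", "sex", "birth_date", "death_date", "emigration_date"],
    "episodes": [
        "person_id",
        "drug_first",
        "drug_second",
        "episode_start",
        "episode_end",
        "coexposure_days",
        "potential_days",
        "N",
        "J",
        "stage",
        "sequence_index",
        "label_approach1",
        "label_approach2",
        "label_approach3",
        "label_truth",
    ],
}


def _check_header(header: Sequence[str], schema_name: str) -> None:
    expected = SCHEMAS[schema_name]
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(
            f"{schema_name} table is missing column(s): {', '.join(missing)}"
        )
    extra = [c for c in header if c not in expected]
    if extra:
        raise SchemaError(f"{schema_name} table has unknown column(s): {', '.join(extra)}")


def _row_to_record(row: dict, schema_name: str, line: int):
    if schema_name == "prescriptions":
        rec = PrescriptionRecord(
            person_id=row["person_id"],
            atc=row["atc"],
            redeem_date=_parse_date(row["redeem_date"], "redeem_date", line),
        )
    elif schema_name == "diagnoses":
        rec = DiagnosisRecord(
            person_id=row["person_id"],
            icd_code=row["icd_code"],
            admit_date=_parse_date(row["admit_date"], "admit_date", line),
            discharge_date=_parse_date(row["discharge_date"], "discharge_date", line),
        )
    elif schema_name == "persons":
        rec = PersonRecord(
            person_id=row["person_id"],
            sex=row["sex"],
            birth_date=_parse_date(row["birth_date"], "birth_date", line),
            death_date=_parse_opt_date(row.get("death_date", ""), "death_date", line),
            emigration_date=_parse_opt_date(
                row.get("emigration_date", ""), "emigration_date", line
            ),
        )
    else:  # pragma: no cover - guarded by read_table
        raise ValueError(f"unknown schema {schema_name!r}")
    try:
        rec.validate()
    except ValueError as exc:
        raise RowValidationError(line, str(exc)) from None
    return rec


def read_table(path, schema_name: str):
    """Read one registry table, validating every row.

    Parameters
    ----------
    path
        CSV file with the documented header.
    schema_name
        One of ``prescriptions``, ``diagnoses``, ``persons``.

    Returns
    -------
    list of typed records in file order.
    """
    if schema_name not in ("prescriptions", "diagnoses", "persons"):
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path} is empty (no header row)")
        _check_header(reader.fieldnames, schema_name)
        for line, row in enumerate(reader, start=2):
            records.append(_row_to_record(row, schema_name, line))
    return records


def write_table(records: Iterable, path, schema_name: str) -> None:
    """Write typed records to CSV using the documented schema."""
    path = Path(path)
    columns = SCHEMAS[schema_name]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            writer.writerow(
                ["" if getattr(rec, c) is None else getattr(rec, c) for c in columns]
            )


def write_episodes(episodes: Iterable[EpisodeRow], path) -> None:
    """Write episode rows; ``write_episodes`` then :func:`read_episodes` is identity."""
    path = Path(path)
    columns = SCHEMAS["episodes"]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for ep in episodes:
            writer.writerow([getattr(ep, c) for c in columns])


def read_episodes(path) -> list[EpisodeRow]:
    """Read an episodes CSV back into :class:`EpisodeRow` objects."""
    path = Path(path)
    episodes = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path} is empty (no header row)")
        _check_header(reader.fieldnames, "episodes")
        for line, row in enumerate(reader, start=2):
            try:
                ep = EpisodeRow(
                    person_id=row["person_id"],
                    drug_first=row["drug_first"],
                    drug_second=row["drug_second"],
                    episode_start=_parse_date(row["episode_start"], "episode_start", line),
                    episode_end=_parse_date(row["episode_end"], "episode_end", line),
                    coexposure_days=int(row["coexposure_days"]),
                    potential_days=int(row["potential_days"]),
                    N=float(row["N"]),
                    J=int(row["J"]),
                    stage=row["stage"],
                    sequence_index=int(row["sequence_index"]),
                    label_approach1=row["label_approach1"],
                    label_approach2=row["label_approach2"],
                    label_approach3=row["label_approach3"],
                    label_truth=row["label_truth"],
                )
                ep.validate()
            except RowValidationError:
                raise
            except ValueError as exc:
                raise RowValidationError(line, str(exc)) from None
            episodes.append(ep)
    return episodes
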