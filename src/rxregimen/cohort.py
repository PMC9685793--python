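"""Incident new-user cohort construction and follow-up windows.

The study population is everyone who (a) has a qualifying epilepsy
diagnosis (ICD-8 345 / ICD-10 G40*), (b) redeems a first-ever anti-seizure
medication (ASM) on or after the admission date of that diagnosis — the
redemption date becomes the *index date* — and (c) meets the age and
calendar-window constraints.  The new-user (wash-out) requirement is
absolute: any ASM redemption strictly before the index date excludes the
person.  Follow-up runs from the index date for a fixed window (default
730 days), censored at death, emigration or the administrative study end.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import CohortConfig
from .registry_io import DiagnosisRecord, PersonRecord, PrescriptionRecord

__all__ = ["CohortMember", "ExclusionLog", "build_cohort", "summarize_cohort"]

DAYS_PER_YEAR = 365.25


class EmptyCohortError(ValueError):
    """Raised when a summary is requested for an empty cohort."""


@dataclasses.dataclass(frozen=True)
class CohortMember:
    """One study-population member with their follow-up window."""

    person_id: str
    index_date: dt.date
    followup_end: dt.date
    age_at_index: float
    sex: str
    first_asm_atc: str
    first_diag_icd: str
    diag_admit_date: dt.date
    diag_discharge_date: dt.date
    hosp_duration_days: int
    diag_to_first_rx_days: int
    death_date: Optional[dt.date] = None
    emigration_date: Optional[dt.date] = None

    @property
    def followup_days(self) -> int:
        return (self.followup_end - self.index_date).days


@dataclasses.dataclass
class ExclusionLog:
    """Attrition audit: person ids excluded per reason code."""

    no_diagnosis: list[str] = dataclasses.field(default_factory=list)
    no_asm: list[str] = dataclasses.field(default_factory=list)
    prior_asm: list[str] = dataclasses.field(default_factory=list)
    age: list[str] = dataclasses.field(default_factory=list)
    window: list[str] = dataclasses.field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {f.name: len(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _is_asm(atc: str, prefixes: Sequence[str]) -> bool:
    return any(atc.startswith(p) for p in prefixes)


def _is_epilepsy(icd: str, prefixes: Sequence[str]) -> bool:
    return any(icd.startswith(p) for p in prefixes)


def build_cohort(
    prescriptions: Iterable[PrescriptionRecord],
    diagnoses: Iterable[DiagnosisRecord],
    persons: Iterable[PersonRecord],
    config: CohortConfig | None = None,
) -> tuple[list[CohortMember], ExclusionLog]:
    """Build the incident new-user cohort.

    Returns the members (sorted by person id, so output is independent of
    input row order) and an exclusion log keyed by reason.
    """
    cfg = config or CohortConfig()
    log = ExclusionLog()

    rx_by_person: dict[str, list[PrescriptionRecord]] = {}
    for rx in prescriptions:
        rx_by_person.setdefault(rx.person_id, []).append(rx)
    dx_by_person: dict[str, list[DiagnosisRecord]] = {}
    for dx in diagnoses:
        if _is_epilepsy(dx.icd_code, cfg.epilepsy_icd_prefixes):
            dx_by_person.setdefault(dx.person_id, []).append(dx)

    members: list[CohortMember] = []
    for person in sorted(persons, key=lambda p: p.person_id):
        pid = person.person_id
        dxs = dx_by_person.get(pid)
        if not dxs:
            log.no_diagnosis.append(pid)
            continue
        first_dx = min(dxs, key=lambda d: (d.admit_date, d.icd_code))

        asm_rx = sorted(
            (r for r in rx_by_person.get(pid, ()) if _is_asm(r.atc, cfg.asm_atc_prefixes)),
            key=lambda r: (r.redeem_date, r.atc),
        )
        on_or_after = [r for r in asm_rx if r.redeem_date >= first_dx.admit_date]
        if not on_or_after:
            log.no_asm.append(pid)
            continue
        index_rx = on_or_after[0]
        if any(r.redeem_date < index_rx.redeem_date for r in asm_rx):
            log.prior_asm.append(pid)
            continue

        index_date = index_rx.redeem_date
        if not (cfg.study_start <= index_date <= cfg.study_end):
            log.window.append(pid)
            continue
        age = (index_date - person.birth_date).days / DAYS_PER_YEAR
        if age < cfg.min_age:
            log.age.append(pid)
            continue

        ends = [index_date + dt.timedelta(days=cfg.followup_days), cfg.study_end]
        if person.death_date is not None:
            ends.append(person.death_date)
        if person.emigration_date is not None:
            ends.append(person.emigration_date)
        followup_end = min(ends)

        members.append(
            CohortMember(
                person_id=pid,
                index_date=index_date,
                followup_end=followup_end,
                age_at_index=age,
                sex=person.sex,
                first_asm_atc=index_rx.atc,
                first_diag_icd=first_dx.icd_code,
                diag_admit_date=first_dx.admit_date,
                diag_discharge_date=first_dx.discharge_date,
                hosp_duration_days=(first_dx.discharge_date - first_dx.admit_date).days,
                diag_to_first_rx_days=(index_date - first_dx.admit_date).days,
                death_date=person.death_date,
                emigration_date=person.emigration_date,
            )
        )
    return members, log


def _median_iqr(values: Sequence[float]) -> dict[str, float]:
    # type-7 (linear interpolation) quantiles, numpy's default
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_cohort(members: Sequence[CohortMember]) -> dict:
    """Baseline descriptives: sex and first-ASM mix, age and hospital stay.

    Categorical blocks report count and proportion (proportions sum to 1
    within each block); continuous variables report median and IQR using
    linear-interpolation quantiles.
    """
    if not members:
        raise EmptyCohortError("cannot summarize an empty cohort")
    n = len(members)
    sex_counts = Counter(m.sex for m in members)
    asm_counts = Counter(m.first_asm_atc for m in members)
    return {
        "n": n,
        "sex": {
            k: {"count": v, "proportion": v / n} for k, v in sorted(sex_counts.items())
        },
        "first_asm": {
            k: {"count": v, "proportion": v / n}
            for k, v in asm_counts.most_common()
        },
        "age_at_index": _median_iqr([m.age_at_index for m in members]),
        "hosp_duration_days": _median_iqr([m.hosp_duration_days for m in members]),
        "diag_to_first_rx_days": _median_iqr([m.diag_to_first_rx_days for m in members]),
    }
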