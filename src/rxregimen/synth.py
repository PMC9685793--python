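"""Synthetic registry generator with planted switch / add-on ground truth.

Real register data carry no ground truth about why a second drug appears;
the original method was validated against manual chart-style review.  This
generator replaces that review: it writes the three registry tables
(prescriptions, diagnoses, persons) with dispensing trajectories whose
regimen-change type is known *by construction*, so the whole pipeline can
be tested end-to-end.

Each simulated person is hospitalized for epilepsy (G40* code), redeems a
first anti-seizure drug shortly after admission (the index date), and then
follows one of four planted trajectories:

* **monotherapy** — a single drug refilled through follow-up;
* **switch** — drug A refilled until a switch day, drug B starting with a
  short taper overlap (a few days) and continuing; the co-exposure
  proportion N is small by construction;
* **add-on** — drug B starts on top of A and both continue (sustained
  overlap, N = 1), or, for a configurable fraction, a *short-term* add-on
  of a rule drug (clonazepam or phenytoin) redeemed once or twice and then
  stopped — small N, the known failure mode of pure thresholding;
* **unknown** — both drugs stop mid-window with an intermediate overlap
  fraction planted inside the ambiguous band (0.10 < N < 0.35).

Refill behavior is modeled as per-person-per-drug phenotypes: most persons
refill exactly when the supply runs out, a minority refill a fixed number
of days early.  Within a phenotype the refill gap is constant, which keeps
the planted overlaps exactly recoverable; the messiness of real refill
behavior is deliberately *not* emulated (see the package methods note).
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import ATC_CLONAZEPAM, ATC_PHENYTOIN
from .registry_io import DiagnosisRecord, PersonRecord, PrescriptionRecord

__all__ = [
    "DrugSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_registry",
    "validate_truth",
    "truth_labels_for_episodes",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclasses.dataclass(frozen=True)
class DrugSpec:
    name: str
    atc: str
    supply_days: int
    first_line_weight: float
    rule_drug: bool = False


def default_palette() -> tuple[DrugSpec, ...]:
    # The anti-seizure drugs seen in elderly epilepsy care; weights follow
    # the observed first-drug mix (valproate and lamotrigine dominate).
    return (
        DrugSpec("valproate", "N03AG01", 30, 0.35),
        DrugSpec("lamotrigine", "N03AX09", 30, 0.22),
        DrugSpec("oxcarbazepine", "N03AF02", 30, 0.18),
        DrugSpec("levetiracetam", "N03AX14", 30, 0.10),
        DrugSpec("carbamazepine", "N03AF01", 90, 0.08),
        DrugSpec("phenobarbital", "N03AA02", 90, 0.07),
        DrugSpec("phenytoin", ATC_PHENYTOIN, 30, 0.0, rule_drug=True),
        DrugSpec("clonazepam", ATC_CLONAZEPAM, 30, 0.0, rule_drug=True),
    )


@dataclasses.dataclass
class SimulationConfig:
    """All the dials of the generator; the defaults are the study conditions."""

    n_persons: int = 1000
    seed: int = 0
    # planted trajectory mix (must sum to 1)
    p_switch: float = 0.12
    p_addon: float = 0.43
    p_unknown: float = 0.05
    p_monotherapy: float = 0.40
    # fraction of add-ons that are short-term rule-drug add-ons
    short_term_addon_fraction: float = 0.30
    # refill phenotypes: days redeemed early, with probabilities
    early_refill_offsets: tuple[int, ...] = (0, 6, 8)
    early_refill_probs: tuple[float, ...] = (0.70, 0.15, 0.15)
    # switch taper overlap, days (inclusive range)
    taper_days_min: int = 4
    taper_days_max: int = 8
    # ambiguous overlap band for planted unknowns
    unknown_n_range: tuple[float, float] = (0.17, 0.28)
    # timing of the regimen change within follow-up: early / middle / late
    stage_probs: tuple[float, float, float] = (0.82, 0.12, 0.06)
    # censoring hazards per day of follow-up (0 = no censoring)
    mortality_hazard_per_day: float = 0.0
    emigration_hazard_per_day: float = 0.0
    # calendar window for hospital admissions; chosen so the full 730-day
    # follow-up fits before the administrative study end
    admit_start: dt.date = dt.date(1996, 1, 1)
    admit_end: dt.date = dt.date(2015, 6, 30)
    followup_days: int = 730
    # fraction of extra persons who are ineligible (young or prior users)
    ineligible_fraction: float = 0.05
    palette: tuple[DrugSpec, ...] = dataclasses.field(default_factory=default_palette)

    def validate(self) -> None:
        mix = self.p_switch + self.p_addon + self.p_unknown + self.p_monotherapy
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"trajectory mix must sum to 1, got {mix}")
        if self.mortality_hazard_per_day < 0 or self.emigration_hazard_per_day < 0:
            raise ValueError("hazards must be >= 0")
        lo, hi = self.unknown_n_range
        if not (0.10 < lo < hi < 0.35):
            raise ValueError(
                "unknown_n_range must lie strictly inside the ambiguous band (0.10, 0.35)"
            )
        if not (0 < self.taper_days_min <= self.taper_days_max):
            raise ValueError("taper day range must be positive")
        min_supply = min(d.supply_days for d in self.palette)
        if self.taper_days_max >= min_supply:
            raise ValueError("taper overlap must be shorter than the smallest supply")
        if self.taper_days_max * 10 > self.followup_days - 615:
            # late switches start around day 600; the remaining window must
            # be >= 10x the taper so planted N stays under the 10% threshold
            raise ValueError("taper too long for a late switch within the follow-up")


@dataclasses.dataclass
class GroundTruth:
    """One planted co-exposure episode with its true label and stage."""

    person_id: str
    drug_first: str
    drug_second: str
    true_label: str  # switch / add-on / unknown
    true_stage: str
    overlap_start_day: int  # days from index
    overlap_days: int
    censored: bool = False


ICD_CODES = (("G409", 0.594), ("G402", 0.155), ("G408", 0.112), ("G403", 0.080), ("G401", 0.059))

EARLY, MIDDLE, LATE = "early", "middle", "late"


def _stage_for_day(day: int, followup_days: int) -> str:
    from .coexposure import stage_boundaries

    early_end, _q3, late_start = stage_boundaries(followup_days)
    if day <= early_end:
        return EARLY
    if day >= late_start:
        return LATE
    return MIDDLE


def _draw_change_day(rng, stage_probs, kind: str) -> int:
    """Target day of the regimen change; ranges keep planted N in band."""
    if kind == "unknown":
        # late unknowns cannot be planted (both drugs must stop inside the
        # window), so the stage draw collapses to early/middle
        stage = rng.choice([EARLY, MIDDLE], p=_norm(stage_probs[:2]))
        return int(rng.integers(100, 181)) if stage == EARLY else int(rng.integers(185, 461))
    stage = rng.choice([EARLY, MIDDLE, LATE], p=_norm(stage_probs))
    if stage == EARLY:
        return int(rng.integers(60, 181))
    if stage == MIDDLE:
        return int(rng.integers(185, 521))
    return int(rng.integers(550, 601))


def _norm(p):
    arr = np.asarray(p, dtype=float)
    return arr / arr.sum()


class _PersonBuilder:
    """Accumulates one person's prescriptions as day offsets from index."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.rx: list[tuple[str, int]] = []  # (atc, day offset)
        self._gaps: dict[str, int] = {}

    def gap(self, drug: DrugSpec) -> int:
        """Personal refill gap for a drug: supply minus the phenotype offset."""
        if drug.atc not in self._gaps:
            if drug.rule_drug:
                offset = 0  # rule drugs are short-course: no early refills
            else:
                offset = int(
                    self.rng.choice(self.cfg.early_refill_offsets, p=self.cfg.early_refill_probs)
                )
            self._gaps[drug.atc] = drug.supply_days - offset
        return self._gaps[drug.atc]

    def refill_through(self, drug: DrugSpec, start: int, until: int) -> None:
        """Redemptions at start, start+g, ... while the day is < ``until``."""
        g = self.gap(drug)
        day = start
        while day < until:
            self.rx.append((drug.atc, day))
            day += g

    def refill_count(self, drug: DrugSpec, start: int, count: int) -> int:
        """``count`` redemptions from ``start``; returns the supply end day."""
        g = self.gap(drug)
        for j in range(count):
            self.rx.append((drug.atc, start + j * g))
        return start + count * g


def _plant_switch(b: _PersonBuilder, drug_a: DrugSpec, drug_b: DrugSpec, cfg, rng):
    g_a = b.gap(drug_a)
    o = int(rng.integers(cfg.taper_days_min, cfg.taper_days_max + 1))
    target = _draw_change_day(rng, cfg.stage_probs, "switch")
    k = max(1, round((target + o) / g_a) - 1)
    end_a = b.refill_count(drug_a, 0, k + 1)  # A covers [0, (k+1)*g_a)
    b_start = end_a - o
    b.refill_through(drug_b, b_start, cfg.followup_days)
    return GroundTruth(
        person_id="",
        drug_first=drug_a.atc,
        drug_second=drug_b.atc,
        true_label="switch",
        true_stage=_stage_for_day(b_start, cfg.followup_days),
        overlap_start_day=b_start,
        overlap_days=o,
    )


def _plant_sustained_addon(b, drug_a, drug_b, cfg, rng):
    t = _draw_change_day(rng, cfg.stage_probs, "add-on")
    b.refill_through(drug_a, 0, cfg.followup_days)
    b.refill_through(drug_b, t, cfg.followup_days)
    return GroundTruth(
        person_id="",
        drug_first=drug_a.atc,
        drug_second=drug_b.atc,
        true_label="add-on",
        true_stage=_stage_for_day(t, cfg.followup_days),
        overlap_start_day=t,
        overlap_days=cfg.followup_days - t,
    )


def _plant_short_addon(b, drug_a, drug_b, cfg, rng):
    t = _draw_change_day(rng, cfg.stage_probs, "add-on")
    b.refill_through(drug_a, 0, cfg.followup_days)
    n_redeem = int(rng.integers(1, 3))
    end_b = b.refill_count(drug_b, t, n_redeem)
    return GroundTruth(
        person_id="",
        drug_first=drug_a.atc,
        drug_second=drug_b.atc,
        true_label="add-on",
        true_stage=_stage_for_day(t, cfg.followup_days),
        overlap_start_day=t,
        overlap_days=min(end_b, cfg.followup_days) - t,
    )


def _plant_unknown(b, drug_a, drug_b, cfg, rng):
    g_a, g_b = b.gap(drug_a), b.gap(drug_b)
    k_b = int(rng.integers(3, 8))
    potential = (k_b + 1) * g_b
    n_target = rng.uniform(*cfg.unknown_n_range)
    o = max(1, round(n_target * potential))
    target = _draw_change_day(rng, cfg.stage_probs, "unknown")
    k_a = max(1, round((target + o) / g_a) - 1)
    end_a = b.refill_count(drug_a, 0, k_a + 1)
    t = end_a - o  # B starts o days before A's supply runs out
    b.refill_count(drug_b, t, k_b + 1)
    return GroundTruth(
        person_id="",
        drug_first=drug_a.atc,
        drug_second=drug_b.atc,
        true_label="unknown",
        true_stage=_stage_for_day(t, cfg.followup_days),
        overlap_start_day=t,
        overlap_days=o,
    )


def simulate_registry(
    config: SimulationConfig | None = None,
) -> tuple[
    list[PrescriptionRecord],
    list[DiagnosisRecord],
    list[PersonRecord],
    list[GroundTruth],
]:
    """Generate the three registry tables plus the planted ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    tables.  Per-person randomness is drawn from a generator seeded with
    ``(seed, person index)`` so individual persons are reproducible
    independently of cohort size.
    """
    cfg = config or SimulationConfig()
    cfg.validate()

    palette = list(cfg.palette)
    first_line = [d for d in palette if not d.rule_drug and d.first_line_weight > 0]
    weights = _norm([d.first_line_weight for d in first_line])
    short_supply = [d for d in first_line if d.supply_days == min(d.supply_days for d in first_line)]
    rule_drugs = [d for d in palette if d.rule_drug]

    prescriptions: list[PrescriptionRecord] = []
    diagnoses: list[DiagnosisRecord] = []
    persons: list[PersonRecord] = []
    truths: list[GroundTruth] = []

    n_total = cfg.n_persons + int(round(cfg.n_persons * cfg.ineligible_fraction))
    admit_span = (cfg.admit_end - cfg.admit_start).days
    for i in range(n_total):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"P{i:06d}"
        ineligible = i >= cfg.n_persons

        admit = cfg.admit_start + dt.timedelta(days=int(rng.integers(0, admit_span + 1)))
        hosp_days = int(np.clip(round(rng.lognormal(np.log(5.0), 2.1)), 0, 60))
        discharge = admit + dt.timedelta(days=hosp_days)
        icd = str(rng.choice([c for c, _ in ICD_CODES], p=_norm([w for _, w in ICD_CODES])))
        diagnoses.append(DiagnosisRecord(pid, icd, admit, discharge))

        rx_delay = int(np.clip(round(rng.lognormal(np.log(8.0), 1.5)), 0, 36))
        index_date = admit + dt.timedelta(days=rx_delay)

        if ineligible and rng.random() < 0.5:
            age_years = float(rng.uniform(40, 60))  # fails the age criterion
        else:
            age_years = float(rng.uniform(65.5, 95))
        birth = index_date - dt.timedelta(days=round(age_years * 365.25))
        sex = "male" if rng.random() < 0.52 else "female"

        builder = _PersonBuilder(cfg, rng)
        kind = str(
            rng.choice(
                ["switch", "add-on", "unknown", "monotherapy"],
                p=[cfg.p_switch, cfg.p_addon, cfg.p_unknown, cfg.p_monotherapy],
            )
        )
        truth: Optional[GroundTruth] = None
        if ineligible or kind == "monotherapy":
            drug_a = first_line[int(rng.choice(len(first_line), p=weights))]
            builder.refill_through(drug_a, 0, cfg.followup_days)
        elif kind == "switch":
            # taper overlaps need a monthly refill rhythm on both sides
            drug_a = short_supply[int(rng.integers(len(short_supply)))]
            drug_b = _other(short_supply, drug_a, rng)
            truth = _plant_switch(builder, drug_a, drug_b, cfg, rng)
        elif kind == "add-on":
            drug_a = first_line[int(rng.choice(len(first_line), p=weights))]
            if rng.random() < cfg.short_term_addon_fraction and rule_drugs:
                drug_b = rule_drugs[int(rng.integers(len(rule_drugs)))]
                truth = _plant_short_addon(builder, drug_a, drug_b, cfg, rng)
            else:
                drug_b = _other(short_supply, drug_a, rng)
                truth = _plant_sustained_addon(builder, drug_a, drug_b, cfg, rng)
        else:  # unknown
            drug_a = short_supply[int(rng.integers(len(short_supply)))]
            drug_b = _other(short_supply, drug_a, rng)
            truth = _plant_unknown(builder, drug_a, drug_b, cfg, rng)

        # censoring: exponential waiting times from the index date
        censor_day = cfg.followup_days
        death_date = emigration_date = None
        if cfg.mortality_hazard_per_day > 0:
            d = int(round(rng.exponential(1.0 / cfg.mortality_hazard_per_day)))
            if d < cfg.followup_days:
                death_date = index_date + dt.timedelta(days=d)
                censor_day = min(censor_day, d)
        if cfg.emigration_hazard_per_day > 0:
            d = int(round(rng.exponential(1.0 / cfg.emigration_hazard_per_day)))
            if d < cfg.followup_days:
                emigration_date = index_date + dt.timedelta(days=d)
                censor_day = min(censor_day, d)

        if ineligible and age_years >= 65:
            # prior-user phenotype: an old redemption before the diagnosis
            prior = first_line[int(rng.integers(len(first_line)))]
            prescriptions.append(
                PrescriptionRecord(pid, prior.atc, admit - dt.timedelta(days=400))
            )

        for atc, day in sorted(builder.rx, key=lambda t: (t[1], t[0])):
            if day < censor_day:
                prescriptions.append(
                    PrescriptionRecord(pid, atc, index_date + dt.timedelta(days=day))
                )

        persons.append(PersonRecord(pid, sex, birth, death_date, emigration_date))
        if truth is not None:
            truth.person_id = pid
            truth.censored = truth.overlap_start_day >= censor_day
            truths.append(truth)

    return prescriptions, diagnoses, persons, truths


def _other(pool: Sequence[DrugSpec], exclude: DrugSpec, rng) -> DrugSpec:
    candidates = [d for d in pool if d.atc != exclude.atc]
    return candidates[int(rng.integers(len(candidates)))]


def validate_truth(ground_truth: Sequence[GroundTruth], detected_episodes) -> dict:
    """Match planted episodes to detected ones by person, pair and window.

    A planted episode matches when a detected episode of the same person
    and (unordered) drug pair overlaps its planted day window by at least
    one day.  Unmatched entries are flagged ``censored`` when the planted
    overlap began at or after the person's censoring day, else ``missing``.
    """
    by_person: dict[str, list] = {}
    for ep in detected_episodes:
        by_person.setdefault(ep.person_id, []).append(ep)
    rows = []
    n_matched = 0
    for truth in ground_truth:
        match = None
        for ep in by_person.get(truth.person_id, ()):  # few episodes per person
            if {ep.drug_first, ep.drug_second} != {truth.drug_first, truth.drug_second}:
                continue
            if ep.J < truth.overlap_start_day + truth.overlap_days and (
                ep.J + ep.coexposure_days > truth.overlap_start_day
            ):
                match = ep
                break
        if match is not None:
            n_matched += 1
            status = "matched"
        else:
            status = "censored" if truth.censored else "missing"
        rows.append({"truth": truth, "episode": match, "status": status})
    return {
        "rows": rows,
        "n_truth": len(ground_truth),
        "n_matched": n_matched,
        "match_rate": n_matched / len(ground_truth) if ground_truth else float("nan"),
    }


def truth_labels_for_episodes(
    ground_truth: Sequence[GroundTruth], episodes
) -> list[Optional[str]]:
    """Planted label for each detected episode (None when nothing matches)."""
    by_key = {
        (t.person_id, frozenset((t.drug_first, t.drug_second))): t.true_label
        for t in ground_truth
    }
    return [
        by_key.get((ep.person_id, frozenset((ep.drug_first, ep.drug_second))))
        for ep in episodes
    ]


TRUTH_COLUMNS = [
    "person_id",
    "drug_first",
    "drug_second",
    "true_label",
    "true_stage",
    "overlap_start_day",
    "overlap_days",
    "censored",
]


def write_ground_truth(truths: Sequence[GroundTruth], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_COLUMNS)
        for t in truths:
            writer.writerow([getattr(t, c) for c in TRUTH_COLUMNS])


def read_ground_truth(path) -> list[GroundTruth]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [
            GroundTruth(
                person_id=row["person_id"],
                drug_first=row["drug_first"],
                drug_second=row["drug_second"],
                true_label=row["true_label"],
                true_stage=row["true_stage"],
                overlap_start_day=int(row["overlap_start_day"]),
                overlap_days=int(row["overlap_days"]),
                censored=row["censored"] == "True",
            )
            for row in csv.DictReader(fh)
        ]
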