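"""Medication events, overlap detection and the N / J / stage statistics.

All intervals are half-open day ranges ``[start, end)``; an overlap length
is the size of the interval intersection in days.  For each cohort member:

1. Same-drug supply intervals (redemption date + estimated duration) that
   overlap or abut are merged into maximal *medication events*, clipped to
   the follow-up window.
2. Every maximal intersection between events of two *different* drugs is a
   *co-exposure episode*.
3. ``N`` is the proportion of co-exposure days out of the potential
   co-exposure time: from the first overlapping day to the person's last
   day in anti-seizure treatment or the end of the observation window,
   whichever comes first.
4. ``J`` is the number of days from the index date (start of follow-up) to
   the first day of the overlap; it places the episode in the *early*
   (first quartile of the window), *middle*, or *late* (past the third
   quartile) stage of therapy.

A brief overlap relative to the remaining treatment time (small N) is the
footprint of a switch with a short taper; a sustained overlap (large N) is
the footprint of an add-on.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

from .cohort import CohortMember
from .config import CoexposureConfig
from .duration import PrescriptionWithDuration

__all__ = [
    "MedicationEvent",
    "CoExposureEpisode",
    "stage_boundaries",
    "build_events",
    "find_episodes",
    "compute_N",
    "compute_J_and_stage",
    "detect_episodes",
]


@dataclasses.dataclass(frozen=True)
class MedicationEvent:
    """A continuous per-person per-drug exposure interval, end exclusive."""

    person_id: str
    atc: str
    start: dt.date
    end: dt.date
    source_prescription_count: int = 1

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclasses.dataclass
class CoExposureEpisode:
    """One overlap period between medication events of two different drugs."""

    person_id: str
    drug_first: str  # drug whose event started earlier
    drug_second: str
    overlap_start: dt.date
    overlap_end: dt.date
    coexposure_days: int
    potential_days: int = 0
    N: float = 0.0
    J: int = 0
    stage: str = ""
    sequence_index: int = 0
    # durations of the two overlapping events, kept for the feature vector
    event_first_days: int = 0
    event_second_days: int = 0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_first, self.drug_second)


def stage_boundaries(followup_days: int = 730) -> tuple[float, float, int]:
    """Quartile cut points of the observation window.

    Returns ``(early_end, middle_end, late_start)``: the early stage covers
    day 0 up to the first quartile of the window, the late stage starts at
    the first whole day past the third quartile, and the middle stage lies
    between.  For the default 730-day window: 182.5, 547.5 and 548.
    """
    q1 = followup_days / 4
    q3 = 3 * followup_days / 4
    return q1, q3, math.ceil(q3)


def build_events(
    prescriptions: Iterable[PrescriptionWithDuration],
    member: CohortMember,
    grace_gap_days: int = 0,
) -> list[MedicationEvent]:
    """Merge supply intervals into maximal per-drug medication events.

    Prescriptions outside ``[index_date, followup_end)`` are ignored;
    event ends are clipped at ``followup_end``.  Intervals of the same drug
    merge when they overlap or abut (or are separated by at most
    ``grace_gap_days``).
    """
    by_atc: dict[str, list[tuple[dt.date, dt.date, int]]] = {}
    for rx in prescriptions:
        if rx.person_id != member.person_id:
            continue
        if not (member.index_date <= rx.redeem_date < member.followup_end):
            continue
        start = rx.redeem_date
        end = min(start + dt.timedelta(days=rx.duration_days), member.followup_end)
        if end > start:
            by_atc.setdefault(rx.atc, []).append((start, end, 1))

    grace = dt.timedelta(days=grace_gap_days)
    events: list[MedicationEvent] = []
    for atc in sorted(by_atc):
        intervals = sorted(by_atc[atc])
        cur_start, cur_end, cur_n = intervals[0]
        for start, end, n in intervals[1:]:
            if start <= cur_end + grace:
                cur_end = max(cur_end, end)
                cur_n += n
            else:
                events.append(
                    MedicationEvent(member.person_id, atc, cur_start, cur_end, cur_n)
                )
                cur_start, cur_end, cur_n = start, end, n
        events.append(MedicationEvent(member.person_id, atc, cur_start, cur_end, cur_n))
    events.sort(key=lambda e: (e.start, e.atc))
    return events


def find_episodes(
    events: Sequence[MedicationEvent], member: CohortMember
) -> list[CoExposureEpisode]:
    """Every maximal intersection between events of different drugs.

    ``drug_first`` is the drug whose event started earlier (ties broken by
    ATC order); ``sequence_index`` is the 1-based temporal rank of the
    episode within the person (ties broken by the drug pair).
    """
    episodes: list[CoExposureEpisode] = []
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if a.atc == b.atc:
                continue
            start = max(a.start, b.start)
            end = min(a.end, b.end)
            if end <= start:
                continue
            if (a.start, a.atc) <= (b.start, b.atc):
                first, second = a, b
            else:
                first, second = b, a
            episodes.append(
                CoExposureEpisode(
                    person_id=member.person_id,
                    drug_first=first.atc,
                    drug_second=second.atc,
                    overlap_start=start,
                    overlap_end=end,
                    coexposure_days=(end - start).days,
                    event_first_days=first.days,
                    event_second_days=second.days,
                )
            )
    episodes.sort(key=lambda e: (e.overlap_start, e.drug_first, e.drug_second))
    for rank, ep in enumerate(episodes, start=1):
        ep.sequence_index = rank
    return episodes


def compute_N(
    episode: CoExposureEpisode,
    events: Sequence[MedicationEvent],
    member: CohortMember,
    denominator_scope: str = "any_asm",
) -> float:
    """Proportion of co-exposure days out of potential co-exposure time.

    The denominator runs from the first overlapping day to the last day in
    treatment — over all of the person's events (``any_asm``) or only the
    episode's own pair (``pair_only``) — or the end of the observation
    window, whichever comes first.
    """
    if denominator_scope == "pair_only":
        pool = [e for e in events if e.atc in (episode.drug_first, episode.drug_second)]
    else:
        pool = list(events)
    last_treatment_end = max(e.end for e in pool)
    horizon = min(last_treatment_end, member.followup_end)
    potential = (horizon - episode.overlap_start).days
    episode.potential_days = potential
    episode.N = episode.coexposure_days / potential
    return episode.N


def compute_J_and_stage(
    episode: CoExposureEpisode, member: CohortMember, followup_days: int = 730
) -> tuple[int, str]:
    """Days from the index date to the first co-exposure day, and the stage."""
    j = (episode.overlap_start - member.index_date).days
    early_end, _q3, late_start = stage_boundaries(followup_days)
    if j <= early_end:
        stage = "early"
    elif j >= late_start:
        stage = "late"
    else:
        stage = "middle"
    episode.J = j
    episode.stage = stage
    return j, stage


def detect_episodes(
    prescriptions: Iterable[PrescriptionWithDuration],
    member: CohortMember,
    config: CoexposureConfig | None = None,
    followup_days: int = 730,
) -> tuple[list[MedicationEvent], list[CoExposureEpisode]]:
    """Run steps 1-4 for one member: events, overlaps, N, J and stage."""
    cfg = config or CoexposureConfig()
    events = build_events(prescriptions, member, cfg.grace_gap_days)
    episodes = find_episodes(events, member)
    for ep in episodes:
        compute_N(ep, events, member, cfg.denominator_scope)
        compute_J_and_stage(ep, member, followup_days)
    return events, episodes
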