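"""End-to-end orchestration: tables in, labeled episodes and reports out.

Sequence: cohort construction -> supply-duration fitting -> medication
events and co-exposure episodes per member -> approach 1/2 labels ->
feature building -> (when reference labels exist) approach-3 training ->
evaluation reports.  Everything downstream of the seed is deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from . import classify as _classify
from . import coexposure as _coexp
from . import evaluate as _evaluate
from .cohort import CohortMember, ExclusionLog, build_cohort
from .config import PipelineConfig
from .duration import DurationModel, assign_durations, fit_duration_model
from .registry_io import DiagnosisRecord, EpisodeRow, PersonRecord, PrescriptionRecord
from .synth import GroundTruth, truth_labels_for_episodes

__all__ = ["PipelineResult", "run_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    members: list[CohortMember]
    exclusions: ExclusionLog
    duration_model: DurationModel
    events: list[_coexp.MedicationEvent]
    episodes: list[_coexp.CoExposureEpisode]
    episode_members: list[CohortMember]  # aligned 1:1 with episodes
    labels_approach1: list[str]
    labels_approach2: list[str]
    labels_approach3: list[str]  # "" when approach 3 was not run
    truth_labels: list[Optional[str]]
    approach3: Optional[_classify.Approach3Result] = None
    reports: dict = dataclasses.field(default_factory=dict)

    def counts(self) -> dict:
        return {
            "cohort_size": len(self.members),
            "exclusions": self.exclusions.counts(),
            "n_events": len(self.events),
            "n_episodes": len(self.episodes),
        }

    def episode_rows(self) -> list[EpisodeRow]:
        rows = []
        for i, ep in enumerate(self.episodes):
            rows.append(
                EpisodeRow(
                    person_id=ep.person_id,
                    drug_first=ep.drug_first,
                    drug_second=ep.drug_second,
                    episode_start=ep.overlap_start,
                    episode_end=ep.overlap_end,
                    coexposure_days=ep.coexposure_days,
                    potential_days=ep.potential_days,
                    N=ep.N,
                    J=ep.J,
                    stage=ep.stage,
                    sequence_index=ep.sequence_index,
                    label_approach1=self.labels_approach1[i],
                    label_approach2=self.labels_approach2[i],
                    label_approach3=self.labels_approach3[i],
                    label_truth=self.truth_labels[i] or "",
                )
            )
        return rows


def run_pipeline(
    prescriptions: Sequence[PrescriptionRecord],
    diagnoses: Sequence[DiagnosisRecord],
    persons: Sequence[PersonRecord],
    config: PipelineConfig | None = None,
    ground_truth: Optional[Sequence[GroundTruth]] = None,
    run_approach3: bool = True,
) -> PipelineResult:
    """Run the full pipeline on three registry tables.

    Approach 3 requires reference labels; it runs only when ``ground_truth``
    supplies them (or is skipped with ``run_approach3=False``).
    """
    cfg = config or PipelineConfig()
    members, exclusions = build_cohort(prescriptions, diagnoses, persons, cfg.cohort)

    asm_rx = [
        rx
        for rx in prescriptions
        if any(rx.atc.startswith(p) for p in cfg.cohort.asm_atc_prefixes)
    ]
    model = fit_duration_model(asm_rx, cfg.see)
    with_durations = assign_durations(asm_rx, model)
    rx_by_person: dict[str, list] = {}
    for rx in with_durations:
        rx_by_person.setdefault(rx.person_id, []).append(rx)

    all_events, episodes, episode_members = [], [], []
    for member in members:
        events, eps = _coexp.detect_episodes(
            rx_by_person.get(member.person_id, ()),
            member,
            cfg.coexposure,
            cfg.cohort.followup_days,
        )
        all_events.extend(events)
        episodes.extend(eps)
        episode_members.extend([member] * len(eps))

    ccfg = cfg.classify
    labels1 = [
        _classify.classify_approach1(ep, ccfg.add_on_threshold, ccfg.switch_threshold)
        for ep in episodes
    ]
    labels2 = [
        _classify.classify_approach2(
            ep, ccfg.rules, l1, ccfg.add_on_threshold, ccfg.switch_threshold
        )
        for ep, l1 in zip(episodes, labels1)
    ]

    truth_labels: list[Optional[str]]
    if ground_truth is not None:
        truth_labels = truth_labels_for_episodes(ground_truth, episodes)
    else:
        truth_labels = [None] * len(episodes)

    labels3 = [""] * len(episodes)
    approach3 = None
    labeled_idx = [i for i, t in enumerate(truth_labels) if t is not None]
    if run_approach3 and len({truth_labels[i] for i in labeled_idx}) >= 2:
        features = [
            _classify.build_features(episodes[i], episode_members[i]) for i in labeled_idx
        ]
        approach3 = _classify.train_and_classify_approach3(
            features, [truth_labels[i] for i in labeled_idx], ccfg
        )
        for j, i in enumerate(labeled_idx):
            labels3[i] = approach3.labels[j]

    reports: dict = {}
    if labeled_idx:
        reference = [truth_labels[i] for i in labeled_idx]
        for approach, labels in (
            ("approach1", labels1),
            ("approach2", labels2),
            ("approach3", labels3),
        ):
            if approach == "approach3" and approach3 is None:
                continue
            predicted = [labels[i] for i in labeled_idx]
            reports[approach] = {
                task: _evaluate.score(predicted, reference, task)
                for task in ("switch", "add-on")
            }

    return PipelineResult(
        members=members,
        exclusions=exclusions,
        duration_model=model,
        events=all_events,
        episodes=episodes,
        episode_members=episode_members,
        labels_approach1=labels1,
        labels_approach2=labels2,
        labels_approach3=labels3,
        truth_labels=truth_labels,
        approach3=approach3,
        reports=reports,
    )
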