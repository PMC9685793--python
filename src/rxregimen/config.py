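"""Configuration dataclasses and YAML loading.

One YAML file configures the whole pipeline; each section maps to one
module.  Every constant that the method leaves open (ATC prefix set, gap
trimming quantile, classification thresholds, fold counts, seeds) is a knob
here so variants can be swapped in without touching code.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "CohortConfig",
    "SeeConfig",
    "CoexposureConfig",
    "RuleEntry",
    "ClassifyConfig",
    "PipelineConfig",
    "load_config",
]

# ATC codes of the anti-seizure drug palette used throughout.
ATC_CLONAZEPAM = "N05BA09"
ATC_PHENYTOIN = "N03AB02"


@dataclasses.dataclass
class CohortConfig:
    """Incident new-user cohort definition.

    Anti-seizure medications are the ATC N03A group plus clonazepam, which
    is classed as a benzodiazepine (N05BA09) yet is used as an ASM in
    epilepsy care.  Eligibility: epilepsy diagnosis (ICD-8 345 / ICD-10
    G40*), first-ever ASM redemption on/after that diagnosis, minimum age
    at the index date, index date inside the calendar window.
    """

    asm_atc_prefixes: tuple[str, ...] = ("N03A", ATC_CLONAZEPAM)
    epilepsy_icd_prefixes: tuple[str, ...] = ("G40", "345")
    min_age: float = 65.0
    study_start: dt.date = dt.date(1996, 1, 1)
    study_end: dt.date = dt.date(2018, 1, 1)
    followup_days: int = 730


@dataclasses.dataclass
class SeeConfig:
    """Supply-duration estimator knobs (gap clustering)."""

    trim_quantile: float = 0.8
    k_min: int = 1
    k_max: int = 5
    min_gaps: int = 10
    default_duration_days: int = 30
    seed: int = 0


@dataclasses.dataclass
class CoexposureConfig:
    """Overlap-algebra knobs.

    ``grace_gap_days`` lets same-drug supply intervals separated by a short
    gap merge into one medication event (0 = only overlapping/abutting).
    ``denominator_scope`` picks whose treatment end bounds the potential
    co-exposure time: any ASM event of the person, or only the pair itself.
    """

    grace_gap_days: int = 0
    denominator_scope: str = "any_asm"  # or "pair_only"


@dataclasses.dataclass(frozen=True)
class RuleEntry:
    """One pharmacological override: an ATC (or pair "A+B") forced to a label."""

    pattern: str
    label: str = "add-on"


def default_rules() -> tuple[RuleEntry, ...]:
    # Clonazepam: short-course first-line drug for myoclonic seizures.
    # Phenytoin: co-drug for convulsive status epilepticus, not for long-term
    # combination use.  Brief overlaps involving either are add-ons, not switches.
    return (RuleEntry(ATC_CLONAZEPAM, "add-on"), RuleEntry(ATC_PHENYTOIN, "add-on"))


@dataclasses.dataclass
class ClassifyConfig:
    """Thresholds, rule table and supervised-learning settings."""

    add_on_threshold: float = 0.35
    switch_threshold: float = 0.10
    rules: tuple[RuleEntry, ...] = dataclasses.field(default_factory=default_rules)
    models: tuple[str, ...] = (
        "linear_regression",
        "naive_bayes",
        "svm",
        "neural_network",
        "cart",
        "random_forest",
    )
    n_folds: int = 8
    test_fraction: float = 0.25
    seed: int = 0
    linear_model: str = "linear"  # or "logistic"


@dataclasses.dataclass
class PipelineConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    see: SeeConfig = dataclasses.field(default_factory=SeeConfig)
    coexposure: CoexposureConfig = dataclasses.field(default_factory=CoexposureConfig)
    classify: ClassifyConfig = dataclasses.field(default_factory=ClassifyConfig)


def _coerce_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _build(section: dict, cls, **coercions):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if key in coercions:
            value = coercions[key](value)
        kwargs[key] = value
    return cls(**kwargs)


def _coerce_rules(entries) -> tuple[RuleEntry, ...]:
    rules = []
    for entry in entries:
        if isinstance(entry, str):
            rules.append(RuleEntry(entry))
        elif isinstance(entry, dict):
            pattern = entry.get("pattern", "")
            label = entry.get("label", "add-on")
            if label not in ("switch", "add-on", "unknown"):
                raise ValueError(f"rule label must be switch/add-on/unknown, got {label!r}")
            rules.append(RuleEntry(pattern, label))
        else:
            raise ValueError(f"malformed rule entry: {entry!r}")
        if not rules[-1].pattern or rules[-1].pattern != rules[-1].pattern.upper():
            raise ValueError(f"rule pattern must be a non-empty uppercase ATC: {entry!r}")
    return tuple(rules)


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, applying defaults.

    The YAML layout mirrors the dataclasses::

        cohort: {min_age: 65, followup_days: 730, ...}
        see: {trim_quantile: 0.8, k_max: 5, ...}
        coexposure: {grace_gap_days: 0, denominator_scope: any_asm}
        classify: {add_on_threshold: 0.35, rules: [N05BA09, N03AB02], ...}
    """
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for section, values in overrides.items():
            data.setdefault(section, {}).update(values)
    cfg = PipelineConfig()
    if "cohort" in data:
        cfg.cohort = _build(
            data["cohort"],
            CohortConfig,
            asm_atc_prefixes=tuple,
            epilepsy_icd_prefixes=tuple,
            study_start=_coerce_date,
            study_end=_coerce_date,
        )
    if "see" in data:
        cfg.see = _build(data["see"], SeeConfig)
    if "coexposure" in data:
        cfg.coexposure = _build(data["coexposure"], CoexposureConfig)
        if cfg.coexposure.denominator_scope not in ("any_asm", "pair_only"):
            raise ValueError(
                f"denominator_scope must be any_asm or pair_only, "
                f"got {cfg.coexposure.denominator_scope!r}"
            )
    if "classify" in data:
        cfg.classify = _build(
            data["classify"], ClassifyConfig, rules=_coerce_rules, models=tuple
        )
    return cfg


def is_asm(atc: str, prefixes=CohortConfig.asm_atc_prefixes) -> bool:
    """Whether an ATC code counts as an anti-seizure medication."""
    return any(atc.startswith(p) for p in prefixes)
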