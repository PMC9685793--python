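"""Data-driven prescription supply-duration estimation.

Nordic prescription registers record the redemption date but not the number
of days a dispensation covers.  The estimator here recovers supply
durations from the data themselves, in the spirit of the Sessa Empirical
Estimator: for each drug (ATC code) it pools the *refill gaps* — day
differences between consecutive redemptions of the same drug by the same
person — trims the long right tail at an ECDF quantile (gaps beyond it are
treatment interruptions, not supplies), and clusters the remaining gaps
with k-means, choosing k by mean silhouette width.  Each cluster's median
is a candidate supply duration (e.g. one-month and three-month packs
produce clusters near 30 and 90 days).  A prescription is then assigned
the cluster median closest to that person's own median refill gap for the
drug; persons with a single redemption get the smallest cluster (the most
conservative supply), and drugs with too few gaps to fit fall back to a
configurable default.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .config import SeeConfig
from .registry_io import PrescriptionRecord

__all__ = [
    "DurationModel",
    "PrescriptionWithDuration",
    "fit_duration_model",
    "assign_durations",
    "compute_refill_gaps",
]


@dataclasses.dataclass(frozen=True)
class PrescriptionWithDuration:
    """A prescription annotated with its estimated supply duration."""

    person_id: str
    atc: str
    redeem_date: dt.date
    duration_days: int


@dataclasses.dataclass
class DurationModel:
    """Fitted per-ATC refill-gap clusters.

    ``cluster_medians`` maps ATC -> ascending tuple of cluster medians in
    days; drugs absent from the map had fewer than ``min_gaps`` usable
    gaps and fall back to ``default_duration_days``.
    """

    cluster_medians: dict[str, tuple[float, ...]]
    fitted_on_n_gaps: dict[str, int]
    trim_quantile: float
    k_range: tuple[int, int]
    default_duration_days: int
    all_defaults: bool = False  # no ATC had enough gaps

    def durations_for(self, atc: str) -> tuple[float, ...]:
        return self.cluster_medians.get(atc, (float(self.default_duration_days),))

    def to_csv(self, path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["atc", "cluster_id", "median_days", "n"])
            for atc in sorted(self.cluster_medians):
                n = self.fitted_on_n_gaps[atc]
                for i, median in enumerate(self.cluster_medians[atc]):
                    writer.writerow([atc, i, median, n])


def compute_refill_gaps(
    prescriptions: Iterable[PrescriptionRecord],
) -> dict[str, dict[str, list[int]]]:
    """Per-ATC, per-person positive day gaps between consecutive redemptions."""
    dates: dict[tuple[str, str], list] = {}
    for rx in prescriptions:
        dates.setdefault((rx.atc, rx.person_id), []).append(rx.redeem_date)
    gaps: dict[str, dict[str, list[int]]] = {}
    for (atc, pid), ds in dates.items():
        ds.sort()
        person_gaps = [
            (b - a).days for a, b in zip(ds, ds[1:]) if (b - a).days > 0
        ]
        if person_gaps:
            gaps.setdefault(atc, {})[pid] = person_gaps
    return gaps


def _choose_k(values: np.ndarray, k_min: int, k_max: int, seed: int) -> int:
    distinct = np.unique(values).size
    if distinct < 3 or k_max == 1:
        return 1
    best_k, best_score = None, -np.inf
    X = values.reshape(-1, 1)
    for k in range(max(k_min, 2), min(k_max, distinct) + 1):
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
        score = silhouette_score(X, labels)
        # strict > keeps ties on the smaller k
        if score > best_score:
            best_k, best_score = k, score
    return best_k if best_k is not None else 1


def fit_duration_model(
    prescriptions: Iterable[PrescriptionRecord], config: SeeConfig | None = None
) -> DurationModel:
    """Fit refill-gap clusters per ATC.

    Pools gaps across persons per ATC, trims gaps above the
    ``trim_quantile`` ECDF quantile, then k-means with k selected by mean
    silhouette over ``k_min..k_max`` (k=1 when fewer than 3 distinct gap
    values remain).  Deterministic given the config seed.
    """
    cfg = config or SeeConfig()
    gaps_by_atc = compute_refill_gaps(prescriptions)
    medians: dict[str, tuple[float, ...]] = {}
    n_gaps: dict[str, int] = {}
    for atc in sorted(gaps_by_atc):
        pooled = np.asarray(
            [g for person_gaps in gaps_by_atc[atc].values() for g in person_gaps],
            dtype=float,
        )
        pooled.sort()
        if pooled.size < cfg.min_gaps:
            continue
        threshold = np.quantile(pooled, cfg.trim_quantile)
        kept = pooled[pooled <= threshold]
        if kept.size == 0:
            continue
        k = _choose_k(kept, cfg.k_min, cfg.k_max, cfg.seed)
        if k == 1:
            medians[atc] = (float(np.median(kept)),)
        else:
            labels = KMeans(n_clusters=k, random_state=cfg.seed, n_init=10).fit_predict(
                kept.reshape(-1, 1)
            )
            cluster_meds = sorted(
                float(np.median(kept[labels == c])) for c in range(k)
            )
            medians[atc] = tuple(cluster_meds)
        n_gaps[atc] = int(kept.size)
    return DurationModel(
        cluster_medians=medians,
        fitted_on_n_gaps=n_gaps,
        trim_quantile=cfg.trim_quantile,
        k_range=(cfg.k_min, cfg.k_max),
        default_duration_days=cfg.default_duration_days,
        all_defaults=not medians,
    )


def assign_durations(
    prescriptions: Sequence[PrescriptionRecord], model: DurationModel
) -> list[PrescriptionWithDuration]:
    """Annotate each prescription with its supply duration in whole days.

    Nearest-cluster rule: the duration is the fitted cluster median closest
    (absolute difference) to the person's own median refill gap for that
    drug; persons without a computable gap get the smallest cluster median.
    Total and deterministic given the model.
    """
    gaps_by_atc = compute_refill_gaps(prescriptions)
    out = []
    for rx in prescriptions:
        clusters = model.durations_for(rx.atc)
        person_gaps = gaps_by_atc.get(rx.atc, {}).get(rx.person_id)
        if person_gaps is None:
            duration = min(clusters)
        else:
            person_median = float(np.median(person_gaps))
            duration = min(clusters, key=lambda c: (abs(c - person_median), c))
        out.append(
            PrescriptionWithDuration(
                person_id=rx.person_id,
                atc=rx.atc,
                redeem_date=rx.redeem_date,
                duration_days=max(1, round(duration)),
            )
        )
    return out
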