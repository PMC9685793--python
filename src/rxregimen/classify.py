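"""Switch / add-on / unknown labeling of co-exposure episodes.

Three approaches of increasing sophistication:

* **Approach 1 — thresholds.**  An episode is an *add-on* when the
  co-exposure proportion N is at least 35% and a *switch* when N is at
  most 10%; anything between is *unknown*.  Short-course add-ons (a second
  drug used briefly on top of ongoing therapy) produce small N and are the
  known failure mode of this rule.
* **Approach 2 — pharmacological overrides.**  Drugs that notoriously
  appear as brief add-ons (clonazepam, short-course first-line drug for
  myoclonic seizures; phenytoin, a status-epilepticus co-drug unsuited to
  long-term combination) force the add-on label regardless of N; episodes
  matching no rule keep their approach-1 label.
* **Approach 3 — supervised learning.**  Six models (linear regression
  thresholded at 0.5, naive Bayes, SVM, a small neural network, CART and
  random forest) are trained on a nine-variable feature vector with
  8-fold cross-validation, folds built so every drug-pair combination is
  represented, and evaluated as two one-vs-rest binary tasks (switch,
  add-on).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortMember
from .coexposure import CoExposureEpisode
from .config import ClassifyConfig, RuleEntry

__all__ = [
    "LABELS",
    "EpisodeFeatures",
    "ModelReport",
    "Approach3Result",
    "DegenerateTaskError",
    "classify_approach1",
    "classify_approach2",
    "build_features",
    "features_to_frame",
    "assign_folds",
    "train_and_classify_approach3",
]

LABELS = ("switch", "add-on", "unknown")
TASKS = ("switch", "add-on")
MODEL_NAMES = (
    "linear_regression",
    "naive_bayes",
    "svm",
    "neural_network",
    "cart",
    "random_forest",
)


class DegenerateTaskError(ValueError):
    """A classification task has fewer than two classes in the labels."""


def classify_approach1(
    episode: CoExposureEpisode | float,
    add_on_threshold: float = 0.35,
    switch_threshold: float = 0.10,
) -> str:
    """Threshold rule on the co-exposure proportion N."""
    n = episode if isinstance(episode, float) else episode.N
    if n >= add_on_threshold:
        return "add-on"
    if n <= switch_threshold:
        return "switch"
    return "unknown"


def _rule_matches(rule: RuleEntry, episode: CoExposureEpisode) -> bool:
    if "+" in rule.pattern:
        a, b = rule.pattern.split("+", 1)
        return {a, b} == {episode.drug_first, episode.drug_second}
    return rule.pattern in (episode.drug_first, episode.drug_second)


def classify_approach2(
    episode: CoExposureEpisode,
    rules: Sequence[RuleEntry],
    approach1_label: Optional[str] = None,
    add_on_threshold: float = 0.35,
    switch_threshold: float = 0.10,
) -> str:
    """Pharmacological overrides on top of the threshold rule.

    The first matching rule's label wins; otherwise the approach-1 label
    passes through unchanged.
    """
    for rule in rules:
        if _rule_matches(rule, episode):
            return rule.label
    if approach1_label is None:
        approach1_label = classify_approach1(episode, add_on_threshold, switch_threshold)
    return approach1_label


@dataclasses.dataclass(frozen=True)
class EpisodeFeatures:
    """The nine-variable feature vector of one episode.

    The medication-event duration feature is realized as two numbers (one
    per overlapping event).  ``person_id`` and the drug pair are carried as
    metadata only and never enter the design matrix.
    """

    person_id: str
    drug_first: str
    drug_second: str
    j_days: int
    days_first_coexposure_to_followup_end: int
    sequence_index: int
    followup_length_days: int
    index_year: int
    event_first_duration_days: int
    event_second_duration_days: int
    first_diag_icd: str
    hosp_discharge_to_first_rx_days: int
    hosp_duration_days: int


def build_features(episode: CoExposureEpisode, member: CohortMember) -> EpisodeFeatures:
    """Assemble the feature vector from an episode and its cohort member."""
    return EpisodeFeatures(
        person_id=member.person_id,
        drug_first=episode.drug_first,
        drug_second=episode.drug_second,
        j_days=episode.J,
        days_first_coexposure_to_followup_end=(
            member.followup_end - episode.overlap_start
        ).days,
        sequence_index=episode.sequence_index,
        followup_length_days=member.followup_days,
        index_year=member.index_date.year,
        event_first_duration_days=episode.event_first_days,
        event_second_duration_days=episode.event_second_days,
        first_diag_icd=member.first_diag_icd,
        hosp_discharge_to_first_rx_days=(
            member.index_date - member.diag_discharge_date
        ).days,
        hosp_duration_days=member.hosp_duration_days,
    )


NUMERIC_FEATURES = [
    "j_days",
    "days_first_coexposure_to_followup_end",
    "sequence_index",
    "followup_length_days",
    "index_year",
    "event_first_duration_days",
    "event_second_duration_days",
    "hosp_discharge_to_first_rx_days",
    "hosp_duration_days",
]


def features_to_frame(features: Sequence[EpisodeFeatures]) -> pd.DataFrame:
    """Design matrix: numeric features plus one-hot encoded diagnosis code."""
    df = pd.DataFrame([dataclasses.asdict(f) for f in features])
    X = df[NUMERIC_FEATURES].astype(float)
    icd = pd.get_dummies(df["first_diag_icd"], prefix="icd", dtype=float)
    return pd.concat([X, icd], axis=1)


def assign_folds(
    pairs: Sequence[tuple[str, str]], n_folds: int, seed: int
) -> np.ndarray:
    """Combination-aware fold assignment.

    Episodes of a drug-pair combination with at least ``n_folds`` episodes
    are dealt (after a seeded shuffle) round-robin so the combination
    appears in every fold; smaller combinations are dealt round-robin
    across a global counter so they spread as evenly as possible.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, pair in enumerate(pairs):
        groups[tuple(sorted(pair))].append(i)
    folds = np.empty(len(pairs), dtype=int)
    cursor = 0
    for pair in sorted(groups):
        idx = np.array(groups[pair])
        rng.shuffle(idx)
        if len(idx) >= n_folds:
            for j, i in enumerate(idx):
                folds[i] = j % n_folds
        else:
            for i in idx:
                folds[i] = cursor % n_folds
                cursor += 1
    return folds


def _make_estimator(name: str, seed: int, linear_model: str = "linear"):
    if name == "linear_regression":
        if linear_model == "logistic":
            return LogisticRegression(max_iter=1000)
        return LinearRegression()
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if name == "neural_network":
        return make_pipeline(
            StandardScaler(),
            # no early stopping: its held-out split is too small to be
            # informative at the episode counts this tool typically sees
            MLPClassifier(
                hidden_layer_sizes=(16,),
                max_iter=1000,
                random_state=seed,
            ),
        )
    if name == "cart":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def _fit_predict(name, est, X_train, y_train, X_test):
    """Fit and return (binary predictions, continuous scores) on X_test."""
    if name == "linear_regression" and isinstance(est, LinearRegression):
        est.fit(X_train, y_train.astype(float))
        score = est.predict(X_test)
        return score >= 0.5, score
    est.fit(X_train, y_train)
    if hasattr(est, "predict_proba"):
        score = est.predict_proba(X_test)[:, 1]
    else:
        score = est.decision_function(X_test)
    return est.predict(X_test).astype(bool), score


@dataclasses.dataclass
class ModelReport:
    """Cross-validation summary of one model on one one-vs-rest task."""

    model: str
    task: str
    fold_accuracies: list[float]
    median_accuracy: float
    sensitivity: float  # pooled over out-of-fold predictions
    specificity: float
    median_fold_sensitivity: float
    auc: Optional[float] = None
    holdout_accuracy: Optional[float] = None


@dataclasses.dataclass
class Approach3Result:
    reports: list[ModelReport]
    best_model: dict[str, str]  # task -> model name
    labels: list[str]  # combined per-episode label from the best models
    fold_assignment: np.ndarray
    oof_scores: dict[tuple[str, str], np.ndarray]  # (model, task) -> scores
    oof_predictions: dict[tuple[str, str], np.ndarray]


def _stratified_split(labels: np.ndarray, test_fraction: float, rng) -> np.ndarray:
    """Boolean test mask, stratified by label."""
    test = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_test = int(round(len(idx) * test_fraction))
        test[idx[:n_test]] = True
    return test


def train_and_classify_approach3(
    features: Sequence[EpisodeFeatures],
    reference_labels: Sequence[str],
    config: ClassifyConfig | None = None,
) -> Approach3Result:
    """Six-model cross-validated classification of episodes.

    Each requested model is evaluated on two one-vs-rest binary tasks
    (switch-vs-rest, add-on-vs-rest) with combination-aware k-fold
    cross-validation: fold accuracies, their median, pooled out-of-fold
    sensitivity/specificity and AUC.  A stratified train/test split
    (default 75/25) additionally yields a held-out accuracy per model and
    task.  The best model per task — highest median fold accuracy, ties
    broken by median fold sensitivity — supplies the deployed labels,
    combined across tasks by the larger out-of-fold score (neither task
    positive means *unknown*).  Deterministic given the config seed.
    """
    cfg = config or ClassifyConfig()
    labels = np.asarray(reference_labels)
    if len(labels) != len(features):
        raise ValueError("features and reference_labels must align 1:1")
    if np.unique(labels).size < 2:
        raise DegenerateTaskError("reference labels contain a single class")

    X = features_to_frame(features).to_numpy()
    pairs = [(f.drug_first, f.drug_second) for f in features]
    folds = assign_folds(pairs, cfg.n_folds, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    test_mask = _stratified_split(labels, cfg.test_fraction, rng)

    reports: list[ModelReport] = []
    oof_scores: dict[tuple[str, str], np.ndarray] = {}
    oof_preds: dict[tuple[str, str], np.ndarray] = {}
    for task in TASKS:
        y = labels == task
        if y.all() or not y.any():
            raise DegenerateTaskError(f"task {task!r} has a single class")
        for name in cfg.models:
            accs, sens = [], []
            pred = np.zeros(len(y), dtype=bool)
            score = np.zeros(len(y), dtype=float)
            for f in range(cfg.n_folds):
                tr, te = folds != f, folds == f
                if not te.any():
                    continue
                est = _make_estimator(name, cfg.seed, cfg.linear_model)
                p, s = _fit_predict(name, est, X[tr], y[tr], X[te])
                pred[te], score[te] = p, s
                accs.append(float((p == y[te]).mean()))
                pos = y[te]
                sens.append(float((p & pos).sum() / pos.sum()) if pos.any() else np.nan)
            tp = int((pred & y).sum())
            tn = int((~pred & ~y).sum())
            fp = int((pred & ~y).sum())
            fn = int((~pred & y).sum())
            est = _make_estimator(name, cfg.seed, cfg.linear_model)
            p_ho, _ = _fit_predict(
                name, est, X[~test_mask], y[~test_mask], X[test_mask]
            )
            reports.append(
                ModelReport(
                    model=name,
                    task=task,
                    fold_accuracies=accs,
                    median_accuracy=float(np.median(accs)),
                    sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
                    specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
                    median_fold_sensitivity=float(np.nanmedian(sens)),
                    auc=float(roc_auc_score(y, score)),
                    holdout_accuracy=float((p_ho == y[test_mask]).mean()),
                )
            )
            oof_scores[(name, task)] = score
            oof_preds[(name, task)] = pred

    best_model = {}
    for task in TASKS:
        candidates = [r for r in reports if r.task == task]
        best = max(
            candidates, key=lambda r: (r.median_accuracy, r.median_fold_sensitivity)
        )
        best_model[task] = best.model

    sw_pred = oof_preds[(best_model["switch"], "switch")]
    ad_pred = oof_preds[(best_model["add-on"], "add-on")]
    sw_score = oof_scores[(best_model["switch"], "switch")]
    ad_score = oof_scores[(best_model["add-on"], "add-on")]
    combined = []
    for i in range(len(labels)):
        if sw_pred[i] and ad_pred[i]:
            combined.append("switch" if sw_score[i] >= ad_score[i] else "add-on")
        elif sw_pred[i]:
            combined.append("switch")
        elif ad_pred[i]:
            combined.append("add-on")
        else:
            combined.append("unknown")
    return Approach3Result(
        reports=reports,
        best_model=best_model,
        labels=combined,
        fold_assignment=folds,
        oof_scores=oof_scores,
        oof_predictions=oof_preds,
    )
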