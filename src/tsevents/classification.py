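"""Maximum-similarity classification with reference models.

The classifier follows a three-step strategy: (I) build one reference
model per class from a training cohort, after screening outlying subjects
within each class; (II) compare a new subject with every model; (III)
assign the class whose model is most similar.  Ties are broken towards
the lexicographically smallest label and flagged.

The API follows the model/results convention of statistical modelling
packages: :class:`EventClassifier` holds the training data and
configuration, ``fit()`` returns a :class:`ClassifierResults` carrying the
per-class reference models, the outlier screening verdicts, a
``predict()`` method and a ``summary()`` table.  ``cross_validate`` runs
the stratified k-fold protocol (k=10 by default, i.e. 90% training / 10%
testing per fold) and reports per-class and overall accuracy.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import SubjectRecord
from .modeling import (
    DegenerateModelError,
    ModelConfig,
    OutlierParams,
    OutlierVerdict,
    ReferenceModel,
    build_reference_model,
    detect_outliers,
    model_similarity,
    pairwise_similarity_matrix,
)
from .similarity import FeatureScaling

__all__ = [
    "ClassifierConfig",
    "EventClassifier",
    "ClassifierResults",
    "Prediction",
    "CVResult",
    "cross_validate",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration shared by training and cross-validation.

    ``anchor_weight`` fixes the weight of the event anchor-time feature in
    the similarity scaling (0 for domains where event timing varies
    freely, e.g. stabilometric falls); ``None`` keeps equal feature
    weights.  ``screen_outliers`` applies the four-criteria vote within
    each training class before model building.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    outlier: OutlierParams = field(default_factory=OutlierParams)
    anchor_weight: float | None = None
    screen_outliers: bool = True


@dataclass(frozen=True)
class Prediction:
    label: str
    scores: dict[str, float]
    tie: bool


class EventClassifier:
    """Event-based subject classifier (model object).

    Parameters
    ----------
    subjects : list of SubjectRecord
        Training subjects; every series leaf must already carry event
        annotations (run the detector first).
    labels : list of str
        Class label per subject; at least two distinct classes.
    config : ClassifierConfig
    """

    def __init__(
        self,
        subjects: list[SubjectRecord],
        labels: list[str],
        config: ClassifierConfig = ClassifierConfig(),
    ) -> None:
        if len(subjects) != len(labels):
            raise ValueError("subjects and labels must have the same length")
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        self.subjects = list(subjects)
        self.labels = list(labels)
        self.classes = classes
        self.config = config

    @classmethod
    def from_cohort(cls, cohort, config: ClassifierConfig = ClassifierConfig()):
        """Build from a synthetic cohort (subjects carry their class_label)."""
        return cls(list(cohort.subjects), [s.class_label for s in cohort.subjects], config)

    def fit(self) -> "ClassifierResults":
        """Screen outliers per class, build one reference model per class."""
        pooled = [e for s in self.subjects for e in s.pooled_events()]
        if not pooled:
            raise DegenerateModelError("training cohort contains no events")
        sp = {
            float(leaf.series.sampling_period_ms)
            for s in self.subjects
            for _, leaf in s.iter_series_leaves()
        }
        if len(sp) != 1:
            raise ValueError("mixed sampling periods in training cohort")
        models_sp = sp.pop()
        scaling = FeatureScaling.from_events(
            pooled, sampling_period_ms=models_sp, anchor_weight=self.config.anchor_weight
        )

        models: dict[str, ReferenceModel] = {}
        verdicts: dict[str, list[OutlierVerdict]] = {}
        for label in self.classes:
            members = [s for s, l in zip(self.subjects, self.labels) if l == label]
            retained = members
            if self.config.screen_outliers and len(members) >= 3:
                # screening asks "is this subject typical of its own class",
                # so the similarity scale is class-internal
                class_events = [e for s in members for e in s.pooled_events()]
                class_scaling = (
                    FeatureScaling.from_events(
                        class_events,
                        sampling_period_ms=models_sp,
                        anchor_weight=self.config.anchor_weight,
                    )
                    if class_events
                    else scaling
                )
                matrix = pairwise_similarity_matrix(members, class_scaling)
                v = detect_outliers(
                    matrix, self.config.outlier, [s.subject_id for s in members]
                )
                verdicts[label] = v
                retained = [s for s, verdict in zip(members, v) if not verdict.is_outlier]
            else:
                verdicts[label] = []
            if len(retained) < 2:
                raise DegenerateModelError(
                    f"class {label!r} has fewer than 2 non-outlier training subjects"
                )
            models[label] = build_reference_model(
                retained, label, self.config.model, scaling
            )
        return ClassifierResults(self, models, scaling, verdicts)


class ClassifierResults:
    """Fitted state: per-class reference models plus diagnostics."""

    def __init__(
        self,
        model: EventClassifier,
        models: dict[str, ReferenceModel],
        scaling: FeatureScaling,
        outlier_verdicts: dict[str, list[OutlierVerdict]],
    ) -> None:
        self.model = model
        self.models = models
        self.scaling = scaling
        self.outlier_verdicts = outlier_verdicts

    def similarity_scores(self, subject: SubjectRecord) -> dict[str, float]:
        return {
            label: model_similarity(subject, m, self.scaling)
            for label, m in self.models.items()
        }

    def predict(self, subject: SubjectRecord) -> Prediction:
        """Argmax-similarity class; ties flagged and broken lexicographically."""
        scores = self.similarity_scores(subject)
        best = max(scores.values())
        winners = sorted(l for l, s in scores.items() if best - s <= _TIE_TOL)
        return Prediction(label=winners[0], scores=scores, tie=len(winners) > 1)

    def state_hash(self) -> str:
        """Deterministic digest of the fitted state (models + scaling)."""
        payload = {
            "scaling": {
                "ranges": list(np.round(self.scaling.ranges, 12)),
                "weights": list(np.round(self.scaling.weights, 12)),
            },
            "models": {
                label: [
                    [
                        e.event_type,
                        round(e.duration_ms, 9),
                        round(e.magnitude, 9),
                        e.anchor_timestamp,
                        round(e.support, 9),
                        e.cluster_size,
                    ]
                    for e in m.events
                ]
                for label, m in sorted(self.models.items())
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def summary(self) -> str:
        lines = ["Event-based reference-model classifier", "=" * 42]
        for label in sorted(self.models):
            m = self.models[label]
            flagged = [v.subject_id for v in self.outlier_verdicts.get(label, []) if v.is_outlier]
            lines.append(
                f"class {label!r}: {len(m.events)} model event(s) from "
                f"{len(m.provenance.get('training_ids', []))} subjects"
                + (f"; outliers removed: {', '.join(flagged)}" if flagged else "")
            )
            lines.append(m.as_table().to_string(index=False))
        return "\n".join(lines)


@dataclass
class CVResult:
    """Cross-validation outcome.

    ``assignments`` has one row per subject with its fold, true and
    predicted label and tie flag; accuracies are pooled over folds
    (per-fold accuracies are recoverable from ``assignments``).
    """

    assignments: pd.DataFrame
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    k: int
    seed: int

    def summary(self) -> str:
        lines = [f"{self.k}-fold cross-validation (seed {self.seed})", "-" * 44]
        lines.append(f"{'Class':<16}{'Accuracy':>10}")
        for label, acc in sorted(self.per_class_accuracy.items()):
            lines.append(f"{label:<16}{acc:>9.2f}%")
        lines.append(f"{'overall':<16}{self.overall_accuracy:>9.2f}%")
        return "\n".join(lines)


def cross_validate(
    subjects: list[SubjectRecord],
    labels: list[str],
    k: int = 10,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
) -> CVResult:
    """Stratified k-fold evaluation of the classification strategy.

    Outlier screening happens inside each training fold only, never on the
    held-out subjects.  Per-class accuracy is correct/total within the
    class, pooled across folds, on the 0-100 scale.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} subjects < k={k}; "
            f"reducing to {counts.min()} stratified folds",
            stacklevel=2,
        )
        k = int(counts.min())
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        clf = EventClassifier(
            [subjects[i] for i in train_idx], [labels[i] for i in train_idx], config
        )
        res = clf.fit()
        for i in test_idx:
            pred = res.predict(subjects[i])
            rows.append(
                {
                    "subject_id": subjects[i].subject_id,
                    "fold": fold,
                    "true": labels[i],
                    "predicted": pred.label,
                    "tie": pred.tie,
                }
            )
    df = pd.DataFrame(rows)
    per_class = {
        label: 100.0 * float((grp.predicted == grp.true).mean())
        for label, grp in df.groupby("true")
    }
    overall = 100.0 * float((df.predicted == df.true).mean())
    return CVResult(
        assignments=df,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        k=k,
        seed=seed,
    )
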