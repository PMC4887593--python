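"""Reference-model generation and similarity-matrix outlier screening.

A reference model is a class prototype: the set of events that are "often
found" across a training cohort.  All events of all retained training
series are pooled and clustered by average-linkage agglomerative
clustering on the event dissimilarity ``1 - event_similarity`` (events of
different types never merge); each cluster whose support — the fraction of
training series contributing at least one event — reaches ``min_support``
contributes one model event, its medoid, so every model row is a real
observed event.

Before a model is built, outlying subjects are screened out from the
pairwise subject-similarity matrix by a vote over four criteria that mimic
how a human eyeballing a similarity matrix spots the odd one out:

C1  the subject's mean similarity to the cohort is far below the cohort
    average (z-score test on row means);
C2  the subject resembles nobody (its best similarity is below an
    isolation threshold);
C3  the subject sits in a tiny cluster of the similarity dendrogram;
C4  removing the subject makes its own cluster noticeably tighter.

A subject is an outlier when at least ``vote_threshold`` criteria fire.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import Event, SubjectRecord
from .similarity import (
    FeatureScaling,
    event_similarity_matrix,
    series_similarity,
    subject_similarity,
)

__all__ = [
    "ModelEvent",
    "ReferenceModel",
    "ModelConfig",
    "OutlierParams",
    "OutlierVerdict",
    "DegenerateModelError",
    "pairwise_similarity_matrix",
    "detect_outliers",
    "build_reference_model",
    "model_similarity",
]

# events of different types must never merge during clustering
_TYPE_GATE_DISTANCE = 1.0e6


class DegenerateModelError(ValueError):
    """No event cluster reached the support threshold."""


@dataclass(frozen=True)
class ModelEvent:
    """One representative (medoid) event of a reference model."""

    event_type: str
    duration_ms: float
    magnitude: float
    anchor_timestamp: int
    support: float
    cluster_size: int

    def __post_init__(self) -> None:
        if not (0 < self.support <= 1):
            raise ValueError("support must be in (0, 1]")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")

    @property
    def anchor_index(self) -> int:
        # duck-types as an Event for the similarity machinery
        return self.anchor_timestamp


@dataclass
class ReferenceModel:
    """Class prototype: representative events plus provenance."""

    class_label: str
    events: list[ModelEvent]
    sampling_period_ms: float = 10.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.anchor_timestamp)
        if not self.events:
            raise DegenerateModelError(f"reference model for {self.class_label!r} is empty")

    def as_table(self) -> pd.DataFrame:
        """Model events in the tabular layout used for reporting."""
        return pd.DataFrame(
            {
                "#Event": np.arange(1, len(self.events) + 1),
                "Type": [e.event_type for e in self.events],
                "Duration (ms)": [e.duration_ms for e in self.events],
                "Magnitude": [e.magnitude for e in self.events],
                "#Timestamp": [e.anchor_timestamp for e in self.events],
                "Support": [e.support for e in self.events],
                "Cluster size": [e.cluster_size for e in self.events],
            }
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "class_label": self.class_label,
                    "sampling_period_ms": self.sampling_period_ms,
                    "provenance": self.provenance,
                    "events": [vars(e) | {} for e in self.events],
                },
                indent=2,
                default=lambda o: dict(o.__dict__) if hasattr(o, "__dict__") else str(o),
            )
        )

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        data = json.loads(Path(path).read_text())
        return cls(
            class_label=data["class_label"],
            events=[ModelEvent(**e) for e in data["events"]],
            sampling_period_ms=data.get("sampling_period_ms", 10.0),
            provenance=data.get("provenance", {}),
        )


@dataclass(frozen=True)
class ModelConfig:
    """Clustering parameters for reference-model generation.

    ``tau_m`` is the average-linkage cut on the 1-similarity scale;
    ``min_support`` the minimum fraction of training series a cluster must
    draw events from.
    """

    tau_m: float = 0.3
    min_support: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.tau_m:
            raise ValueError("tau_m must be positive")
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")


@dataclass(frozen=True)
class OutlierParams:
    """Thresholds of the four-criteria outlier vote."""

    z: float = 2.0
    isolation: float = 0.5
    min_cluster_size: int = 2
    delta: float = 0.05
    vote_threshold: int = 2
    cut: float = 0.5  # dendrogram cut on the 1-similarity scale


@dataclass(frozen=True)
class OutlierVerdict:
    subject_id: str
    criteria_hit: tuple[bool, bool, bool, bool]
    is_outlier: bool


def pairwise_similarity_matrix(
    subjects: Sequence[SubjectRecord],
    scaling: FeatureScaling,
    **subject_kwargs,
) -> np.ndarray:
    """Symmetric, unit-diagonal matrix of overall subject similarities."""
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = subject_similarity(subjects[i], subjects[j], scaling, **subject_kwargs).overall
            m[i, j] = m[j, i] = s
    return m


def detect_outliers(
    matrix: np.ndarray,
    params: OutlierParams = OutlierParams(),
    subject_ids: Sequence[str] | None = None,
) -> list[OutlierVerdict]:
    """Apply the four-criteria vote to a pairwise similarity matrix."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if n < 3:
        raise ValueError("outlier detection needs at least 3 subjects")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("subject_ids length mismatch")

    off = m.copy()
    np.fill_diagonal(off, np.nan)
    row_means = np.nanmean(off, axis=1)
    mu = row_means.mean()
    sd = row_means.std(ddof=1)
    c1 = row_means < mu - params.z * sd

    c2 = np.nanmax(off, axis=1) < params.isolation

    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    labels = fcluster(
        linkage(squareform(d, checks=False), method="average"),
        t=params.cut,
        criterion="distance",
    )
    sizes = np.bincount(labels)
    c3 = sizes[labels] < params.min_cluster_size

    def cohesion(members: np.ndarray) -> float:
        # mean pairwise similarity; a singleton is vacuously cohesive
        if members.size < 2:
            return 1.0
        sub = m[np.ix_(members, members)]
        iu = np.triu_indices(members.size, k=1)
        return float(sub[iu].mean())

    c4 = np.zeros(n, dtype=bool)
    everyone = np.arange(n)
    for lbl in np.unique(labels):
        members = np.nonzero(labels == lbl)[0]
        if members.size == 1:
            # a subject alone in its cluster: its "cluster" degenerates to
            # the cohort — does removing it tighten the cohort as a whole?
            i = members[0]
            rest = np.delete(everyone, i)
            c4[i] = (cohesion(rest) - cohesion(everyone)) > params.delta
            continue
        full = cohesion(members)
        for pos, i in enumerate(members):
            rest = np.delete(members, pos)
            if (cohesion(rest) - full) > params.delta:
                c4[i] = True

    verdicts = []
    for i in range(n):
        hits = (bool(c1[i]), bool(c2[i]), bool(c3[i]), bool(c4[i]))
        verdicts.append(
            OutlierVerdict(
                subject_id=ids[i],
                criteria_hit=hits,
                is_outlier=sum(hits) >= params.vote_threshold,
            )
        )
    return verdicts


def _pooled_training_events(
    training: Sequence[SubjectRecord],
) -> tuple[list[Event], list[int], int, float]:
    """Pool annotated events with their series index; check uniform rate."""
    events: list[Event] = []
    series_of: list[int] = []
    periods = set()
    n_series = 0
    for subject in training:
        for _, leaf in subject.iter_series_leaves():
            if leaf.events is None:
                raise ValueError(
                    f"subject {subject.subject_id!r} has unannotated series; detect events first"
                )
            periods.add(float(leaf.series.sampling_period_ms))
            for e in leaf.events:
                events.append(e)
                series_of.append(n_series)
            n_series += 1
    if n_series == 0:
        raise ValueError("training subjects contain no series")
    if len(periods) > 1:
        raise ValueError(f"mixed sampling periods in training cohort: {sorted(periods)}")
    return events, series_of, n_series, periods.pop()


def build_reference_model(
    training: Sequence[SubjectRecord],
    class_label: str,
    config: ModelConfig = ModelConfig(),
    scaling: FeatureScaling | None = None,
) -> ReferenceModel:
    """Cluster the pooled training events into a class prototype.

    ``training`` must already be screened for outliers and annotated with
    events.  Raises :class:`DegenerateModelError` when no cluster reaches
    ``min_support``.
    """
    if not training:
        raise ValueError("training set must be non-empty")
    events, series_of, n_series, sp = _pooled_training_events(training)
    if not events:
        raise DegenerateModelError(f"no events in training cohort for {class_label!r}")
    if scaling is None:
        scaling = FeatureScaling.from_events(events, sampling_period_ms=sp)

    n = len(events)
    if n == 1:
        labels = np.array([1])
    else:
        sims = event_similarity_matrix(events, events, scaling, sp)
        dist = 1.0 - sims
        types = np.array([e.event_type for e in events])
        dist[types[:, None] != types[None, :]] = _TYPE_GATE_DISTANCE
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)
        labels = fcluster(
            linkage(squareform(dist, checks=False), method="average"),
            t=config.tau_m,
            criterion="distance",
        )

    series_of_arr = np.asarray(series_of)
    model_events = []
    for lbl in np.unique(labels):
        members = np.nonzero(labels == lbl)[0]
        support = np.unique(series_of_arr[members]).size / n_series
        if support < config.min_support:
            continue
        # the archetype should look like a typical series of its class: a
        # pattern found on average m times per series contributes its m
        # most central cluster members (the first being the medoid)
        multiplicity = max(1, int(round(members.size / n_series)))
        if members.size == 1:
            ordered = [events[members[0]]]
        else:
            sub = 1.0 - event_similarity_matrix(
                [events[i] for i in members], [events[i] for i in members], scaling, sp
            )
            costs = sub.sum(axis=1)
            # deterministic tie-break: earliest start, then type
            order = sorted(
                range(members.size),
                key=lambda p: (
                    costs[p],
                    events[members[p]].start_index,
                    events[members[p]].event_type,
                ),
            )
            ordered = [events[members[p]] for p in order]
        for rep in ordered[:multiplicity]:
            model_events.append(
                ModelEvent(
                    event_type=rep.event_type,
                    duration_ms=rep.duration_ms,
                    magnitude=rep.magnitude,
                    anchor_timestamp=rep.anchor_index,
                    support=float(support),
                    cluster_size=int(members.size),
                )
            )
    if not model_events:
        raise DegenerateModelError(
            f"degenerate model for {class_label!r}: no cluster reaches "
            f"min_support={config.min_support}"
        )
    return ReferenceModel(
        class_label=class_label,
        events=model_events,
        sampling_period_ms=sp,
        provenance={
            "training_ids": [s.subject_id for s in training],
            "n_series": n_series,
            "n_events": len(events),
            "tau_m": config.tau_m,
            "min_support": config.min_support,
        },
    )


def model_similarity(
    subject: SubjectRecord, model: ReferenceModel, scaling: FeatureScaling
) -> float:
    """Similarity of a subject to a reference model, in [0, 1].

    The model plays the role of an archetypal patient: its events are the
    event set of each series leaf of a pseudo-subject with the subject's
    tree shape.  Every series of the subject is compared with the model
    events by the series-similarity matching and the leaf scores are
    aggregated by the (equal-weight) tree mean, exactly as in a
    subject-to-subject comparison.
    """
    scores = []
    for _, leaf in subject.iter_series_leaves():
        if leaf.events is None:
            raise ValueError(
                f"subject {subject.subject_id!r} has unannotated series; detect events first"
            )
        scores.append(
            series_similarity(
                leaf.events,
                model.events,
                scaling,
                sampling_period_ms=leaf.series.sampling_period_ms,
                sampling_period_ms_b=model.sampling_period_ms,
            )
        )
    if not scores:
        raise ValueError(f"subject {subject.subject_id!r} has no series leaves")
    return float(np.mean(scores))
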