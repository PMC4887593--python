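"""Event-level, series-level and subject-level similarity.

All similarities are symmetric, reflexive and bounded in [0, 1].

* Two events of different type are maximally dissimilar (similarity 0).
  Same-type events are compared feature-wise (duration, magnitude, anchor
  time) with a normalised L1 term per feature,
  ``max(0, 1 - |f_a - f_b| / range_f)``, combined as a weighted mean.
* Two series are compared through a maximum-weight one-to-one matching of
  their event sets; the score ``2 * sum(matched weights) / (|a| + |b|)``
  penalises unmatched events on either side symmetrically and, with 0/1
  event weights, reduces exactly to the Dice-style expert-agreement
  statistic.
* Two subjects are compared along their shared register/measurement/
  condition tree: series leaves score by series similarity, quantitative
  leaves by a normalised absolute difference, qualitative leaves by
  equality, and every internal node aggregates its children by a weighted
  mean.  The annotated tree is returned as a :class:`SimilarityReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import SeriesLeaf, SubjectRecord, ValueLeaf

__all__ = [
    "FeatureScaling",
    "SimilarityReport",
    "event_features",
    "event_similarity",
    "event_similarity_matrix",
    "series_similarity",
    "subject_similarity",
]


@dataclass(frozen=True)
class FeatureScaling:
    """Normalisation ranges and weights for the three event features.

    Ranges must be positive; weights are non-negative and are normalised
    to sum to 1.  An ``anchor_weight`` of 0 makes event timing irrelevant
    (the usual choice for stabilometric falls, whose timing varies
    freely); equal weights are the default.
    """

    duration_range_ms: float
    magnitude_range: float
    anchor_range_ms: float
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if min(self.duration_range_ms, self.magnitude_range, self.anchor_range_ms) <= 0:
            raise ValueError("feature ranges must be positive")
        w = np.asarray(self.weights, dtype=float)
        if w.size != 3 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be 3 non-negative numbers with positive sum")
        object.__setattr__(self, "weights", tuple(w / w.sum()))

    @property
    def ranges(self) -> np.ndarray:
        return np.array([self.duration_range_ms, self.magnitude_range, self.anchor_range_ms])

    @classmethod
    def from_events(
        cls,
        events: Sequence,
        sampling_period_ms: float = 10.0,
        anchor_weight: float | None = None,
        quantiles: tuple[float, float] = (0.05, 0.95),
    ) -> "FeatureScaling":
        """Derive ranges from observed event features.

        Ranges are the inter-quantile spread (5-95% by default, floored),
        which is robust both to the heavy right tail of lognormal-like
        duration distributions and to contamination by outlying events;
        ``quantiles=(0, 1)`` recovers the plain peak-to-peak range.
        ``anchor_weight`` in [0, 1] fixes the anchor-time weight and splits
        the remainder equally between duration and magnitude; ``None``
        keeps equal weights.
        """
        if not events:
            raise ValueError("cannot derive scaling from an empty event list")
        feats = np.array([event_features(e, sampling_period_ms) for e in events])
        spread = np.quantile(feats, quantiles[1], axis=0) - np.quantile(
            feats, quantiles[0], axis=0
        )
        floors = np.array([1.0, 1e-6, 1.0])
        ranges = np.maximum(spread, floors)
        if anchor_weight is None:
            weights = (1 / 3, 1 / 3, 1 / 3)
        else:
            if not 0 <= anchor_weight <= 1:
                raise ValueError("anchor_weight must be in [0, 1]")
            rest = (1.0 - anchor_weight) / 2.0
            weights = (rest, rest, anchor_weight)
        return cls(float(ranges[0]), float(ranges[1]), float(ranges[2]), weights)


def event_features(event, sampling_period_ms: float = 10.0) -> np.ndarray:
    """Feature vector (duration_ms, magnitude, anchor_time_ms) of an event.

    Works on anything exposing ``duration_ms``, ``magnitude`` and
    ``anchor_index`` — detected events and reference-model events alike.
    """
    return np.array(
        [event.duration_ms, event.magnitude, event.anchor_index * sampling_period_ms]
    )


def event_similarity(a, b, scaling: FeatureScaling, sampling_period_ms: float = 10.0) -> float:
    """Similarity of two events in [0, 1]; 0 when their types differ."""
    if a.event_type != b.event_type:
        return 0.0
    fa = event_features(a, sampling_period_ms)
    fb = event_features(b, sampling_period_ms)
    terms = np.maximum(0.0, 1.0 - np.abs(fa - fb) / scaling.ranges)
    return float(np.dot(scaling.weights, terms))


def event_similarity_matrix(
    a: Sequence,
    b: Sequence,
    scaling: FeatureScaling,
    sampling_period_ms: float = 10.0,
    sampling_period_ms_b: float | None = None,
) -> np.ndarray:
    """Vectorised |a| x |b| matrix of pairwise event similarities."""
    sp_b = sampling_period_ms if sampling_period_ms_b is None else sampling_period_ms_b
    fa = np.array([event_features(e, sampling_period_ms) for e in a])
    fb = np.array([event_features(e, sp_b) for e in b])
    diffs = np.abs(fa[:, None, :] - fb[None, :, :]) / scaling.ranges
    sims = np.maximum(0.0, 1.0 - diffs) @ np.asarray(scaling.weights)
    types_a = np.array([e.event_type for e in a])
    types_b = np.array([e.event_type for e in b])
    sims[types_a[:, None] != types_b[None, :]] = 0.0
    return sims


def series_similarity(
    a: Sequence,
    b: Sequence,
    scaling: FeatureScaling,
    sampling_period_ms: float = 10.0,
    sampling_period_ms_b: float | None = None,
    return_matching: bool = False,
):
    """Event-matching similarity of two annotated series in [0, 1].

    A maximum-weight one-to-one matching between the two event sets is
    solved as an assignment problem; the score is
    ``2 * total matched weight / (|a| + |b|)``.  Two empty sets are
    vacuously identical (score 1); one empty side scores 0.

    With ``return_matching=True`` additionally returns the matched index
    pairs ``(i, j, weight)`` with strictly positive weight.
    """
    na, nb = len(a), len(b)
    if na == 0 and nb == 0:
        return (1.0, []) if return_matching else 1.0
    if na == 0 or nb == 0:
        return (0.0, []) if return_matching else 0.0
    weights = event_similarity_matrix(a, b, scaling, sampling_period_ms, sampling_period_ms_b)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    total = float(weights[rows, cols].sum())
    score = min(1.0, 2.0 * total / (na + nb))
    if not return_matching:
        return score
    matching = [
        (int(i), int(j), float(weights[i, j]))
        for i, j in zip(rows, cols)
        if weights[i, j] > 0
    ]
    return score, matching


@dataclass
class SimilarityReport:
    """Tree-annotated similarity between two subjects.

    ``node_scores`` maps every tree path (including the register root) to
    its score; ``overall`` equals the root score; ``matched_event_pairs``
    lists ``(leaf path, index in a, index in b, weight)`` tuples.
    """

    overall: float
    node_scores: dict[str, float]
    matched_event_pairs: list[tuple[str, int, int, float]]


def _leaf_score(
    path: str,
    la,
    lb,
    scaling: FeatureScaling,
    quantitative_ranges: Mapping[str, float],
    pairs: list,
) -> float:
    if isinstance(la, SeriesLeaf):
        if la.events is None or lb.events is None:
            raise ValueError(f"series leaf {path} has no event annotations; detect events first")
        score, matching = series_similarity(
            la.events,
            lb.events,
            scaling,
            sampling_period_ms=la.series.sampling_period_ms,
            sampling_period_ms_b=lb.series.sampling_period_ms,
            return_matching=True,
        )
        pairs.extend((path, i, j, w) for i, j, w in matching)
        return score
    if la.kind == "qualitative":
        return 1.0 if la.value == lb.value else 0.0
    va, vb = float(la.value), float(lb.value)
    if va == vb:
        return 1.0
    rng = quantitative_ranges.get(la.name, max(abs(va), abs(vb)))
    if rng <= 0:
        return 0.0
    return max(0.0, 1.0 - abs(va - vb) / rng)


def subject_similarity(
    p: SubjectRecord,
    q: SubjectRecord,
    scaling: FeatureScaling,
    quantitative_ranges: Mapping[str, float] | None = None,
    node_weights: Mapping[str, float] | None = None,
) -> SimilarityReport:
    """Compare two subjects along their shared tree.

    Both subjects must have the same measurement/condition/leaf structure;
    the first divergent path is named in the error otherwise.  Internal
    nodes aggregate their children by a weighted mean (equal weights
    unless ``node_weights`` assigns a weight to a child path).
    """
    quantitative_ranges = quantitative_ranges or {}
    node_weights = node_weights or {}
    if len(p.measurements) != len(q.measurements):
        raise ValueError("structural mismatch at /register: different number of measurements")
    scores: dict[str, float] = {}
    pairs: list[tuple[str, int, int, float]] = []

    def aggregate(children: list[tuple[str, float]], path: str) -> float:
        w = np.array([node_weights.get(cp, 1.0) for cp, _ in children], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError(f"bad node weights under {path}")
        vals = np.array([s for _, s in children])
        return float(np.dot(w / w.sum(), vals))

    m_children = []
    for mi, (ma, mb) in enumerate(zip(p.measurements, q.measurements), start=1):
        mpath = f"/register/measurement[{ma.name}]"
        if ma.name != mb.name:
            raise ValueError(
                f"structural mismatch at /register/measurement[{mi}]: "
                f"{ma.name!r} vs {mb.name!r}"
            )
        if len(ma.conditions) != len(mb.conditions):
            raise ValueError(f"structural mismatch at {mpath}: different number of conditions")
        c_children = []
        for ci, (ca, cb) in enumerate(zip(ma.conditions, mb.conditions), start=1):
            cpath = f"{mpath}/condition[{ca.name}]"
            if ca.name != cb.name:
                raise ValueError(
                    f"structural mismatch at {mpath}/condition[{ci}]: "
                    f"{ca.name!r} vs {cb.name!r}"
                )
            if len(ca.leaves) != len(cb.leaves):
                raise ValueError(f"structural mismatch at {cpath}: different number of leaves")
            l_children = []
            for la, lb in zip(ca.leaves, cb.leaves):
                tag = "series" if isinstance(la, SeriesLeaf) else "value"
                lpath = f"{cpath}/{tag}[{la.name}]"
                if type(la) is not type(lb) or la.name != lb.name or la.kind != lb.kind:
                    raise ValueError(f"structural mismatch at {lpath}")
                s = _leaf_score(lpath, la, lb, scaling, quantitative_ranges, pairs)
                scores[lpath] = s
                l_children.append((lpath, s))
            scores[cpath] = aggregate(l_children, cpath)
            c_children.append((cpath, scores[cpath]))
        scores[mpath] = aggregate(c_children, mpath)
        m_children.append((mpath, scores[mpath]))
    overall = aggregate(m_children, "/register")
    scores["/register"] = overall
    return SimilarityReport(overall=overall, node_scores=scores, matched_event_pairs=pairs)
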