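"""Expert-agreement metric and confusion-matrix indicators.

The agreement between an expert-annotated event set and the detector's
event set is summarised by the Dice-style statistic

    SIM = 2 * n_match / (n_exp + n_lang)

which is 1 exactly when both sets coincide and 0 when nothing matches.
Matching is one-to-one: an expert event and a detected event may pair up
when they have the same type and their intervals overlap by at least a
configurable fraction of the shorter one; the pairing maximises the number
of matched pairs.

Outlier-screening performance against expert judgement is reported with
the usual confusion-matrix indicators (precision, recall, specificity,
accuracy) as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Event

__all__ = [
    "EvaluationCounts",
    "ConfusionMatrix",
    "match_event_sets",
    "sim_exp_lang",
    "truncate",
    "sim_exp_lang_display",
    "confusion_metrics",
]


@dataclass(frozen=True)
class EvaluationCounts:
    """Event counts entering the agreement metric.

    ``n_exp``: events specified by the experts; ``n_lang``: events
    identified by the definition language; ``n_match``: events found by
    both (one-to-one).
    """

    n_exp: int
    n_lang: int
    n_match: int

    def __post_init__(self) -> None:
        if min(self.n_exp, self.n_lang, self.n_match) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_match > min(self.n_exp, self.n_lang):
            raise ValueError("n_match cannot exceed min(n_exp, n_lang)")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def match_event_sets(
    reference: Sequence[Event],
    detected: Sequence[Event],
    min_overlap: float = 0.5,
) -> EvaluationCounts:
    """Count one-to-one matches between two event lists.

    A pair is eligible when both events have the same type and their
    interval overlap covers at least ``min_overlap`` of the shorter event.
    The returned ``n_match`` is the maximum number of simultaneously
    matchable pairs (solved as an assignment problem), so the result does
    not depend on list order.
    """
    if not (0 < min_overlap <= 1):
        raise ValueError("min_overlap must be in (0, 1]")
    n_ref, n_det = len(reference), len(detected)
    if n_ref == 0 or n_det == 0:
        return EvaluationCounts(n_ref, n_det, 0)
    eligible = np.zeros((n_ref, n_det))
    for i, r in enumerate(reference):
        for j, d in enumerate(detected):
            if r.event_type != d.event_type:
                continue
            shorter = min(r.n_samples, d.n_samples)
            if r.overlap_samples(d) >= min_overlap * shorter:
                eligible[i, j] = 1.0
    rows, cols = linear_sum_assignment(eligible, maximize=True)
    n_match = int(eligible[rows, cols].sum())
    return EvaluationCounts(n_ref, n_det, n_match)


def sim_exp_lang(counts: EvaluationCounts) -> float:
    """Dice-style agreement ``2 * n_match / (n_exp + n_lang)`` in [0, 1].

    Two empty event sets agree vacuously: the 0/0 case is defined as 1.
    """
    denom = counts.n_exp + counts.n_lang
    if denom == 0:
        return 1.0
    return 2.0 * counts.n_match / denom


def truncate(x: float, decimals: int = 3) -> float:
    """Truncate (not round) ``x`` to ``decimals`` decimal places."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 1e-9) / factor


def sim_exp_lang_display(
    counts: EvaluationCounts, decimals: int = 3, convention: str = "truncate"
) -> float:
    """Agreement value formatted for display.

    Truncation is the default convention (three decimals), matching how
    the reference tables print the statistic; ``convention="round"`` is
    also supported.
    """
    value = sim_exp_lang(counts)
    if convention == "truncate":
        return truncate(value, decimals)
    if convention == "round":
        return round(value, decimals)
    raise ValueError(f"unknown display convention {convention!r}")


def confusion_metrics(cm: ConfusionMatrix, decimals: int | None = 1) -> dict[str, float | None]:
    """Precision, recall, specificity and accuracy as 0-100 percentages.

    A metric whose denominator is zero is reported as ``None`` (undefined)
    rather than 0.  ``decimals=None`` returns unrounded percentages.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        if den == 0:
            return None
        pct = 100.0 * num / den
        return pct if decimals is None else round(pct, decimals)

    return {
        "precision": ratio(cm.tp, cm.tp + cm.fp),
        "recall": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
    }
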