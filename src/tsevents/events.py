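"""Declarative event definitions and the event detector.

Two trigger families cover the reference domains:

* ``relative_amplitude`` — a wave (the signal between two successive zero
  crossings of the mean-centred trace) becomes an event when its peak
  deviation exceeds ``k`` times a robust baseline scale and its period lies
  within a band.  EEG spike waves use the 20-70 ms band, sharp waves
  70-200 ms; a spicule additionally requires an abrupt change of polarity,
  operationalised as an adjacent opposite-sign wave whose own peak exceeds
  ``k/2`` times the baseline scale.
* ``absolute_threshold`` — each maximal run of samples above a fixed
  threshold (the raised-foot pressure threshold for stabilometric falls)
  becomes one event; short gaps can be merged and a minimum duration
  enforced to guard against sensor chatter.

Definitions can be written in a small keyword rule-file syntax, one block
per event type::

    spike: factor 3, period 20 ms to 70 ms
    fall:
        value > 50
        min_duration 100 ms
        merge_gap 50 ms
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .core import AnnotatedSeries, Event, TimeSeries, make_event

__all__ = [
    "EventDefinition",
    "Wave",
    "segment_waves",
    "baseline_scale",
    "detect_events",
    "check_events",
    "parse_definitions",
    "parse_definitions_text",
    "RuleSyntaxError",
]

TRIGGERS = ("relative_amplitude", "absolute_threshold")
BASELINE_STATS = ("mad", "std")


class RuleSyntaxError(ValueError):
    """A rule file could not be parsed; the message carries the line number."""


@dataclass(frozen=True)
class EventDefinition:
    """One declarative event rule.

    Exactly one trigger mode is active.  ``amplitude_factor`` (k) scales
    the baseline amplitude for relative triggers; ``threshold`` is the
    absolute level for threshold triggers.  ``flank_factor`` (k') scales
    the amplitude the adjacent opposite-polarity wave must reach when
    ``polarity_change_required`` is set; it defaults to k/2.
    """

    event_type: str
    trigger: str
    amplitude_factor: float = 3.0
    threshold: float | None = None
    min_period_ms: float = 0.0
    max_period_ms: float = math.inf
    polarity_change_required: bool = False
    baseline_stat: str = "mad"
    min_duration_ms: float = 0.0
    merge_gap_ms: float = 0.0
    flank_factor: float | None = None

    def __post_init__(self) -> None:
        if self.trigger not in TRIGGERS:
            raise ValueError(f"unknown trigger mode {self.trigger!r}")
        if self.baseline_stat not in BASELINE_STATS:
            raise ValueError(f"baseline_stat must be one of {BASELINE_STATS}")
        if not self.min_period_ms <= self.max_period_ms:
            raise ValueError(
                f"{self.event_type}: min_period_ms ({self.min_period_ms}) exceeds "
                f"max_period_ms ({self.max_period_ms})"
            )
        if self.trigger == "absolute_threshold" and self.threshold is None:
            raise ValueError(f"{self.event_type}: absolute_threshold requires a threshold")
        if self.trigger == "relative_amplitude" and not self.amplitude_factor > 0:
            raise ValueError(f"{self.event_type}: amplitude_factor must be positive")

    @property
    def effective_flank_factor(self) -> float:
        return self.flank_factor if self.flank_factor is not None else self.amplitude_factor / 2.0


@dataclass(frozen=True)
class Wave:
    """A zero-crossing-delimited half-wave of the mean-centred signal."""

    start_index: int
    end_index: int
    peak_index: int
    peak_amplitude: float
    period_ms: float
    sign: int


# ---------------------------------------------------------------------------
# wave segmentation


def _centred(series: TimeSeries) -> np.ndarray:
    return series.values - series.values.mean()


def segment_waves(series: TimeSeries) -> list[Wave]:
    """Partition the mean-centred signal into constant-sign waves.

    Samples within a relative tolerance of zero inherit the sign of the
    next nonzero sample (trailing near-zeros keep the previous sign), so a
    sampled sinusoid whose grid hits the crossings exactly still splits
    into equal half-cycles.  A constant series yields no waves.
    """
    x = _centred(series)
    amax = float(np.max(np.abs(x))) if x.size else 0.0
    if amax <= 0.0:
        return []
    tol = 1e-9 * amax
    s = np.zeros(x.size, dtype=np.int8)
    s[x > tol] = 1
    s[x < -tol] = -1
    nz = np.nonzero(s)[0]
    if nz.size == 0:
        return []
    idx = np.searchsorted(nz, np.arange(x.size), side="left")
    idx = np.clip(idx, 0, nz.size - 1)
    filled = s[nz[idx]]
    cuts = np.nonzero(np.diff(filled))[0] + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [x.size]))
    sp = series.sampling_period_ms
    waves = []
    for a, b in zip(starts, ends):
        seg = np.abs(x[a:b])
        peak = a + int(np.argmax(seg))
        waves.append(
            Wave(
                start_index=int(a),
                end_index=int(b),
                peak_index=peak,
                peak_amplitude=float(np.abs(x[peak])),
                period_ms=(int(b) - int(a)) * sp,
                sign=int(filled[a]),
            )
        )
    return waves


def baseline_scale(series: TimeSeries, stat: str = "mad") -> float:
    """Robust amplitude scale of the mean-centred signal.

    ``mad`` (default) is the median absolute deviation scaled by 1.4826 to
    be comparable to a standard deviation under Gaussian noise; ``std`` is
    the plain standard deviation.
    """
    x = _centred(series)
    if stat == "mad":
        med = np.median(x)
        return float(1.4826 * np.median(np.abs(x - med)))
    if stat == "std":
        return float(np.std(x))
    raise ValueError(f"unknown baseline statistic {stat!r}")


# ---------------------------------------------------------------------------
# detection


def _detect_relative(
    series: TimeSeries, definition: EventDefinition, waves: list[Wave], scale: float
) -> list[Event]:
    sp = series.sampling_period_ms
    out = []
    amp_min = definition.amplitude_factor * scale
    flank_min = definition.effective_flank_factor * scale
    for i, w in enumerate(waves):
        if w.peak_amplitude <= amp_min:
            continue
        if not (definition.min_period_ms <= w.period_ms <= definition.max_period_ms):
            continue
        if w.period_ms < definition.min_duration_ms:
            continue
        if definition.polarity_change_required:
            neighbours = [waves[j] for j in (i - 1, i + 1) if 0 <= j < len(waves)]
            # waves alternate sign by construction, so adjacency itself is
            # the "no intervening sub-baseline wave" condition
            if not any(
                nb.sign == -w.sign and nb.peak_amplitude > flank_min for nb in neighbours
            ):
                continue
        out.append(
            make_event(
                definition.event_type, w.start_index, w.end_index, w.peak_amplitude, w.peak_index, sp
            )
        )
    return out


def _suprathreshold_runs(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = values > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = (np.nonzero(d == 1)[0] + 1).tolist()
    ends = (np.nonzero(d == -1)[0] + 1).tolist()
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(values.size)
    return list(zip(starts, ends))


def _detect_absolute(series: TimeSeries, definition: EventDefinition) -> list[Event]:
    sp = series.sampling_period_ms
    v = series.values
    runs = _suprathreshold_runs(v, float(definition.threshold))
    gap = int(round(definition.merge_gap_ms / sp))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        dur = (b - a) * sp
        if dur < definition.min_duration_ms:
            continue
        if not (definition.min_period_ms <= dur <= definition.max_period_ms):
            continue
        seg = v[a:b]
        supra = seg[seg > float(definition.threshold)]
        magnitude = float(supra.mean()) if supra.size else float(seg.mean())
        anchor = a + int(np.argmax(seg))
        out.append(make_event(definition.event_type, a, b, magnitude, anchor, sp))
    return out


def detect_events(series: TimeSeries, definitions: list[EventDefinition]) -> AnnotatedSeries:
    """Apply every definition to a cleaned series and collect its events.

    Detection is deterministic; the returned events are sorted by start
    index and are non-overlapping within each event type.
    """
    if not definitions:
        raise ValueError("definitions must be non-empty")
    waves: list[Wave] | None = None
    scales: dict[str, float] = {}
    events: list[Event] = []
    for d in definitions:
        if d.trigger == "relative_amplitude":
            if waves is None:
                waves = segment_waves(series)
            if d.baseline_stat not in scales:
                scales[d.baseline_stat] = baseline_scale(series, d.baseline_stat)
            events.extend(_detect_relative(series, d, waves, scales[d.baseline_stat]))
        elif d.trigger == "absolute_threshold":
            events.extend(_detect_absolute(series, d))
        else:  # pragma: no cover - EventDefinition already validates
            raise ValueError(f"unknown trigger mode {d.trigger!r}")
    return AnnotatedSeries(series=series, events=events)


# ---------------------------------------------------------------------------
# post-hoc verification (independent re-check of the definition predicates)


def check_events(annotated: AnnotatedSeries, definitions: list[EventDefinition]) -> None:
    """Re-check each detected event against its definition from raw samples.

    Works directly on the signal (constant sign over the interval,
    amplitude/threshold tests, period bounds) rather than through the
    detector's wave list; raises ``AssertionError`` on any violation.
    """
    by_type = {d.event_type: d for d in definitions}
    series = annotated.series
    sp = series.sampling_period_ms
    x = _centred(series)
    amax = float(np.max(np.abs(x))) if x.size else 0.0
    tol = 1e-9 * amax if amax > 0 else 0.0
    for e in annotated.events:
        d = by_type[e.event_type]
        assert d.min_period_ms <= e.duration_ms <= d.max_period_ms, e
        assert e.duration_ms >= d.min_duration_ms, e
        if d.trigger == "relative_amplitude":
            scale = baseline_scale(series, d.baseline_stat)
            seg = x[e.start_index : e.end_index]
            peak = float(np.max(np.abs(seg)))
            assert peak > d.amplitude_factor * scale, e
            assert abs(peak - e.magnitude) <= 1e-9 * max(1.0, peak), e
            sign = 1 if x[e.anchor_index] >= 0 else -1
            assert np.all(sign * seg >= -tol), f"sign not constant inside {e}"
        else:
            v = series.values[e.start_index : e.end_index]
            thr = float(d.threshold)
            if d.merge_gap_ms == 0:
                assert np.all(v > thr), e
            else:
                assert v[0] > thr and v[-1] > thr and np.max(v) > thr, e
            supra = v[v > thr]
            assert abs(float(supra.mean()) - e.magnitude) <= 1e-9 * max(1.0, abs(e.magnitude)), e


# ---------------------------------------------------------------------------
# rule-file parser

_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"

_CLAUSES: list[tuple[re.Pattern, str]] = [
    (re.compile(rf"^value\s*>\s*({_NUM})$"), "threshold"),
    (re.compile(rf"^threshold\s+({_NUM})$"), "threshold"),
    (re.compile(rf"^(?:factor|k)\s+({_NUM})$"), "factor"),
    (
        re.compile(rf"^period\s+({_NUM})\s*(?:ms)?\s*(?:-|–|to)\s*({_NUM})\s*(?:ms)?$"),
        "period",
    ),
    (re.compile(rf"^period_min_ms\s+({_NUM})$"), "period_min"),
    (re.compile(rf"^period_max_ms\s+({_NUM})$"), "period_max"),
    (re.compile(rf"^min_duration(?:_ms)?\s+({_NUM})\s*(?:ms)?$"), "min_duration"),
    (re.compile(rf"^merge_gap(?:_ms)?\s+({_NUM})\s*(?:ms)?$"), "merge_gap"),
    (re.compile(r"^polarity_change(?:\s+(true|false))?$"), "polarity"),
    (re.compile(r"^baseline\s+(mad|std)$"), "baseline"),
    (re.compile(r"^trigger\s+(relative_amplitude|absolute_threshold)$"), "trigger"),
    (re.compile(rf"^flank_factor\s+({_NUM})$"), "flank"),
]

_HEADER = re.compile(r"^([A-Za-z_][\w\-]*)\s*:\s*(.*)$")


def _apply_clause(block: dict, clause: str, lineno: int) -> None:
    for pattern, key in _CLAUSES:
        m = pattern.match(clause)
        if m:
            if key == "threshold":
                block["threshold"] = float(m.group(1))
            elif key == "factor":
                block["amplitude_factor"] = float(m.group(1))
            elif key == "period":
                block["min_period_ms"] = float(m.group(1))
                block["max_period_ms"] = float(m.group(2))
            elif key == "period_min":
                block["min_period_ms"] = float(m.group(1))
            elif key == "period_max":
                block["max_period_ms"] = float(m.group(1))
            elif key == "min_duration":
                block["min_duration_ms"] = float(m.group(1))
            elif key == "merge_gap":
                block["merge_gap_ms"] = float(m.group(1))
            elif key == "polarity":
                block["polarity_change_required"] = (m.group(1) or "true") == "true"
            elif key == "baseline":
                block["baseline_stat"] = m.group(1)
            elif key == "trigger":
                block["trigger"] = m.group(1)
            elif key == "flank":
                block["flank_factor"] = float(m.group(1))
            return
    raise RuleSyntaxError(f"line {lineno}: cannot parse clause {clause!r}")


def _finish_block(block: dict, lineno: int) -> EventDefinition:
    if "trigger" not in block:
        block["trigger"] = (
            "absolute_threshold" if "threshold" in block else "relative_amplitude"
        )
    try:
        return EventDefinition(**block)
    except ValueError as exc:
        raise RuleSyntaxError(f"line {lineno}: {exc}") from None


def parse_definitions_text(text: str) -> list[EventDefinition]:
    """Parse rule text (see module docstring for the syntax)."""
    definitions: list[EventDefinition] = []
    block: dict | None = None
    block_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        indented = line[0] in " \t"
        line = line.strip()
        if not indented:
            m = _HEADER.match(line)
            if not m:
                raise RuleSyntaxError(f"line {lineno}: expected 'name:' block header")
            if block is not None:
                definitions.append(_finish_block(block, block_line))
            block = {"event_type": m.group(1)}
            block_line = lineno
            inline = m.group(2).strip()
            if inline:
                for clause in inline.split(","):
                    _apply_clause(block, clause.strip(), lineno)
        else:
            if block is None:
                raise RuleSyntaxError(f"line {lineno}: clause outside any event block")
            _apply_clause(block, line, lineno)
    if block is not None:
        definitions.append(_finish_block(block, block_line))
    if not definitions:
        raise RuleSyntaxError("rule file defines no events")
    return definitions


def parse_definitions(path) -> list[EventDefinition]:
    """Parse a rule file into event definitions (one per block)."""
    return parse_definitions_text(Path(path).read_text())
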