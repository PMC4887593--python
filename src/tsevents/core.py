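"""Core domain types and file formats.

The package works on fixed-rate numeric signals (EEG channels, force-plate
pressure traces) organised into a three-level subject hierarchy:

    register (the subject) -> measurement -> condition -> leaf

where a leaf is either a :class:`TimeSeries` or a single tagged value
(quantitative or qualitative).  Regions of a series that carry the
information of interest to domain experts — paroxysmal EEG waves,
stabilometric falls — are represented as :class:`Event` objects located by
0-based, half-open sample intervals.

Three plain-text formats are supported:

* series CSV: one numeric sample per line, optional single header line;
* subject XML: ``register(id) > measurement(name) > condition(name) >
  {series(id, sampling_period_ms) | value(name, kind)}``;
* annotations: a delimited table with columns
  ``type,start,end,duration_ms,magnitude,anchor``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "DOMAIN_TAGS",
    "SchemaError",
    "TimeSeries",
    "Event",
    "make_event",
    "AnnotatedSeries",
    "SeriesLeaf",
    "ValueLeaf",
    "Condition",
    "Measurement",
    "SubjectRecord",
    "read_series_csv",
    "write_series_csv",
    "read_subject_xml",
    "write_subject_xml",
    "read_annotations",
    "write_annotations",
    "ANNOTATION_COLUMNS",
]

DOMAIN_TAGS = ("eeg", "stabilometry", "generic")
LEAF_KINDS = ("quantitative", "qualitative")

#: column order of the flat annotation table
ANNOTATION_COLUMNS = ("type", "start", "end", "duration_ms", "magnitude", "anchor")


class SchemaError(ValueError):
    """A subject document violates the canonical register/measurement/condition schema."""


@dataclass(frozen=True, eq=False)
class TimeSeries:
    """A fixed-rate numeric signal.

    Parameters
    ----------
    values : array-like of float
        Ordered samples; at least one, all finite after cleaning.
    sampling_period_ms : float
        Time between consecutive samples in milliseconds (default 10).
    series_id : str
        Identifier of the channel / trial.
    domain_tag : {'eeg', 'stabilometry', 'generic'}
        Domain the series comes from; drives per-domain defaults elsewhere.
    """

    values: np.ndarray
    sampling_period_ms: float = 10.0
    series_id: str = "series"
    domain_tag: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("a time series needs at least one sample")
        if not self.sampling_period_ms > 0:
            raise ValueError("sampling_period_ms must be positive")
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.sampling_period_ms

    def time_of(self, index: int) -> float:
        """Time in milliseconds of sample ``index`` from the series start."""
        return index * self.sampling_period_ms

    def replace(self, **changes) -> "TimeSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Event:
    """A typed, located, characterised region of a series.

    Indices are 0-based and the interval is half-open ``[start, end)``.
    ``magnitude`` is the amplitude (peak deviation from baseline) for EEG
    waves and the mean suprathreshold intensity for falls; ``anchor_index``
    points at the extremum inside the event.
    """

    event_type: str
    start_index: int
    end_index: int
    duration_ms: float
    magnitude: float
    anchor_index: int

    def __post_init__(self) -> None:
        if not self.start_index < self.end_index:
            raise ValueError("event interval is empty (start_index >= end_index)")
        if not (self.start_index <= self.anchor_index < self.end_index):
            raise ValueError("anchor_index must lie inside [start_index, end_index)")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be positive")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def overlap_samples(self, other: "Event") -> int:
        """Number of samples shared with ``other``."""
        lo = max(self.start_index, other.start_index)
        hi = min(self.end_index, other.end_index)
        return max(0, hi - lo)


def make_event(
    event_type: str,
    start_index: int,
    end_index: int,
    magnitude: float,
    anchor_index: int,
    sampling_period_ms: float,
) -> Event:
    """Build an :class:`Event` with the duration derived from its indices.

    This is the canonical constructor: it guarantees the invariant
    ``duration_ms == (end_index - start_index) * sampling_period_ms``.
    """
    return Event(
        event_type=event_type,
        start_index=int(start_index),
        end_index=int(end_index),
        duration_ms=(int(end_index) - int(start_index)) * sampling_period_ms,
        magnitude=float(magnitude),
        anchor_index=int(anchor_index),
    )


@dataclass(eq=False)
class AnnotatedSeries:
    """A series together with its (sorted, per-type non-overlapping) events."""

    series: TimeSeries
    events: list[Event]

    def __post_init__(self) -> None:
        evs = sorted(self.events, key=lambda e: (e.start_index, e.event_type))
        sp = self.series.sampling_period_ms
        n = self.series.n_samples
        last_end: dict[str, int] = {}
        for e in evs:
            if e.end_index > n or e.start_index < 0:
                raise ValueError(
                    f"event [{e.start_index}, {e.end_index}) outside series of {n} samples"
                )
            if abs(e.duration_ms - e.n_samples * sp) > 1e-9 * max(1.0, e.duration_ms):
                raise ValueError(
                    f"event duration {e.duration_ms} ms inconsistent with "
                    f"{e.n_samples} samples at {sp} ms"
                )
            if e.start_index < last_end.get(e.event_type, 0):
                raise ValueError(f"overlapping events of type {e.event_type!r}")
            last_end[e.event_type] = e.end_index
        self.events = evs

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# subject hierarchy


@dataclass(eq=False)
class SeriesLeaf:
    """A time-series leaf; ``events`` is filled by annotation/detection."""

    series: TimeSeries
    events: list[Event] | None = None

    @property
    def name(self) -> str:
        return self.series.series_id

    @property
    def kind(self) -> str:
        return "time_series"


@dataclass(eq=False)
class ValueLeaf:
    """A single-valued leaf, tagged quantitative or qualitative."""

    name: str
    value: object
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in LEAF_KINDS:
            raise ValueError(f"leaf kind must be one of {LEAF_KINDS}, got {self.kind!r}")
        if self.kind == "quantitative":
            self.value = float(self.value)  # type: ignore[arg-type]


Leaf = Union[SeriesLeaf, ValueLeaf]


@dataclass(eq=False)
class Condition:
    name: str
    leaves: list[Leaf] = field(default_factory=list)


@dataclass(eq=False)
class Measurement:
    name: str
    conditions: list[Condition] = field(default_factory=list)


@dataclass(eq=False)
class SubjectRecord:
    """Hierarchical record of one subject (the register root)."""

    subject_id: str
    measurements: list[Measurement] = field(default_factory=list)
    class_label: str | None = None

    def iter_leaves(self) -> Iterator[tuple[str, Leaf]]:
        """Yield ``(path, leaf)`` pairs in document order."""
        for m in self.measurements:
            for c in m.conditions:
                for leaf in c.leaves:
                    tag = "series" if isinstance(leaf, SeriesLeaf) else "value"
                    path = (
                        f"/register/measurement[{m.name}]"
                        f"/condition[{c.name}]/{tag}[{leaf.name}]"
                    )
                    yield path, leaf

    def iter_series_leaves(self) -> Iterator[tuple[str, SeriesLeaf]]:
        for path, leaf in self.iter_leaves():
            if isinstance(leaf, SeriesLeaf):
                yield path, leaf

    def pooled_events(self) -> list[Event]:
        """All annotated events of the subject, across every series leaf.

        Raises if any series leaf has not been annotated yet.
        """
        pooled: list[Event] = []
        for path, leaf in self.iter_series_leaves():
            if leaf.events is None:
                raise ValueError(f"series leaf {path} has no event annotations")
            pooled.extend(leaf.events)
        pooled.sort(key=lambda e: (e.start_index, e.event_type))
        return pooled

    def structure_signature(self):
        """Nested tuple describing the tree shape, for structural comparison."""
        return tuple(
            (
                m.name,
                tuple(
                    (c.name, tuple((leaf.kind, leaf.name) for leaf in c.leaves))
                    for c in m.conditions
                ),
            )
            for m in self.measurements
        )


# ---------------------------------------------------------------------------
# series CSV


def read_series_csv(
    path,
    sampling_period_ms: float = 10.0,
    series_id: str | None = None,
    domain_tag: str = "generic",
) -> TimeSeries:
    """Read a one-sample-per-line CSV file.

    A single non-numeric first line is tolerated as a header; any other
    non-numeric line is an error.  An empty file raises ``ValueError``.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise ValueError(f"empty series: {path}")
    try:
        float(lines[0][1])
    except ValueError:
        lines = lines[1:]  # header line
        if not lines:
            raise ValueError(f"empty series: {path}") from None
    values = []
    for lineno, token in lines:
        try:
            values.append(float(token))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable sample {token!r}") from None
    return TimeSeries(
        np.array(values),
        sampling_period_ms=sampling_period_ms,
        series_id=series_id or path.stem,
        domain_tag=domain_tag,
    )


def write_series_csv(series: TimeSeries, path, header: bool = False) -> None:
    """Write one sample per line; ``repr`` formatting round-trips exactly."""
    path = Path(path)
    lines = []
    if header:
        lines.append("value")
    lines.extend(repr(float(v)) for v in series.values)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# subject XML


def _schema_error(path: str, message: str) -> SchemaError:
    return SchemaError(f"{path}: {message}")


def read_subject_xml(path) -> SubjectRecord:
    """Parse a subject document into a :class:`SubjectRecord`.

    Schema violations raise :class:`SchemaError` naming the offending
    element path.
    """
    doc = etree.parse(str(path))
    root = doc.getroot()
    if root.tag != "register":
        raise _schema_error(f"/{root.tag}", "root element must be <register>")
    subject_id = root.get("id")
    if not subject_id:
        raise _schema_error("/register", "missing required attribute 'id'")
    record = SubjectRecord(subject_id=subject_id, class_label=root.get("class_label"))
    for mi, melem in enumerate(root, start=1):
        mpath = f"/register/measurement[{mi}]"
        if melem.tag != "measurement":
            raise _schema_error(f"/register/{melem.tag}[{mi}]", "expected <measurement>")
        mname = melem.get("name")
        if not mname:
            raise _schema_error(mpath, "missing required attribute 'name'")
        measurement = Measurement(name=mname)
        for ci, celem in enumerate(melem, start=1):
            cpath = f"{mpath}/condition[{ci}]"
            if celem.tag != "condition":
                raise _schema_error(f"{mpath}/{celem.tag}[{ci}]", "expected <condition>")
            cname = celem.get("name")
            if not cname:
                raise _schema_error(cpath, "missing required attribute 'name'")
            condition = Condition(name=cname)
            for li, lelem in enumerate(celem, start=1):
                lpath = f"{cpath}/{lelem.tag}[{li}]"
                if lelem.tag == "series":
                    sid = lelem.get("id")
                    if not sid:
                        raise _schema_error(lpath, "missing required attribute 'id'")
                    try:
                        sp = float(lelem.get("sampling_period_ms", "10"))
                    except ValueError:
                        raise _schema_error(lpath, "bad sampling_period_ms") from None
                    tokens = (lelem.text or "").split()
                    if not tokens:
                        raise _schema_error(lpath, "series has no samples")
                    try:
                        vals = np.array([float(t) for t in tokens])
                    except ValueError:
                        raise _schema_error(lpath, "non-numeric sample") from None
                    condition.leaves.append(
                        SeriesLeaf(
                            TimeSeries(
                                vals,
                                sampling_period_ms=sp,
                                series_id=sid,
                                domain_tag=lelem.get("domain", "generic"),
                            )
                        )
                    )
                elif lelem.tag == "value":
                    vname = lelem.get("name")
                    kind = lelem.get("kind")
                    if not vname:
                        raise _schema_error(lpath, "missing required attribute 'name'")
                    if kind not in LEAF_KINDS:
                        raise _schema_error(lpath, f"kind must be one of {LEAF_KINDS}")
                    text = (lelem.text or "").strip()
                    try:
                        condition.leaves.append(ValueLeaf(vname, text, kind))
                    except ValueError:
                        raise _schema_error(lpath, "non-numeric quantitative value") from None
                else:
                    raise _schema_error(lpath, "expected <series> or <value>")
            measurement.conditions.append(condition)
        record.measurements.append(measurement)
    return record


def write_subject_xml(subject: SubjectRecord, path) -> None:
    root = etree.Element("register", id=subject.subject_id)
    if subject.class_label is not None:
        root.set("class_label", subject.class_label)
    for m in subject.measurements:
        melem = etree.SubElement(root, "measurement", name=m.name)
        for c in m.conditions:
            celem = etree.SubElement(melem, "condition", name=c.name)
            for leaf in c.leaves:
                if isinstance(leaf, SeriesLeaf):
                    s = leaf.series
                    selem = etree.SubElement(
                        celem,
                        "series",
                        id=s.series_id,
                        sampling_period_ms=repr(float(s.sampling_period_ms)),
                        domain=s.domain_tag,
                    )
                    selem.text = " ".join(repr(float(v)) for v in s.values)
                else:
                    velem = etree.SubElement(celem, "value", name=leaf.name, kind=leaf.kind)
                    velem.text = (
                        repr(float(leaf.value))
                        if leaf.kind == "quantitative"
                        else str(leaf.value)
                    )
    etree.ElementTree(root).write(str(path), pretty_print=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# annotations


def write_annotations(annotated: "AnnotatedSeries | Sequence[Event]", path) -> None:
    """Write one record per event as a flat delimited table."""
    events = annotated.events if isinstance(annotated, AnnotatedSeries) else list(annotated)
    df = pd.DataFrame(
        [
            (e.event_type, e.start_index, e.end_index, e.duration_ms, e.magnitude, e.anchor_index)
            for e in events
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_annotations(path) -> list[Event]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns {sorted(missing)}")
    return [
        Event(
            event_type=str(r.type),
            start_index=int(r.start),
            end_index=int(r.end),
            duration_ms=float(r.duration_ms),
            magnitude=float(r.magnitude),
            anchor_index=int(r.anchor),
        )
        for r in df.itertuples()
    ]
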