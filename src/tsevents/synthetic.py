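"""Synthetic cohorts with planted, ground-truth events.

The generator emulates the statistical structure of the two study
cohorts so every pipeline stage is testable without any real recordings:

* EEG-like series (4000 samples at 10 ms): Gaussian baseline noise with
  paroxysm-like half-sine deflections of random polarity planted at
  non-overlapping random anchors.  Class presets follow the per-class
  event statistics of the reference cohorts — epileptic: 9.47 events per
  series on average, 195 ms mean duration, amplitude 78; healthy: 5.49 /
  56 ms / 54.
* Stabilometry-like series (1000 samples at 10 ms): near-zero pressure
  baseline with suprathreshold plateaus (falls) — basketball: 3.37 events
  / 754 ms / intensity 107; skating: 1.45 / 346 ms / 83.

Event counts are Poisson, durations lognormal (positivity), magnitudes
normal; standard deviations default to 20% of the mean since only means
are reported for the reference cohorts.  Every planted event is recorded
in the ground truth with exact sample indices.  Cohorts can include
injected outlier subjects whose feature means are shifted by a chosen
number of scale units in independently random directions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AnnotatedSeries,
    Condition,
    Event,
    Measurement,
    SeriesLeaf,
    SubjectRecord,
    TimeSeries,
    make_event,
)
from .events import EventDefinition, detect_events

__all__ = [
    "EventTypeSpec",
    "ClassSpec",
    "SyntheticCohort",
    "generate_series",
    "generate_cohort",
    "annotate_cohort",
    "default_definitions",
    "eeg_epileptic_spec",
    "eeg_healthy_spec",
    "stabilometry_basketball_spec",
    "stabilometry_skating_spec",
]


@dataclass(frozen=True)
class EventTypeSpec:
    """Distributional parameters of one planted event family.

    ``kind`` is the waveform: a half-sine ``deflection`` (EEG paroxysm)
    or a suprathreshold ``plateau`` (stabilometric fall).  Durations are
    drawn lognormal with the given mean/sd and clipped to
    ``[duration_min_ms, duration_max_ms]``; magnitudes are normal,
    floored at a small positive value.  ``polarity_flank`` appends an
    opposite-polarity half-amplitude flank (spicule-like shape).
    """

    name: str
    duration_mean_ms: float
    magnitude_mean: float
    duration_sd_ms: float | None = None
    magnitude_sd: float | None = None
    duration_min_ms: float = 20.0
    duration_max_ms: float = 600.0
    kind: str = "deflection"
    weight: float = 1.0
    polarity_flank: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("deflection", "plateau"):
            raise ValueError("kind must be 'deflection' or 'plateau'")
        if min(self.duration_mean_ms, self.magnitude_mean) <= 0:
            raise ValueError("means must be positive")
        if self.duration_sd_ms is None:
            object.__setattr__(self, "duration_sd_ms", 0.2 * self.duration_mean_ms)
        if self.magnitude_sd is None:
            object.__setattr__(self, "magnitude_sd", 0.2 * self.magnitude_mean)

    def draw_features(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (duration_ms, magnitude) pairs before clipping."""
        cv = self.duration_sd_ms / self.duration_mean_ms
        sigma2 = np.log1p(cv * cv)
        mu = np.log(self.duration_mean_ms) - sigma2 / 2.0
        durations = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        magnitudes = rng.normal(self.magnitude_mean, self.magnitude_sd, size=n)
        return durations, magnitudes


@dataclass(frozen=True)
class ClassSpec:
    """Generator parameters for one subject class."""

    label: str
    domain_tag: str
    event_types: tuple[EventTypeSpec, ...]
    events_per_series: float
    noise_sd: float
    baseline: float = 0.0
    n_samples: int = 4000
    sampling_period_ms: float = 10.0
    series_per_subject: int = 1

    def __post_init__(self) -> None:
        if self.events_per_series < 0:
            raise ValueError("events_per_series must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        longest = max(t.duration_max_ms for t in self.event_types)
        if self.n_samples * self.sampling_period_ms < longest:
            raise ValueError("series shorter than the longest plantable event")


@dataclass
class SyntheticCohort:
    """Labelled subjects with exact planted ground truth."""

    subjects: list[SubjectRecord]
    specs: list[ClassSpec]
    outlier_ids: list[str]
    seed: int

    @property
    def labels(self) -> list[str]:
        return [s.class_label for s in self.subjects]


# ---------------------------------------------------------------------------
# class presets (reference cohort statistics)

_EEG_KW = dict(domain_tag="eeg", noise_sd=10.0, n_samples=4000)
# the stabilometric protocol acquires 4 trials x 3 repetitions per subject
_STAB_KW = dict(
    domain_tag="stabilometry", noise_sd=5.0, n_samples=1000, series_per_subject=12
)


def eeg_epileptic_spec() -> ClassSpec:
    return ClassSpec(
        label="epileptic",
        event_types=(EventTypeSpec("paroxysm", duration_mean_ms=195.0, magnitude_mean=78.0),),
        events_per_series=9.47,
        **_EEG_KW,
    )


def eeg_healthy_spec() -> ClassSpec:
    return ClassSpec(
        label="healthy",
        event_types=(EventTypeSpec("paroxysm", duration_mean_ms=56.0, magnitude_mean=54.0),),
        events_per_series=5.49,
        **_EEG_KW,
    )


def stabilometry_basketball_spec() -> ClassSpec:
    return ClassSpec(
        label="basketball",
        event_types=(
            EventTypeSpec(
                "fall",
                duration_mean_ms=754.0,
                magnitude_mean=107.0,
                duration_min_ms=120.0,
                duration_max_ms=3000.0,
                kind="plateau",
            ),
        ),
        events_per_series=3.37,
        **_STAB_KW,
    )


def stabilometry_skating_spec() -> ClassSpec:
    return ClassSpec(
        label="skating",
        event_types=(
            EventTypeSpec(
                "fall",
                duration_mean_ms=346.0,
                magnitude_mean=83.0,
                duration_min_ms=120.0,
                duration_max_ms=3000.0,
                kind="plateau",
            ),
        ),
        events_per_series=1.45,
        **_STAB_KW,
    )


def default_definitions(domain_tag: str) -> list[EventDefinition]:
    """Detection rules matched to the synthetic presets of a domain.

    The EEG rule uses an amplitude factor of 4 so that, at 4000 samples
    per series, chance exceedances of the noise stay well below one false
    event per series; the fall rule guards against plateau fragmentation
    with a 50 ms merge gap and a 100 ms minimum duration.
    """
    if domain_tag == "eeg":
        return [
            EventDefinition(
                "paroxysm",
                trigger="relative_amplitude",
                amplitude_factor=4.0,
                min_period_ms=20.0,
                max_period_ms=600.0,
            )
        ]
    if domain_tag == "stabilometry":
        return [
            EventDefinition(
                "fall",
                trigger="absolute_threshold",
                threshold=50.0,
                min_duration_ms=100.0,
                merge_gap_ms=50.0,
            )
        ]
    raise ValueError(f"no default definitions for domain {domain_tag!r}")


# ---------------------------------------------------------------------------
# series generation


def _place_events(
    n_samples: int, lengths: Sequence[int], rng: np.random.Generator, gap: int = 3, retries: int = 500
) -> list[int]:
    """Uniform-random non-overlapping starts (with a small guard gap)."""
    placed: list[tuple[int, int]] = []
    starts = []
    for L in lengths:
        hi = n_samples - L - 1
        if hi < 1:
            raise ValueError(f"event of {L} samples does not fit in {n_samples}")
        for _ in range(retries):
            s = int(rng.integers(1, hi + 1))
            if all(s + L + gap <= a or b + gap <= s for a, b in placed):
                placed.append((s, s + L))
                starts.append(s)
                break
        else:
            raise ValueError(
                f"cannot place {len(lengths)} non-overlapping events of total length "
                f"{sum(lengths)} in {n_samples} samples"
            )
    return starts


def _half_sine(length: int) -> np.ndarray:
    # sampled strictly inside (0, pi) so no endpoint is zero
    return np.sin(np.pi * (np.arange(length) + 0.5) / length)


def generate_series(
    spec: ClassSpec, seed: int | np.random.Generator = 0, series_id: str = "s1"
) -> AnnotatedSeries:
    """Generate one series with planted events and exact ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sp = spec.sampling_period_ms
    values = spec.baseline + rng.normal(0.0, spec.noise_sd, spec.n_samples)

    n_events = int(rng.poisson(spec.events_per_series))
    # a finite trial can only hold so many events: truncate the count draw
    # at ~55% occupancy so non-overlapping placement stays feasible
    mean_dur = float(
        np.average(
            [t.duration_mean_ms for t in spec.event_types],
            weights=[t.weight for t in spec.event_types],
        )
    )
    capacity = int(0.55 * spec.n_samples * spec.sampling_period_ms / mean_dur)
    n_events = min(n_events, max(1, capacity)) if n_events else 0
    weights = np.array([t.weight for t in spec.event_types], dtype=float)
    type_idx = rng.choice(len(spec.event_types), size=n_events, p=weights / weights.sum())

    events: list[Event] = []
    lengths, mags, kinds = [], [], []
    for ti in type_idx:
        t = spec.event_types[ti]
        d, m = t.draw_features(1, rng)
        d = float(np.clip(d[0], t.duration_min_ms, t.duration_max_ms))
        mags.append(max(float(m[0]), 1e-3))
        lengths.append(max(2, int(round(d / sp))))
        kinds.append(t)
    starts = _place_events(spec.n_samples, lengths, rng) if n_events else []

    for t, L, A, s in zip(kinds, lengths, mags, starts):
        if t.kind == "deflection":
            polarity = 1.0 if rng.random() < 0.5 else -1.0
            values[s : s + L] += polarity * A * _half_sine(L)
            if t.polarity_flank:
                fl = max(2, L // 2)
                if s + L + fl <= spec.n_samples:
                    values[s + L : s + L + fl] += -polarity * (A / 2.0) * _half_sine(fl)
            anchor = s + int(np.argmax(np.abs(values[s : s + L] - spec.baseline)))
        else:  # plateau
            values[s : s + L] += A
            anchor = s + int(np.argmax(values[s : s + L]))
        events.append(make_event(t.name, s, s + L, A, anchor, sp))

    series = TimeSeries(
        values,
        sampling_period_ms=sp,
        series_id=series_id,
        domain_tag=spec.domain_tag,
    )
    return AnnotatedSeries(series=series, events=events)


# ---------------------------------------------------------------------------
# cohort generation


def _shift_spec(spec: ClassSpec, shift_sd: float, rng: np.random.Generator) -> ClassSpec:
    """Outlier variant: event-feature means shifted by ``shift_sd`` scale units.

    Each outlier subject gets its own shift: duration and magnitude means
    each move by the full ``shift_sd`` scale units, with independent random
    signs per subject, so injected outliers are heterogeneous rather than
    one colluding sub-population.  The shifted mean duration is capped so
    that non-overlapping placement stays feasible at the class event rate.
    """
    new_types = []
    for t in spec.event_types:
        s_dur = rng.choice([-1.0, 1.0])
        s_mag = rng.choice([-1.0, 1.0])
        dur = t.duration_mean_ms + s_dur * shift_sd * t.duration_sd_ms
        mag = t.magnitude_mean + s_mag * shift_sd * t.magnitude_sd
        cap = 0.35 * spec.n_samples * spec.sampling_period_ms / max(spec.events_per_series, 1e-9)
        dur = float(np.clip(dur, 2 * spec.sampling_period_ms, cap))
        # amplitude is physical: a shift past zero reflects
        mag = max(1e-3, abs(float(mag)))
        new_types.append(
            dataclasses.replace(
                t,
                duration_mean_ms=dur,
                magnitude_mean=mag,
                duration_sd_ms=t.duration_sd_ms,
                magnitude_sd=t.magnitude_sd,
                duration_max_ms=max(t.duration_max_ms, 2 * dur),
            )
        )
    return dataclasses.replace(spec, event_types=tuple(new_types))


def _make_subject(spec: ClassSpec, subject_id: str, rng: np.random.Generator) -> SubjectRecord:
    conditions = []
    for j in range(spec.series_per_subject):
        annotated = generate_series(spec, rng, series_id=f"trial{j + 1}")
        conditions.append(
            Condition(name=f"trial{j + 1}", leaves=[SeriesLeaf(annotated.series, annotated.events)])
        )
    return SubjectRecord(
        subject_id=subject_id,
        class_label=spec.label,
        measurements=[Measurement(name=spec.domain_tag, conditions=conditions)],
    )


def generate_cohort(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    outlier_fraction: float = 0.0,
    outlier_shift_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a labelled multi-class cohort, optionally with outliers.

    Subjects' series leaves carry the planted ground-truth events; the
    manifest of true outliers is recorded in ``outlier_ids``.  The whole
    cohort is a deterministic function of ``seed``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if not 0 <= outlier_fraction < 0.5:
        raise ValueError("outlier_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subjects: list[SubjectRecord] = []
    outlier_ids: list[str] = []
    n_out = int(round(outlier_fraction * n_per_class))
    for spec in specs:
        out_idx = set(rng.choice(n_per_class, size=n_out, replace=False).tolist()) if n_out else set()
        for i in range(n_per_class):
            sid = f"{spec.label}-{i + 1:03d}"
            s_spec = spec
            if i in out_idx:
                s_spec = _shift_spec(spec, outlier_shift_sd, rng)
                outlier_ids.append(sid)
            subjects.append(_make_subject(s_spec, sid, rng))
    return SyntheticCohort(
        subjects=subjects, specs=list(specs), outlier_ids=outlier_ids, seed=seed
    )


def annotate_cohort(
    cohort: SyntheticCohort, definitions: list[EventDefinition]
) -> list[SubjectRecord]:
    """Re-annotate cohort subjects with *detected* (not planted) events.

    Returns new SubjectRecords whose leaves carry the detector's output,
    as the end-to-end pipeline would see them; the cohort's ground truth
    is left untouched.
    """
    out = []
    for s in cohort.subjects:
        measurements = []
        for m in s.measurements:
            conditions = []
            for c in m.conditions:
                leaves = []
                for leaf in c.leaves:
                    if isinstance(leaf, SeriesLeaf):
                        detected = detect_events(leaf.series, definitions)
                        leaves.append(SeriesLeaf(leaf.series, detected.events))
                    else:
                        leaves.append(leaf)
                conditions.append(Condition(name=c.name, leaves=leaves))
            measurements.append(Measurement(name=m.name, conditions=conditions))
        out.append(
            SubjectRecord(
                subject_id=s.subject_id, class_label=s.class_label, measurements=measurements
            )
        )
    return out
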