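"""Noise and missing-value screening.

Medical test signals are typically corrupted at the start and the end of
the recording, where patient and supervisor are out of phase; those edges
are trimmed away.  Interior missing values (a pressure sensor reporting 0)
and inconsistent values (outside a domain-dependent plausible range) are
omitted — not interpolated — and a series is only considered valid when at
least 70% of its samples survive.  Invalid series are excluded from all
downstream modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries

__all__ = ["CleanResult", "trim_edges", "clean_series"]


@dataclass(frozen=True)
class CleanResult:
    """Outcome of :func:`clean_series`.

    ``series`` is ``None`` when every sample was dropped (a TimeSeries
    cannot be empty); ``valid`` is then necessarily False.
    """

    series: TimeSeries | None
    retained_fraction: float
    valid: bool
    dropped_indices: list[int]


def trim_edges(series: TimeSeries, start_index: int, end_index: int) -> TimeSeries:
    """Return the sub-series ``[start_index, end_index)``.

    Used to cut away the noisy lead-in/lead-out of a recording.
    """
    if not (0 <= start_index < end_index <= series.n_samples):
        raise ValueError(
            f"empty or out-of-range trim [{start_index}, {end_index}) "
            f"for series of {series.n_samples} samples"
        )
    return series.replace(values=series.values[start_index:end_index])


def clean_series(
    series: TimeSeries,
    missing_sentinel: float | None = None,
    valid_range: tuple[float, float] | None = None,
    validity_threshold: float = 0.70,
) -> CleanResult:
    """Drop missing/inconsistent samples and judge series validity.

    Parameters
    ----------
    missing_sentinel : float or None
        Value marking a missing reading (0 for stabilometric pressure
        sensors); ``None`` disables sentinel screening.
    valid_range : (lo, hi) or None
        Inclusive plausibility range; values outside it are dropped.
    validity_threshold : float in (0, 1]
        Minimum retained fraction for the series to count as valid.
        The comparison is inclusive: exactly 70% retained is valid.

    Retained values keep their original order; non-finite samples are
    always dropped.
    """
    if not (0 < validity_threshold <= 1):
        raise ValueError("validity_threshold must be in (0, 1]")
    v = series.values
    mask = np.isfinite(v)
    if missing_sentinel is not None:
        mask &= v != missing_sentinel
    if valid_range is not None:
        lo, hi = valid_range
        if not lo < hi:
            raise ValueError("valid_range must satisfy lo < hi")
        mask &= (v >= lo) & (v <= hi)
    retained_fraction = float(mask.sum()) / v.size
    valid = retained_fraction >= validity_threshold
    dropped = np.nonzero(~mask)[0].tolist()
    cleaned = series.replace(values=v[mask]) if mask.any() else None
    if cleaned is None:
        valid = False
    return CleanResult(
        series=cleaned,
        retained_fraction=retained_fraction,
        valid=valid,
        dropped_indices=dropped,
    )
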