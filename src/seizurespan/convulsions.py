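"""Clonic-seizure (convulsion) rate series.

Scored events are counted in 1-min bins, smoothed with a 5-min moving window
stepped by 1 min, then normalized and thresholded exactly like the cortical
amplitude series.  Voluntary movements are excluded unless asked for.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .ecog import BinnedSeries, NormalizedSeries, normalize_to_pretreatment
from .session import ConvulsionEvent, EVENT_CATEGORIES, SessionTimeline

SMOOTH_WINDOW_BINS = 5


def bin_event_rate(
    events: Iterable[ConvulsionEvent],
    timeline: SessionTimeline,
    categories: Sequence[str] | None = None,
    bin_range_min: tuple[int, int] | None = None,
    include_voluntary: bool = False,
) -> BinnedSeries:
    """Per-bin event counts (events/min at 1-min bins) for the category set.

    ``categories`` defaults to every convulsive category; VoluntaryMovement
    is rejected unless ``include_voluntary`` is set.
    """
    if categories is None:
        categories = [c for c in EVENT_CATEGORIES if c != "VoluntaryMovement"]
    for c in categories:
        if c not in EVENT_CATEGORIES:
            raise ValueError(f"unknown category {c!r}")
        if c == "VoluntaryMovement" and not include_voluntary:
            raise ValueError(
                "VoluntaryMovement is not a convulsion; pass include_voluntary=True "
                "to count it anyway"
            )
    catset = set(categories)
    events = list(events)
    times_min = np.array(
        [timeline.minutes_rel(e.time_s) for e in events if e.category in catset],
        dtype=float,
    )
    if bin_range_min is None:
        if times_min.size:
            lo = int(np.floor(times_min.min()))
            hi = int(np.floor(times_min.max())) + 1
        else:
            lo, hi = 0, 1
    else:
        lo, hi = bin_range_min
    starts = np.arange(lo, hi, dtype=float)
    counts = np.zeros(starts.size)
    if times_min.size:
        idx = np.floor(times_min).astype(int) - lo
        ok = (idx >= 0) & (idx < starts.size)
        np.add.at(counts, idx[ok], 1.0)
    return BinnedSeries(bin_start_min=starts, values=counts, kind="event_rate")


def smooth_rate(series: BinnedSeries, window_bins: int = SMOOTH_WINDOW_BINS,
                edges: str = "shrink") -> BinnedSeries:
    """Centered moving average over ``window_bins`` bins, stepped by one bin.

    ``edges='shrink'`` averages over the available bins near the ends (same
    bin grid out as in); ``edges='drop'`` removes bins without a full window.
    """
    if series.n_bins < 1:
        raise ValueError("need at least one bin")
    half = window_bins // 2
    v = series.values
    n = v.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = v[lo:hi].mean()
    starts = series.bin_start_min
    if edges == "drop":
        keep = slice(half, n - half) if n > 2 * half else slice(0, 0)
        out, starts = out[keep], starts[keep]
    elif edges != "shrink":
        raise ValueError(f"unknown edge mode {edges!r}")
    return BinnedSeries(bin_start_min=starts, values=out,
                        bin_width_min=series.bin_width_min, kind=series.kind)


def normalize_rate(
    series: BinnedSeries,
    baseline_window_min: tuple[float, float] = (-15.0, 0.0),
    smooth: bool = True,
) -> NormalizedSeries:
    """Smooth (5-min window) then normalize by the pre-treatment mean.

    Shares the normalization/percentile contract of the cortical amplitude
    series, including the degenerate-baseline error when the pre-treatment
    rate is zero.
    """
    if smooth:
        series = smooth_rate(series)
    return normalize_to_pretreatment(series, baseline_window_min)
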