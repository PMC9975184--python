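"""Cortical seizure quantification.

The scalar seizure-intensity measure is the RMS voltage in 1-min bins,
averaged over the valid contacts of the injected hemisphere, normalized by
the session's mean pre-treatment value.  A change is called significant when
the normalized value deviates from the 95th percentile of the pre-treatment
values.  Bin ``k`` covers ``[k, k+1)`` minutes relative to t = 0 (treatment
administration), so the t = 0 bin belongs to the post-treatment period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.signal

from .session import EcogRecording, SessionTimeline

#: Post-treatment evaluation span in minutes, by treatment of record.
POST_SPAN_MIN = {"DCZ": 60.0, "vehicle": 15.0}
PRE_SPAN_MIN = 15.0
#: Display scaling window (minutes relative to treatment).
DISPLAY_WINDOW_MIN = (-15.0, 12.0)


@dataclass
class BinnedSeries:
    """Contiguous equal-width time bins of a scalar session measure.

    ``bin_start_min[k]`` is the left edge of bin k in minutes relative to
    treatment; the bin covers ``[start, start + bin_width_min)``.
    """

    bin_start_min: np.ndarray
    values: np.ndarray
    bin_width_min: float = 1.0
    kind: str = "rms_uV"

    def __post_init__(self) -> None:
        self.bin_start_min = np.asarray(self.bin_start_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_start_min.shape != self.values.shape:
            raise ValueError("bin grid and values must align")
        if self.bin_start_min.size > 1:
            steps = np.diff(self.bin_start_min)
            if not np.allclose(steps, self.bin_width_min, atol=1e-9):
                raise ValueError("bins must be contiguous and equal width")
        if np.isnan(self.values).any():
            raise ValueError("values may not contain NaN (omit missing bins)")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def window_mask(self, start_min: float, end_min: float) -> np.ndarray:
        """Bins whose left edge lies in [start_min, end_min)."""
        return (self.bin_start_min >= start_min - 1e-9) & (
            self.bin_start_min < end_min - 1e-9
        )


@dataclass
class NormalizedSeries:
    """A BinnedSeries divided by its mean over the pre-treatment window.

    ``values`` are the analysis-scale normalized values (baseline mean 1);
    ``display_scale_factor`` > 1 indicates the series (and its percentile
    threshold) were divided for presentation — deviation calls are invariant
    to that scaling because threshold and values scale together.
    """

    raw: BinnedSeries
    values: np.ndarray
    baseline_window_min: tuple[float, float]
    baseline_mean: float
    baseline_p95: float
    display_scale_factor: float = 1.0

    @property
    def bin_start_min(self) -> np.ndarray:
        return self.raw.bin_start_min

    @property
    def bin_width_min(self) -> float:
        return self.raw.bin_width_min

    def window_mask(self, start_min: float, end_min: float) -> np.ndarray:
        return self.raw.window_mask(start_min, end_min)


@dataclass
class DeviationReport:
    """Per-bin significance flags against the pre-treatment 95th percentile."""

    bin_start_min: np.ndarray
    below_p95: np.ndarray
    above_p95: np.ndarray
    suppression_onset_min: float | None


@dataclass
class Spectrogram:
    """Short-time Fourier power, normalized per frequency by a baseline window.

    ``power`` holds the power ratio relative to the per-frequency baseline
    mean (its baseline-window average is 1 by construction); ``power_raw``
    keeps the unnormalized spectrum for energy checks.
    """

    times_s: np.ndarray
    frequencies_hz: np.ndarray
    power: np.ndarray
    power_raw: np.ndarray
    baseline_window_s: tuple[float, float]

    def to_db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.power, 1e-300))


# ---------------------------------------------------------------------------
# filtering


def design_standard_filters(
    sample_rate_hz: float,
    highpass_hz: float = 1.0,
    highpass_order: int = 10,
    bandstop_hz: tuple[float, float] = (48.0, 52.0),
    bandstop_order: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Butterworth high-pass + line-noise band-stop as second-order sections.

    ``bandstop_order`` is the filter order of the band-stop stage; Butterworth
    band filters of order 2N are designed from N analogue poles, hence the
    halving below.  Orders are doubled again in effect by the zero-phase
    forward-backward application in :func:`apply_standard_filters`.
    """
    if sample_rate_hz <= 2 * bandstop_hz[1]:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz too low for a "
            f"{bandstop_hz[0]}-{bandstop_hz[1]} Hz band-stop filter"
        )
    if bandstop_order % 2:
        raise ValueError("band-stop order must be even (2N poles)")
    sos_hp = scipy.signal.butter(
        highpass_order, highpass_hz, btype="highpass", fs=sample_rate_hz, output="sos"
    )
    sos_bs = scipy.signal.butter(
        bandstop_order // 2, bandstop_hz, btype="bandstop", fs=sample_rate_hz, output="sos"
    )
    return sos_hp, sos_bs


def apply_standard_filters(recording: EcogRecording, **filter_kwargs) -> EcogRecording:
    """Zero-phase 1-Hz high-pass (order 10) + 48-52-Hz band-stop (order 20).

    Returns a filtered copy; invalid channels pass through untouched (still
    flagged in the grid mask).
    """
    sos_hp, sos_bs = design_standard_filters(recording.sample_rate_hz, **filter_kwargs)
    out = recording.samples.copy()
    # the 1-Hz high-pass rings for seconds; extend reflection padding well
    # beyond scipy's default so edge transients stay out of the record
    padlen = int(min(3.0 * recording.sample_rate_hz, recording.n_samples - 2))
    for ch in recording.grid.valid_channels:
        x = scipy.signal.sosfiltfilt(sos_hp, recording.samples[ch], padlen=padlen)
        out[ch] = scipy.signal.sosfiltfilt(sos_bs, x, padlen=padlen)
    return EcogRecording(
        grid=recording.grid,
        sample_rate_hz=recording.sample_rate_hz,
        samples=out,
        start_time_s=recording.start_time_s,
    )


# ---------------------------------------------------------------------------
# binned RMS


def default_bin_range(recording: EcogRecording, timeline: SessionTimeline) -> tuple[int, int]:
    """Whole-minute bin range [first, last) covered by both the recording and
    the pre (-15..0) / post (0..60 DCZ, 0..15 vehicle) analysis spans."""
    rel_start = timeline.minutes_rel(recording.start_time_s)
    rel_end = timeline.minutes_rel(recording.end_time_s)
    lo = max(-PRE_SPAN_MIN, float(np.ceil(rel_start - 1e-9)))
    hi = min(POST_SPAN_MIN[timeline.treatment_of_record], float(np.floor(rel_end + 1e-9)))
    if hi <= lo:
        raise ValueError("recording does not cover any whole analysis bin")
    return int(lo), int(hi)


def rms_binned(
    recording: EcogRecording,
    timeline: SessionTimeline,
    channels: Sequence[int] | None = None,
    bin_range_min: tuple[int, int] | None = None,
    aggregate: str = "mean",
) -> BinnedSeries:
    """Per-bin RMS per channel, aggregated across the channel set.

    ``channels`` defaults to all valid contacts of the recording's grid; it
    must be a subset of the valid contacts.  ``aggregate`` is ``mean`` (the
    symmetric default) or ``median``.
    """
    grid = recording.grid
    if channels is None:
        channels = grid.valid_channels
    channels = np.asarray(channels, dtype=int)
    if channels.size == 0:
        raise ValueError("empty channel set")
    valid = set(grid.valid_channels.tolist())
    bad = [int(c) for c in channels if int(c) not in valid]
    if bad:
        raise ValueError(f"channels {bad} are not valid contacts")
    if bin_range_min is None:
        lo, hi = default_bin_range(recording, timeline)
    else:
        lo, hi = bin_range_min
        rel_start = timeline.minutes_rel(recording.start_time_s)
        rel_end = timeline.minutes_rel(recording.end_time_s)
        if lo < rel_start - 1e-9 or hi > rel_end + 1e-9:
            raise ValueError(
                f"requested bins [{lo}, {hi}) min outside recording "
                f"[{rel_start:.3f}, {rel_end:.3f}) min"
            )
    agg = {"mean": np.mean, "median": np.median}[aggregate]

    starts = np.arange(lo, hi, dtype=float)
    values = np.empty(starts.size)
    ref = timeline.reference_time_s
    for i, k in enumerate(starts):
        block = recording.slice_window(ref + k * 60.0, ref + (k + 1.0) * 60.0)
        per_channel = np.sqrt(np.mean(block[channels] ** 2, axis=1))
        values[i] = agg(per_channel)
    return BinnedSeries(bin_start_min=starts, values=values, kind="rms_uV")


# ---------------------------------------------------------------------------
# normalization and significance


def normalize_to_pretreatment(
    series: BinnedSeries, baseline_window_min: tuple[float, float] = (-PRE_SPAN_MIN, 0.0)
) -> NormalizedSeries:
    """Divide by the mean over the pre-treatment window; record the baseline
    95th percentile (linear-interpolation convention) of the normalized
    baseline values."""
    mask = series.window_mask(*baseline_window_min)
    if mask.sum() < 2:
        raise ValueError(
            f"baseline window {baseline_window_min} contains {int(mask.sum())} bins; "
            "need at least 2"
        )
    mean = float(series.values[mask].mean())
    if mean <= 0:
        raise ValueError(f"degenerate baseline (mean {mean:g} <= 0)")
    norm = series.values / mean
    p95 = float(np.percentile(norm[mask], 95.0))
    return NormalizedSeries(
        raw=series,
        values=norm,
        baseline_window_min=tuple(baseline_window_min),
        baseline_mean=mean,
        baseline_p95=p95,
    )


def display_scale(
    series: NormalizedSeries, window_min: tuple[float, float] = DISPLAY_WINDOW_MIN
) -> NormalizedSeries:
    """Presentation-only rescaling by the max |value| in ``window_min``.

    The percentile threshold is scaled with the values, so deviation calls
    are unchanged; the cumulative factor is recorded.
    """
    mask = series.window_mask(*window_min)
    if not mask.any():
        raise ValueError(f"display window {window_min} contains no bins")
    factor = float(np.max(np.abs(series.values[mask])))
    if factor == 0:
        raise ValueError("window maximum is zero; cannot scale")
    return NormalizedSeries(
        raw=series.raw,
        values=series.values / factor,
        baseline_window_min=series.baseline_window_min,
        baseline_mean=series.baseline_mean,
        baseline_p95=series.baseline_p95 / factor,
        display_scale_factor=series.display_scale_factor * factor,
    )


def detect_significant_deviation(
    series: NormalizedSeries, evaluation_window_min: tuple[float, float] | None = None
) -> DeviationReport:
    """Flag bins deviating from the pre-treatment 95th percentile and locate
    the suppression onset.

    The onset is the start (minutes, >= 0) of the final run of bins that sit
    below the threshold and persist through the end of the evaluation window;
    ``None`` when the series does not end below threshold.
    """
    p95 = series.baseline_p95
    starts = series.bin_start_min
    values = series.values
    if evaluation_window_min is not None:
        sel = series.window_mask(*evaluation_window_min) | (starts < 0)
    else:
        sel = np.ones_like(starts, dtype=bool)
    below = (values < p95) & sel
    above = (values > p95) & sel

    post = starts >= -1e-9
    post_idx = np.flatnonzero(post & sel)
    onset: float | None = None
    if post_idx.size and below[post_idx[-1]]:
        i = post_idx.size - 1
        while i > 0 and below[post_idx[i - 1]]:
            i -= 1
        onset = float(starts[post_idx[i]])
    return DeviationReport(
        bin_start_min=starts,
        below_p95=below,
        above_p95=above,
        suppression_onset_min=onset,
    )


# ---------------------------------------------------------------------------
# spectrogram


def spectrogram_normalized(
    recording: EcogRecording,
    channel: int,
    baseline_window_s: tuple[float, float],
    window_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> Spectrogram:
    """STFT power, each frequency row divided by its baseline-window mean.

    Defaults: 1-s Hann window, 50 % overlap.  The baseline window must span
    at least one analysis window.
    """
    fs = recording.sample_rate_hz
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap * nperseg))
    x = recording.samples[channel]
    freqs, t, sxx = scipy.signal.spectrogram(
        x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="spectrum", mode="psd",
    )
    times = recording.start_time_s + t
    b0, b1 = baseline_window_s
    bmask = (times >= b0) & (times <= b1)
    if not bmask.any():
        raise ValueError(
            f"baseline window {baseline_window_s} s shorter than one analysis window"
        )
    base = sxx[:, bmask].mean(axis=1)
    base = np.where(base > 0, base, np.nan)
    rel = sxx / base[:, None]
    return Spectrogram(
        times_s=times,
        frequencies_hz=freqs,
        power=rel,
        power_raw=sxx,
        baseline_window_s=(float(b0), float(b1)),
    )
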