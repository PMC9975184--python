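"""Electrode-array seizure spread mapping.

Per-channel RMS amplitude maps over a time window, and peak-normalized
threshold maps: the set of valid contacts whose RMS reaches a stated
fraction (one-half or one-third) of the peak contact.  The half-maximum
coverage fraction indexes how far the discharge has spread across the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .session import EcogRecording, ElectrodeGrid


@dataclass
class AmplitudeMap:
    """Per-contact RMS (microvolts) over one window; NA contacts carry NaN."""

    grid: ElectrodeGrid
    window_s: tuple[float, float]
    values: np.ndarray  # (n_channels,), NaN at invalid contacts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_channels,):
            raise ValueError("one value per grid contact required")

    @property
    def peak_channel(self) -> int:
        valid = self.grid.valid_channels
        # ties broken by lowest channel index (argmax is first-max already)
        return int(valid[np.argmax(self.values[valid])])

    @property
    def peak_value(self) -> float:
        return float(self.values[self.peak_channel])

    @property
    def na_channels(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.grid.valid_mask))


@dataclass
class SpreadMap:
    """Contacts at or above ``threshold_fraction`` of the peak RMS."""

    grid: ElectrodeGrid
    threshold_fraction: float
    member_channels: tuple[int, ...]
    coverage_fraction: float

    @property
    def n_members(self) -> int:
        return len(self.member_channels)

    @property
    def coverage_percent_rounded(self) -> int:
        """Coverage as an integer percent, rounded half away from zero."""
        return int(math.floor(self.coverage_fraction * 100.0 + 0.5))


def amplitude_map(
    recording: EcogRecording,
    window_s: tuple[float, float],
    filtered: bool = False,
) -> AmplitudeMap:
    """RMS per valid contact over [start, end) seconds on the session clock.

    Computed on the raw signal by default; ``filtered=True`` applies the
    standard high-pass/band-stop chain first.
    """
    if filtered:
        from .ecog import apply_standard_filters

        recording = apply_standard_filters(recording)
    block = recording.slice_window(*window_s)
    rms = np.sqrt(np.mean(block**2, axis=1))
    values = np.full(recording.grid.n_channels, np.nan)
    valid = recording.grid.valid_channels
    values[valid] = rms[valid]
    return AmplitudeMap(grid=recording.grid, window_s=tuple(window_s), values=values)


def threshold_map(amap: AmplitudeMap, fraction: float) -> SpreadMap:
    """Valid contacts with RMS >= fraction * peak (inclusive threshold)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    peak = amap.peak_value
    if not peak > 0:
        raise ValueError("peak value must be positive to threshold")
    valid = amap.grid.valid_channels
    thr = fraction * peak
    members = tuple(int(c) for c in valid if amap.values[c] >= thr - 1e-12 * peak)
    return SpreadMap(
        grid=amap.grid,
        threshold_fraction=fraction,
        member_channels=members,
        coverage_fraction=len(members) / valid.size,
    )


def spread_timecourse(
    recording: EcogRecording,
    windows_s: Sequence[tuple[float, float]],
    fraction: float = 0.5,
    filtered: bool = False,
) -> list[SpreadMap]:
    """One SpreadMap per (ordered) window; thin composition of the two ops."""
    prev_end = -np.inf
    for w in windows_s:
        if w[0] < prev_end:
            raise ValueError("windows must be ordered")
        prev_end = w[0]
    return [
        threshold_map(amplitude_map(recording, w, filtered=filtered), fraction)
        for w in windows_s
    ]


def map_matrix(amap: AmplitudeMap) -> np.ndarray:
    """Amplitude map reshaped to (n_rows, n_cols) for display; NaN at NA."""
    return amap.values.reshape(amap.grid.n_rows, amap.grid.n_cols)
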