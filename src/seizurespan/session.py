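"""Core session data types.

A *session* is one acute seizure-induction experiment: multichannel ECoG from
one or two epidural electrode grids, a timeline of drug administrations
(bicuculline induction, then DCZ or vehicle treatment), and a stream of
manually scored convulsion events.  All times are seconds on the session
clock (recording start = 0); analysis code re-expresses time in minutes
relative to the treatment of record (t = 0 at treatment).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Convulsion categories scored from video.  ``VoluntaryMovement`` is scored
#: but excluded from seizure metrics (it is not a convulsion).
EVENT_CATEGORIES = (
    "Twitch_contra",
    "Twitch_ipsi",
    "Tremor_contra",
    "Tremor_ipsi",
    "Body",
    "Head",
    "VoluntaryMovement",
)

SEIZURE_CATEGORIES = tuple(c for c in EVENT_CATEGORIES if c != "VoluntaryMovement")

#: Tremor is defined as continuous rhythmical shaking lasting longer than 2 s.
TREMOR_MIN_DURATION_S = 2.0


class SessionValidationError(ValueError):
    """Raised when a session object violates a structural invariant."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular epidural electrode array.

    Channel ``k`` sits at ``(row, col) = divmod(k, n_cols)``; physical
    position is ``(row * pitch_mm, col * pitch_mm)``.  ``valid_mask`` flags
    usable contacts; broken / non-available (NA) contacts stay enumerable but
    are excluded from all statistics.
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_mm: float = 2.5
    valid_mask: tuple[bool, ...] | None = None
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise SessionValidationError("grid must have at least one row and column")
        if self.pitch_mm <= 0:
            raise SessionValidationError("pitch_mm must be positive")
        if self.hemisphere not in ("left", "right"):
            raise SessionValidationError(f"unknown hemisphere {self.hemisphere!r}")
        mask = self.valid_mask
        if mask is None:
            mask = (True,) * self.n_channels
        mask = tuple(bool(m) for m in mask)
        if len(mask) != self.n_channels:
            raise SessionValidationError(
                f"valid_mask length {len(mask)} != {self.n_channels} contacts"
            )
        if not any(mask):
            raise SessionValidationError("grid has no valid contact")
        object.__setattr__(self, "valid_mask", mask)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def valid_channels(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.valid_mask))

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))

    def position(self, channel: int) -> tuple[float, float]:
        """Physical (x, y) position of a contact in mm."""
        row, col = divmod(int(channel), self.n_cols)
        return (col * self.pitch_mm, row * self.pitch_mm)

    def rowcol(self, channel: int) -> tuple[int, int]:
        return divmod(int(channel), self.n_cols)

    def channel(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row, col) = ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def distance_pitch(self, ch_a: int, ch_b: int) -> float:
        """Euclidean contact distance in units of the grid pitch."""
        ra, ca = self.rowcol(ch_a)
        rb, cb = self.rowcol(ch_b)
        return math.hypot(ra - rb, ca - cb)


@dataclass
class EcogRecording:
    """Multichannel ECoG voltage time series bound to an electrode grid.

    ``samples`` is (n_channels, n_samples) in microvolts.  Invalid channels
    keep their rows (flagged via the grid mask, never dropped).
    """

    grid: ElectrodeGrid
    sample_rate_hz: float
    samples: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise SessionValidationError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != self.grid.n_channels:
            raise SessionValidationError(
                f"{self.samples.shape[0]} sample rows for "
                f"{self.grid.n_channels}-contact grid"
            )
        if not self.sample_rate_hz > 0:
            raise SessionValidationError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz

    def slice_window(self, start_s: float, end_s: float) -> np.ndarray:
        """Sample block covering [start_s, end_s) on the session clock."""
        if end_s <= start_s:
            raise ValueError("empty window")
        i0 = int(np.ceil((start_s - self.start_time_s) * self.sample_rate_hz - 1e-9))
        i1 = int(np.ceil((end_s - self.start_time_s) * self.sample_rate_hz - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError(
                f"window [{start_s}, {end_s}) s outside recording "
                f"[{self.start_time_s}, {self.end_time_s}) s"
            )
        return self.samples[:, i0:i1]


@dataclass(frozen=True)
class SessionTimeline:
    """Administration times and labels for one session.

    ``reference_time_s`` defines t = 0 of the treatment analysis and must
    equal the first administration time of the treatment of record.
    """

    subject_id: str
    bicuculline_times_s: tuple[float, ...]
    treatment_of_record: str  # "DCZ" | "vehicle"
    vehicle_time_s: float | None = None
    dcz_times_s: tuple[float, ...] = ()
    reference_time_s: float | None = None
    dreadd_hemisphere: str = "left"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bicuculline_times_s", tuple(float(t) for t in self.bicuculline_times_s)
        )
        object.__setattr__(self, "dcz_times_s", tuple(float(t) for t in self.dcz_times_s))
        if self.treatment_of_record not in ("DCZ", "vehicle"):
            raise SessionValidationError(
                f"treatment_of_record must be DCZ or vehicle, got "
                f"{self.treatment_of_record!r}"
            )
        if len(self.bicuculline_times_s) < 1:
            raise SessionValidationError("at least one bicuculline time required")
        if self.reference_time_s is None:
            object.__setattr__(self, "reference_time_s", self._expected_reference())
        object.__setattr__(self, "reference_time_s", float(self.reference_time_s))

    def _expected_reference(self) -> float:
        if self.treatment_of_record == "DCZ":
            if not self.dcz_times_s:
                raise SessionValidationError("DCZ session without dcz_times_s")
            return self.dcz_times_s[0]
        if self.vehicle_time_s is None:
            raise SessionValidationError("vehicle session without vehicle_time_s")
        return float(self.vehicle_time_s)

    @property
    def is_dcz(self) -> bool:
        return self.treatment_of_record == "DCZ"

    def minutes_rel(self, time_s: float | np.ndarray) -> np.ndarray:
        """Session-clock seconds -> minutes relative to t = 0 (treatment)."""
        return (np.asarray(time_s, dtype=float) - self.reference_time_s) / 60.0


@dataclass(frozen=True)
class ConvulsionEvent:
    """One scored convulsive (or voluntary) movement."""

    time_s: float
    category: str
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.category not in EVENT_CATEGORIES:
            raise SessionValidationError(
                f"unknown convulsion category {self.category!r}; "
                f"expected one of {EVENT_CATEGORIES}"
            )

    @property
    def is_seizure(self) -> bool:
        return self.category != "VoluntaryMovement"


@dataclass
class SessionBundle:
    """One session's recordings, timeline and events, plus provenance.

    ``recordings`` holds one entry per implanted hemisphere (one for monkey-
    style unilateral implants, two for bilateral).  ``provenance`` carries the
    config hash and seed for synthetic bundles; it round-trips unchanged.
    """

    session_id: str
    timeline: SessionTimeline
    recordings: list[EcogRecording]
    events: list[ConvulsionEvent] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def recording(self) -> EcogRecording:
        """The recording from the DREADD-expressing hemisphere (analysis default)."""
        for rec in self.recordings:
            if rec.grid.hemisphere == self.timeline.dreadd_hemisphere:
                return rec
        return self.recordings[0]

    def seizure_events(self) -> list[ConvulsionEvent]:
        return [e for e in self.events if e.is_seizure]


def validate_session(bundle: SessionBundle) -> list[str]:
    """Report-only invariant check; empty list iff the bundle is analyzable.

    Checks administration ordering, the tremor >= 2 s scoring rule, the
    reference-time convention, and recording/grid consistency.
    """
    report: list[str] = []
    tl = bundle.timeline
    if not bundle.recordings:
        report.append("bundle has no recording")
    for i, rec in enumerate(bundle.recordings):
        if rec.samples.shape[0] != rec.grid.n_channels:
            report.append(f"recording {i}: channel count mismatch with grid")
        if rec.n_samples == 0:
            report.append(f"recording {i}: empty recording")

    bic0 = tl.bicuculline_times_s[0]
    if any(b2 <= b1 for b1, b2 in zip(tl.bicuculline_times_s, tl.bicuculline_times_s[1:])):
        report.append("bicuculline times not strictly increasing")
    for label, t in (("vehicle", tl.vehicle_time_s), ("DCZ", tl.dcz_times_s[0] if tl.dcz_times_s else None)):
        if t is not None and t <= bic0:
            report.append(
                f"{label} administration at {t} s precedes first bicuculline at {bic0} s"
            )
    if len(tl.dcz_times_s) >= 2 and tl.dcz_times_s[1] <= tl.dcz_times_s[0]:
        report.append("second DCZ dose does not follow the first")
    try:
        expected_ref = tl._expected_reference()
        if not math.isclose(tl.reference_time_s, expected_ref, abs_tol=1e-9):
            report.append(
                f"reference_time_s {tl.reference_time_s} != first "
                f"{tl.treatment_of_record} administration {expected_ref}"
            )
    except SessionValidationError as exc:
        report.append(str(exc))

    for j, ev in enumerate(bundle.events):
        if ev.category.startswith("Tremor"):
            if ev.duration_s is None or ev.duration_s < TREMOR_MIN_DURATION_S:
                report.append(
                    f"event {j}: tremor duration {ev.duration_s} s violates the "
                    f">= {TREMOR_MIN_DURATION_S:g} s scoring rule"
                )
        if bundle.recordings and not any(
            rec.start_time_s - 1e-9 <= ev.time_s <= rec.end_time_s + 1e-9
            for rec in bundle.recordings
        ):
            report.append(f"event {j}: time {ev.time_s} s outside every recording")
    return report


def events_dataframe(events: Iterable[ConvulsionEvent]):
    """Events as a pandas DataFrame (time_s, category, duration_s)."""
    import pandas as pd

    rows = [(e.time_s, e.category, e.duration_s) for e in events]
    return pd.DataFrame(rows, columns=["time_s", "category", "duration_s"])
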