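"""Read/write SessionBundles as a plain-text directory layout.

Layout of a bundle directory::

    timeline.json       session id, administration times, grid descriptors,
                        per-recording file references, provenance
    events.tsv          time_s <TAB> category <TAB> duration_s
    ecog_left.tsv       one row per sample, one column per contact, microvolts
    ecog_right.tsv      (bilateral implants only)

Voltages are written with 17 significant digits, which round-trips IEEE
doubles exactly, so write -> read -> write is byte-identical.  ECoG may also
be supplied as EDF (read-only, via :mod:`mne` when installed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    ConvulsionEvent,
    EcogRecording,
    ElectrodeGrid,
    EVENT_CATEGORIES,
    SessionBundle,
    SessionTimeline,
    SessionValidationError,
)

# 17 digits after the mantissa point always round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17e"

TIMELINE_FILE = "timeline.json"
EVENTS_FILE = "events.tsv"


class BundleReadError(ValueError):
    """Raised when a bundle directory cannot be parsed into a SessionBundle."""


def _grid_to_json(grid: ElectrodeGrid) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "pitch_mm": grid.pitch_mm,
        "valid_mask": [bool(m) for m in grid.valid_mask],
        "hemisphere": grid.hemisphere,
    }


def _grid_from_json(obj: dict) -> ElectrodeGrid:
    return ElectrodeGrid(
        n_rows=int(obj["n_rows"]),
        n_cols=int(obj["n_cols"]),
        pitch_mm=float(obj["pitch_mm"]),
        valid_mask=tuple(bool(m) for m in obj["valid_mask"]),
        hemisphere=obj["hemisphere"],
    )


def write_session_bundle(bundle: SessionBundle, destination: str | Path) -> list[Path]:
    """Write ``bundle`` under ``destination``; returns the files written.

    The layout is deterministic: re-writing a re-read bundle reproduces the
    same bytes.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tl = bundle.timeline
    recordings_meta = []
    for rec in bundle.recordings:
        fname = f"ecog_{rec.grid.hemisphere}.tsv"
        recordings_meta.append(
            {
                "file": fname,
                "sample_rate_hz": rec.sample_rate_hz,
                "start_time_s": rec.start_time_s,
                "grid": _grid_to_json(rec.grid),
            }
        )
        path = dest / fname
        cols = [f"ch{c:03d}" for c in range(rec.grid.n_channels)]
        df = pd.DataFrame(rec.samples.T, columns=cols)
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)

    timeline_obj = {
        "session_id": bundle.session_id,
        "subject_id": tl.subject_id,
        "bicuculline_times_s": list(tl.bicuculline_times_s),
        "vehicle_time_s": tl.vehicle_time_s,
        "dcz_times_s": list(tl.dcz_times_s),
        "treatment_of_record": tl.treatment_of_record,
        "reference_time_s": tl.reference_time_s,
        "dreadd_hemisphere": tl.dreadd_hemisphere,
        "recordings": recordings_meta,
        "provenance": bundle.provenance,
    }
    tl_path = dest / TIMELINE_FILE
    tl_path.write_text(json.dumps(timeline_obj, indent=2, sort_keys=True) + "\n")
    written.append(tl_path)

    ev_path = dest / EVENTS_FILE
    with ev_path.open("w") as fh:
        fh.write("time_s\tcategory\tduration_s\n")
        for ev in bundle.events:
            dur = "" if ev.duration_s is None else _FLOAT_FMT % ev.duration_s
            fh.write(f"{_FLOAT_FMT % ev.time_s}\t{ev.category}\t{dur}\n")
    written.append(ev_path)
    return written


def _read_ecog_tsv(path: Path, meta: dict) -> EcogRecording:
    grid = _grid_from_json(meta["grid"])
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] != grid.n_channels:
        raise BundleReadError(
            f"{path.name}: {df.shape[1]} columns for {grid.n_channels}-contact grid"
        )
    return EcogRecording(
        grid=grid,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        samples=df.to_numpy(dtype=np.float64).T,
        start_time_s=float(meta["start_time_s"]),
    )


def _read_ecog_edf(path: Path, meta: dict) -> EcogRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise BundleReadError(
            f"{path.name}: EDF input requires the 'edf' extra (mne)"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    declared = float(meta["sample_rate_hz"])
    if abs(raw.info["sfreq"] - declared) > 1e-6:
        raise BundleReadError(
            f"{path.name}: declared sample rate {declared} Hz does not match "
            f"EDF header {raw.info['sfreq']} Hz"
        )
    grid = _grid_from_json(meta["grid"])
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EcogRecording(
        grid=grid,
        sample_rate_hz=declared,
        samples=data_uv,
        start_time_s=float(meta["start_time_s"]),
    )


def _read_events(path: Path) -> list[ConvulsionEvent]:
    events: list[ConvulsionEvent] = []
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["time_s", "category"]:
        raise BundleReadError(f"{path.name}: expected header time_s/category/duration_s")
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BundleReadError(f"{path.name} row {row_no}: unparseable line {line!r}")
        time_str, category = parts[0], parts[1]
        dur_str = parts[2] if len(parts) > 2 else ""
        try:
            time_s = float(time_str)
            duration = float(dur_str) if dur_str.strip() else None
        except ValueError as exc:
            raise BundleReadError(
                f"{path.name} row {row_no}: unparseable numeric field in {line!r}"
            ) from exc
        if category not in EVENT_CATEGORIES:
            raise BundleReadError(
                f"{path.name} row {row_no}: unknown category {category!r} "
                f"(expected one of {EVENT_CATEGORIES})"
            )
        events.append(ConvulsionEvent(time_s=time_s, category=category, duration_s=duration))
    return events


def read_session_bundle(source: str | Path) -> SessionBundle:
    """Read a bundle directory written by :func:`write_session_bundle`.

    A missing timeline descriptor, a declared/header sample-rate mismatch, an
    unknown event category or an unparseable event row are hard errors.
    """
    src = Path(source)
    tl_path = src / TIMELINE_FILE
    if not tl_path.exists():
        raise BundleReadError(f"missing timeline descriptor {tl_path}")
    obj = json.loads(tl_path.read_text())

    timeline = SessionTimeline(
        subject_id=obj["subject_id"],
        bicuculline_times_s=tuple(obj["bicuculline_times_s"]),
        vehicle_time_s=obj.get("vehicle_time_s"),
        dcz_times_s=tuple(obj.get("dcz_times_s") or ()),
        treatment_of_record=obj["treatment_of_record"],
        reference_time_s=obj.get("reference_time_s"),
        dreadd_hemisphere=obj.get("dreadd_hemisphere", "left"),
    )

    recordings = []
    for meta in obj["recordings"]:
        path = src / meta["file"]
        if not path.exists():
            raise BundleReadError(f"missing ECoG file {path}")
        if path.suffix.lower() == ".edf":
            recordings.append(_read_ecog_edf(path, meta))
        else:
            recordings.append(_read_ecog_tsv(path, meta))

    ev_path = src / EVENTS_FILE
    events = _read_events(ev_path) if ev_path.exists() else []

    return SessionBundle(
        session_id=obj["session_id"],
        timeline=timeline,
        recordings=recordings,
        events=events,
        provenance=obj.get("provenance", {}),
    )


def bundle_digest(directory: str | Path) -> str:
    """SHA-256 over the bundle files (sorted by name); used in determinism checks."""
    h = hashlib.sha256()
    for path in sorted(Path(directory).glob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
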