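"""Reading, writing and validating walk-test sensor sessions.

A session stores one uniformly sampled tri-axial acceleration series per
body-worn sensor (at minimum both feet), together with the nominal test
duration, an optional spatiotemporal gait summary (cadence, stride length)
and an optional reference distance (e.g. from a calibrated odometer).

Two self-contained on-disk layouts are supported:

* **CSV** (long form, UTF-8, ``.`` decimal separator): a first comment line
  ``# gaitdist-session-v1 <json>`` carrying session metadata, one header row
  ``time_s,location,ax,ay,az`` and one row per sample.  Acceleration is in
  m/s²; the time column is derived from sample index / sampling rate and is
  checked for uniformity on read but never used for integration.
* **HDF5**: one group per sensor location with a dataset ``accel`` of shape
  ``(n, 3)`` and attributes ``sampling_rate_hz`` and (optionally)
  ``start_time``; session-level fields are stored as root attributes.

Units are fixed to m/s².  Files recorded in units of g must be converted
before import: the downstream resting-foot threshold (1 m/s²) is unit-bound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "FOOT_LOCATIONS",
    "ImuRecording",
    "WalkSession",
    "SessionIOError",
    "SessionValidationError",
    "SessionParseError",
    "read_session",
    "write_session",
    "validate_session",
]

#: Recognised body-site labels for sensor placement.
LOCATIONS = (
    "left_foot",
    "right_foot",
    "left_wrist",
    "right_wrist",
    "sternum",
    "lumbar",
)

#: The two locations both distance algorithms actually consume.
FOOT_LOCATIONS = ("left_foot", "right_foot")

_MAGIC = "# gaitdist-session-v1 "


class SessionIOError(IOError):
    """File missing or unwritable."""


class SessionValidationError(ValueError):
    """A session (or file) violates the session invariants."""


class SessionParseError(ValueError):
    """A file row could not be parsed into finite numeric samples."""


@dataclass
class ImuRecording:
    """One sensor's uniformly sampled tri-axial acceleration series.

    Parameters
    ----------
    location
        Body-site label, one of :data:`LOCATIONS`.
    sampling_rate_hz
        Sampling frequency in Hz (strictly positive; 128 for the target
        hardware).
    accel
        Array of shape ``(n, 3)`` holding (ax, ay, az) in m/s².
    start_time
        Optional ISO-8601 timestamp of the first sample.
    """

    location: str
    sampling_rate_hz: float
    accel: np.ndarray
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=np.float64)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise SessionValidationError(
                f"{self.location}: accel must have shape (n, 3), "
                f"got {self.accel.shape}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.accel.shape[0])

    @property
    def times_s(self) -> np.ndarray:
        """Sample times derived from index / sampling rate."""
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class WalkSession:
    """A walk test: sensor recordings plus optional summary and reference.

    ``summary`` holds vendor-style spatiotemporal outputs
    (``cadence_steps_per_min``, ``stride_length_m``); ``reference_distance_m``
    the gold-standard distance; ``metadata`` free-form context such as
    assistive-device use or disability score.
    """

    recordings: dict[str, ImuRecording]
    duration_s: float = 120.0
    summary: dict[str, float] | None = None
    reference_distance_m: float | None = None
    metadata: dict = field(default_factory=dict)

    def foot_recordings(self) -> dict[str, ImuRecording]:
        return {
            loc: rec for loc, rec in self.recordings.items() if loc in FOOT_LOCATIONS
        }


# ---------------------------------------------------------------------------
# validation


def validate_session(
    session: WalkSession, *, foot_length_tol_samples: int = 0
) -> list[str]:
    """Check all session invariants; return a list of issue descriptions.

    Returns an empty list iff the session is valid.  Never raises: each
    problem becomes one human-readable string naming the offending field and
    recording.
    """
    issues: list[str] = []
    for loc, rec in session.recordings.items():
        if loc not in LOCATIONS:
            issues.append(f"{loc}: unknown body-site label")
        if rec.location != loc:
            issues.append(f"{loc}: recording.location mismatch ({rec.location})")
        if not (rec.sampling_rate_hz > 0) or not math.isfinite(rec.sampling_rate_hz):
            issues.append(f"{loc}: sampling_rate_hz must be > 0")
        if rec.n_samples < 1:
            issues.append(f"{loc}: accel has no samples")
        elif not np.isfinite(rec.accel).all():
            bad = int(np.argwhere(~np.isfinite(rec.accel))[0][0])
            issues.append(f"{loc}: non-finite acceleration at sample {bad}")
    feet = session.foot_recordings()
    if len(feet) == 2:
        n_l = feet["left_foot"].n_samples
        n_r = feet["right_foot"].n_samples
        if abs(n_l - n_r) > foot_length_tol_samples:
            issues.append(
                "left_foot/right_foot: lengths differ beyond tolerance "
                f"({n_l} vs {n_r} samples, tol {foot_length_tol_samples})"
            )
    if not (session.duration_s > 0):
        issues.append("duration_s: must be > 0")
    if session.reference_distance_m is not None and session.reference_distance_m < 0:
        issues.append("reference_distance_m: must be >= 0 when present")
    return issues


def _require_feet(recordings: dict[str, ImuRecording]) -> None:
    missing = [loc for loc in FOOT_LOCATIONS if loc not in recordings]
    if len(missing) == len(FOOT_LOCATIONS):
        raise SessionValidationError(
            "no foot recording: missing " + ", ".join(missing)
        )


# ---------------------------------------------------------------------------
# format dispatch


def _sniff_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "hdf5"):
            raise ValueError(f"unknown format {format!r}; expected 'csv' or 'hdf5'")
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_session(path: str | Path, format: str | None = None) -> WalkSession:
    """Read a :class:`WalkSession` from a CSV or HDF5 file.

    ``format`` overrides extension sniffing.  Raises
    :class:`SessionIOError` for a missing file, :class:`SessionParseError`
    for non-numeric/non-finite samples (citing the sample index) and
    :class:`SessionValidationError` when no foot recording is present or an
    invariant fails.
    """
    path = Path(path)
    if not path.exists():
        raise SessionIOError(f"no such file: {path}")
    fmt = _sniff_format(path, format)
    session = _read_csv(path) if fmt == "csv" else _read_hdf5(path)
    _require_feet(session.recordings)
    issues = validate_session(session)
    if issues:
        raise SessionValidationError("; ".join(issues))
    return session


def write_session(
    session: WalkSession, path: str | Path, format: str | None = None
) -> None:
    """Write a session to ``path`` in the documented CSV or HDF5 layout.

    The writer is deterministic: writing the same session twice produces
    byte-identical files, and ``read_session(write_session(s))`` reproduces
    ``s`` exactly (float64 values survive the CSV round trip via shortest
    round-trip repr).
    """
    path = Path(path)
    fmt = _sniff_format(path, format)
    issues = validate_session(session)
    if issues:
        raise SessionValidationError("; ".join(issues))
    try:
        if fmt == "csv":
            _write_csv(session, path)
        else:
            _write_hdf5(session, path)
    except OSError as exc:  # unwritable path, full disk, ...
        raise SessionIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# CSV layout


def _session_meta(session: WalkSession) -> dict:
    meta: dict = {
        "duration_s": session.duration_s,
        "recordings": {
            loc: {
                "sampling_rate_hz": rec.sampling_rate_hz,
                "start_time": rec.start_time,
            }
            for loc, rec in session.recordings.items()
        },
    }
    if session.summary is not None:
        meta["summary"] = session.summary
    if session.reference_distance_m is not None:
        meta["reference_distance_m"] = session.reference_distance_m
    if session.metadata:
        meta["metadata"] = session.metadata
    return meta


def _write_csv(session: WalkSession, path: Path) -> None:
    lines = [_MAGIC + json.dumps(_session_meta(session), sort_keys=True)]
    lines.append("time_s,location,ax,ay,az")
    for loc, rec in session.recordings.items():
        dt = 1.0 / rec.sampling_rate_hz
        for i, (ax, ay, az) in enumerate(rec.accel):
            lines.append(
                f"{repr(i * dt)},{loc},{repr(float(ax))},{repr(float(ay))},{repr(float(az))}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_csv(path: Path) -> WalkSession:
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith(_MAGIC):
        raise SessionParseError(
            f"{path}: missing '{_MAGIC.strip()}' metadata header line"
        )
    meta = json.loads(first[len(_MAGIC):])
    try:
        frame = pd.read_csv(
            path,
            skiprows=1,
            dtype={"time_s": np.float64, "location": str},
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise SessionParseError(f"{path}: malformed CSV body: {exc}") from exc
    expected_cols = ["time_s", "location", "ax", "ay", "az"]
    if list(frame.columns) != expected_cols:
        raise SessionParseError(
            f"{path}: expected columns {expected_cols}, got {list(frame.columns)}"
        )
    for col in ("ax", "ay", "az"):
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame.index[
                pd.to_numeric(frame[col], errors="coerce").isna()
            ][0]
            raise SessionParseError(
                f"{path}: non-numeric value in column {col} at file row {bad}"
            )

    recordings: dict[str, ImuRecording] = {}
    rec_meta = meta.get("recordings", {})
    for loc, group in frame.groupby("location", sort=False):
        if loc not in LOCATIONS:
            raise SessionValidationError(f"{path}: unknown body-site label {loc!r}")
        if loc not in rec_meta:
            raise SessionParseError(
                f"{path}: location {loc!r} present in body but not in metadata"
            )
        accel = group[["ax", "ay", "az"]].to_numpy(dtype=np.float64)
        if not np.isfinite(accel).all():
            bad = int(np.argwhere(~np.isfinite(accel))[0][0])
            raise SessionParseError(
                f"{path}: non-finite value in {loc} at sample {bad}"
            )
        fs = float(rec_meta[loc]["sampling_rate_hz"])
        _check_time_uniformity(group["time_s"].to_numpy(), fs, loc, path)
        recordings[loc] = ImuRecording(
            location=loc,
            sampling_rate_hz=fs,
            accel=accel,
            start_time=rec_meta[loc].get("start_time"),
        )
    return WalkSession(
        recordings=recordings,
        duration_s=float(meta["duration_s"]),
        summary=meta.get("summary"),
        reference_distance_m=meta.get("reference_distance_m"),
        metadata=meta.get("metadata", {}),
    )


def _check_time_uniformity(
    times: np.ndarray, fs: float, loc: str, path: Path
) -> None:
    # The algorithms assume uniform sampling; the explicit time column is
    # advisory only and must not deviate by more than 10% of a sample period.
    if times.size < 2:
        return
    dt = np.diff(times)
    if np.max(np.abs(dt - 1.0 / fs)) > 0.1 / fs:
        raise SessionParseError(
            f"{path}: non-uniform time column for {loc} "
            f"(max deviation exceeds 10% of the sample period)"
        )


# ---------------------------------------------------------------------------
# HDF5 layout


def _write_hdf5(session: WalkSession, path: Path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format"] = "gaitdist-session-v1"
        f.attrs["duration_s"] = float(session.duration_s)
        if session.summary is not None:
            f.attrs["summary_json"] = json.dumps(session.summary, sort_keys=True)
        if session.reference_distance_m is not None:
            f.attrs["reference_distance_m"] = float(session.reference_distance_m)
        if session.metadata:
            f.attrs["metadata_json"] = json.dumps(session.metadata, sort_keys=True)
        for loc, rec in session.recordings.items():
            g = f.create_group(loc)
            # track_times=False keeps files byte-identical across rewrites
            g.create_dataset("accel", data=rec.accel, track_times=False)
            g.attrs["sampling_rate_hz"] = float(rec.sampling_rate_hz)
            if rec.start_time is not None:
                g.attrs["start_time"] = rec.start_time


def _read_hdf5(path: Path) -> WalkSession:
    recordings: dict[str, ImuRecording] = {}
    with h5py.File(path, "r") as f:
        for loc in f.keys():
            if loc not in LOCATIONS:
                raise SessionValidationError(
                    f"{path}: unknown body-site label {loc!r}"
                )
            g = f[loc]
            accel = np.asarray(g["accel"], dtype=np.float64)
            if not np.isfinite(accel).all():
                bad = int(np.argwhere(~np.isfinite(accel))[0][0])
                raise SessionParseError(
                    f"{path}: non-finite value in {loc} at sample {bad}"
                )
            recordings[loc] = ImuRecording(
                location=loc,
                sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                accel=accel,
                start_time=(
                    str(g.attrs["start_time"]) if "start_time" in g.attrs else None
                ),
            )
        summary = (
            json.loads(f.attrs["summary_json"]) if "summary_json" in f.attrs else None
        )
        metadata = (
            json.loads(f.attrs["metadata_json"])
            if "metadata_json" in f.attrs
            else {}
        )
        reference = (
            float(f.attrs["reference_distance_m"])
            if "reference_distance_m" in f.attrs
            else None
        )
        duration = float(f.attrs["duration_s"])
    return WalkSession(
        recordings=recordings,
        duration_s=duration,
        summary=summary,
        reference_distance_m=reference,
        metadata=metadata,
    )
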