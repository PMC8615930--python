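"""Detection of resting feet and whole-patient stops.

After gravity removal a resting foot experiences (ideally) zero
acceleration, so rest is declared wherever the Euclidean magnitude of the
cleaned tri-axial signal stays below a small threshold — 1 m/s² by default,
an allowance for measurement noise.  A whole-patient stop is declared
whenever both feet rest simultaneously for more than one second.

Intervals use 0-based, half-open ``[start_idx, end_idx)`` sample indexing and
are returned disjoint and sorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_io import ImuRecording

__all__ = [
    "DetectionParams",
    "RestInterval",
    "total_acceleration",
    "detect_foot_rests",
    "detect_patient_stops",
    "intervals_to_mask",
]


@dataclass
class DetectionParams:
    """Rest/stop detection settings.

    rest_threshold_ms2 : float
        Magnitude below which a sample counts as resting, in m/s²
        (default 1.0).  Comparison is strict ``<``.
    min_rest_duration_s : float
        Shortest run accepted as a rest, in seconds (default 0.08, about 10
        samples at 128 Hz); suppresses single-sample zero crossings of the
        swing-phase signal.
    min_stop_overlap_s : float
        Both feet must rest simultaneously for strictly longer than this to
        declare a patient stop, in seconds (default 1.0).
    """

    rest_threshold_ms2: float = 1.0
    min_rest_duration_s: float = 0.08
    min_stop_overlap_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rest_threshold_ms2", "min_rest_duration_s", "min_stop_overlap_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RestInterval:
    """Half-open sample interval ``[start_idx, end_idx)`` of detected rest."""

    start_idx: int
    end_idx: int
    subject: str  # left_foot | right_foot | patient

    def __post_init__(self) -> None:
        if not (0 <= self.start_idx < self.end_idx):
            raise ValueError(
                f"invalid interval [{self.start_idx}, {self.end_idx})"
            )

    def duration_s(self, fs: float) -> float:
        return (self.end_idx - self.start_idx) / fs

    def __len__(self) -> int:
        return self.end_idx - self.start_idx


def total_acceleration(rec: ImuRecording) -> np.ndarray:
    """Elementwise Euclidean norm √(ax²+ay²+az²) of the tri-axial signal."""
    return np.linalg.norm(rec.accel, axis=1)


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_foot_rests(
    mag: np.ndarray,
    params: DetectionParams,
    fs: float,
    subject: str = "left_foot",
) -> list[RestInterval]:
    """Find maximal sub-threshold runs of the acceleration magnitude.

    Every returned interval has all samples strictly below
    ``rest_threshold_ms2``, lasts at least ``min_rest_duration_s``, cannot be
    extended in either direction, and the list is disjoint and sorted.
    An empty magnitude series yields an empty list.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    mag = np.asarray(mag, dtype=np.float64)
    mask = mag < params.rest_threshold_ms2
    min_len = params.min_rest_duration_s * fs
    return [
        RestInterval(s, e, subject)
        for s, e in _runs_from_mask(mask)
        if (e - s) >= min_len
    ]


def detect_patient_stops(
    left: list[RestInterval],
    right: list[RestInterval],
    params: DetectionParams,
    fs: float,
) -> list[RestInterval]:
    """Intersect left- and right-foot rests into whole-patient stops.

    A stop is any overlap of a left and a right rest lasting strictly longer
    than ``min_stop_overlap_s``.  Symmetric in its two arguments.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    min_len = params.min_stop_overlap_s * fs
    stops: list[RestInterval] = []
    i = j = 0
    left = sorted(left, key=lambda r: r.start_idx)
    right = sorted(right, key=lambda r: r.start_idx)
    while i < len(left) and j < len(right):
        lo = max(left[i].start_idx, right[j].start_idx)
        hi = min(left[i].end_idx, right[j].end_idx)
        if hi - lo > min_len:
            stops.append(RestInterval(lo, hi, "patient"))
        # advance whichever interval ends first
        if left[i].end_idx <= right[j].end_idx:
            i += 1
        else:
            j += 1
    return stops


def intervals_to_mask(intervals: list[RestInterval], n: int) -> np.ndarray:
    """Boolean mask of length ``n``, True inside any of the intervals."""
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        if iv.end_idx > n:
            raise ValueError(
                f"interval [{iv.start_idx}, {iv.end_idx}) exceeds series length {n}"
            )
        mask[iv.start_idx : iv.end_idx] = True
    return mask
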