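"""Distance from double time-integration with zero-velocity updates.

The foot-mounted dead-reckoning estimator: acceleration is integrated to
velocity and velocity to displacement, s(t) = ∬ a(t) dt².  Raw double
integration accumulates drift quadratically under any residual bias, so the
periodic standstill of each foot is exploited — velocity is clamped to zero
on every detected rest sample and integration restarts from zero after each
rest (zero-velocity updates, ZVU).  Integration is additionally suspended
while the whole patient is stopped, so the cumulative distance freezes
during breaks.

Per stride (the gap between two consecutive rests of one foot), the 3-D
displacement vector is the time-integral of velocity over the gap; its
Euclidean norm is that stride's contribution.  Per-foot distance is the sum
of stride norms and the session distance combines both feet (arithmetic mean
by default — each foot traverses the full path).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .imu_io import FOOT_LOCATIONS, ImuRecording, WalkSession
from .preprocess import FilterParams, preprocess_recording
from .stance import (
    DetectionParams,
    RestInterval,
    detect_foot_rests,
    detect_patient_stops,
    intervals_to_mask,
    total_acceleration,
)

__all__ = [
    "VelocityTrace",
    "DistanceEstimate",
    "integrate_with_zvu",
    "stride_displacements",
    "cumulative_distance",
    "compute_distance_dwa",
]

FootCombine = Literal["mean", "left", "right", "max"]


@dataclass
class VelocityTrace:
    """Per-axis foot velocity (m/s) with zero-velocity updates applied.

    ``velocity`` has shape ``(n, 3)``; ``rest_mask`` is True on every sample
    where velocity was clamped to zero.
    """

    velocity: np.ndarray
    sampling_rate_hz: float
    rest_mask: np.ndarray

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)


@dataclass
class DistanceEstimate:
    """Walked-distance result with per-foot and per-stride breakdown."""

    total_m: float
    per_foot_m: dict[str, float]
    per_stride_m: dict[str, list[float]]
    algorithm: str
    params_used: dict
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def integrate_with_zvu(
    rec: ImuRecording,
    rests: list[RestInterval],
    stops: list[RestInterval] | None = None,
) -> VelocityTrace:
    """Cumulative trapezoidal integration of acceleration with ZVU.

    Velocity is exactly zero on every sample inside a rest or stop interval;
    at the end of each interval integration restarts from an initial value
    of zero.  ``rec`` is expected to be preprocessed (gravity removed,
    filtered).  Passing no intervals gives the naive drift-prone integral.
    """
    n = rec.n_samples
    dt = 1.0 / rec.sampling_rate_hz
    mask = intervals_to_mask(list(rests) + list(stops or []), n)

    # raw cumulative trapezoid, then subtract the running value at the most
    # recent rest sample: equivalent to clamping v=0 there and restarting.
    increments = np.zeros((n, 3))
    increments[1:] = 0.5 * dt * (rec.accel[1:] + rec.accel[:-1])
    v_raw = np.cumsum(increments, axis=0)

    idx = np.arange(n)
    last_rest = np.where(mask, idx, 0)
    np.maximum.accumulate(last_rest, out=last_rest)
    velocity = v_raw - v_raw[last_rest]
    velocity[mask] = 0.0  # exact zeros on rest samples
    return VelocityTrace(velocity, rec.sampling_rate_hz, mask)


def _gaps(rests: list[RestInterval], n: int) -> list[tuple[int, int]]:
    """Non-rest gaps (half-open) between, before and after the rests."""
    gaps: list[tuple[int, int]] = []
    prev_end = 0
    for iv in sorted(rests, key=lambda r: r.start_idx):
        if iv.start_idx > prev_end:
            gaps.append((prev_end, iv.start_idx))
        prev_end = max(prev_end, iv.end_idx)
    if prev_end < n:
        gaps.append((prev_end, n))
    return gaps


def stride_displacements(
    vel: VelocityTrace, rests: list[RestInterval]
) -> list[float]:
    """Euclidean norm of the 3-D displacement over each inter-rest gap.

    Each gap between consecutive rests (a swing) contributes the norm of the
    per-axis time-integral of velocity across it; the bounding rest samples
    (where velocity is zero) anchor the trapezoidal integral.
    """
    n = vel.velocity.shape[0]
    dt = 1.0 / vel.sampling_rate_hz
    out: list[float] = []
    for g0, g1 in _gaps(rests, n):
        lo = max(g0 - 1, 0)
        hi = min(g1 + 1, n)
        disp = np.trapezoid(vel.velocity[lo:hi], dx=dt, axis=0)
        out.append(float(np.linalg.norm(disp)))
    return out


def cumulative_distance(
    vel: VelocityTrace, rests: list[RestInterval]
) -> np.ndarray:
    """Per-sample cumulative distance for one foot.

    Within each gap the partial displacement norm grows; on rest samples the
    curve is flat at the sum of completed strides.  Used for trace output and
    for asserting that distance freezes during patient stops.
    """
    n = vel.velocity.shape[0]
    dt = 1.0 / vel.sampling_rate_hz
    cum = np.zeros(n)
    completed = 0.0
    for g0, g1 in _gaps(rests, n):
        lo = max(g0 - 1, 0)
        seg = vel.velocity[lo:g1]
        inc = np.zeros((g1 - lo, 3))
        inc[1:] = 0.5 * dt * (seg[1:] + seg[:-1])
        partial = np.linalg.norm(np.cumsum(inc, axis=0), axis=1)
        cum[lo:g1] = completed + partial
        stride = partial[-1] if partial.size else 0.0
        if g1 < n:
            cum[g1:] = completed + stride
        completed += stride
    return cum


def compute_distance_dwa(
    session: WalkSession,
    detection: DetectionParams | None = None,
    filt: FilterParams | None = None,
    foot_combine: FootCombine = "mean",
) -> DistanceEstimate:
    """Run the full dead-reckoning pipeline on a walk session.

    Steps: preprocess each foot → acceleration magnitude → per-foot rest
    detection → bilateral patient-stop detection → ZVU integration →
    per-stride displacement norms.  Deterministic for fixed input and
    parameters.

    A foot with no detected rests does not abort the run: ZVU is never
    applied there and the estimate carries a drift-prone warning, mirroring
    the known failure mode on heavily irregular gait.
    """
    detection = detection or DetectionParams()
    filt = filt or FilterParams()
    feet = session.foot_recordings()
    missing = [loc for loc in FOOT_LOCATIONS if loc not in feet]
    if missing:
        raise ValueError(f"missing foot recording(s): {', '.join(missing)}")

    warnings: list[str] = []
    clean = {loc: preprocess_recording(rec, filt) for loc, rec in feet.items()}
    rests = {
        loc: detect_foot_rests(
            total_acceleration(rec), detection, rec.sampling_rate_hz, subject=loc
        )
        for loc, rec in clean.items()
    }
    fs = clean["left_foot"].sampling_rate_hz
    stops = detect_patient_stops(
        rests["left_foot"], rests["right_foot"], detection, fs
    )

    per_foot: dict[str, float] = {}
    per_stride: dict[str, list[float]] = {}
    for loc, rec in clean.items():
        if not rests[loc]:
            warnings.append(
                f"{loc}: no rest intervals detected; ZVU never applied, "
                "estimate is drift-prone"
            )
        vel = integrate_with_zvu(rec, rests[loc], stops)
        strides = stride_displacements(vel, rests[loc] + stops)
        per_stride[loc] = strides
        per_foot[loc] = float(sum(strides))

    if foot_combine == "mean":
        total = float(np.mean(list(per_foot.values())))
    elif foot_combine == "max":
        total = float(max(per_foot.values()))
    elif foot_combine in ("left", "right"):
        total = per_foot[f"{foot_combine}_foot"]
    else:
        raise ValueError(f"unknown foot_combine {foot_combine!r}")

    params_used = {
        "detection": asdict(detection),
        "filter": asdict(filt),
        "foot_combine": foot_combine,
    }
    return DistanceEstimate(
        total_m=total,
        per_foot_m=per_foot,
        per_stride_m=per_stride,
        algorithm="dwa",
        params_used=params_used,
        warnings=warnings,
    )
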