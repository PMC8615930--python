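"""Synthetic walk sessions with known ground-truth distance.

The generator emulates the foot-acceleration signature of a corridor walk
test: per foot, alternating stance segments (gravity plus sensor noise
only) and swing segments carrying a single-period sine pulse on the forward
axis,

    a(t) = A · sin(2π t / T_swing),   A = 2π · stride_length / T_swing²,

which has zero net velocity change — each foot genuinely stops between
strides — and closed-form displacement equal to the stride length.  The two
feet are offset by half a stride period; optional mid-walk pauses replace
walking with bilateral stance; Gaussian noise and constant per-axis bias
are applied last.  Everything is reproducible from the seed.

The pulse shape is chosen for testability (exact analytic ground truth),
not biomechanical realism; see the package methods note for what that does
and does not let the validation claim about real gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .imu_io import ImuRecording, WalkSession

__all__ = ["GaitProfile", "GroundTruth", "simulate_session", "inject_bias"]

GRAVITY_MS2 = 9.81


@dataclass
class GaitProfile:
    """Study conditions for one synthetic walk session.

    Defaults describe a mildly impaired two-minute corridor walk: cadence
    110 steps/min and stride 1.30 m give a nominal (110/2)·2·1.30 ≈ 143 m,
    matching typical clinic distances; stance occupies 35% of the stride
    cycle; sensor noise 0.05 m/s² (1-σ, per axis) stays far below the
    1 m/s² rest threshold.
    """

    cadence_steps_per_min: float = 110.0
    stride_length_m: float = 1.30
    stance_fraction: float = 0.35
    duration_s: float = 120.0
    sampling_rate_hz: float = 128.0
    pauses: tuple[tuple[float, float], ...] = ()
    noise_sd_ms2: float = 0.05
    bias_ms2: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_offset_s: float | None = None  # default: half a stride period
    seed: int = 0
    include_extra_sensors: bool = False

    def __post_init__(self) -> None:
        if self.cadence_steps_per_min < 0 or self.stride_length_m < 0:
            raise ValueError("cadence and stride length must be >= 0")
        if not (0 < self.stance_fraction < 1):
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration_s and sampling_rate_hz must be > 0")
        if self.noise_sd_ms2 < 0:
            raise ValueError("noise_sd_ms2 must be >= 0")
        spans = sorted(self.pauses)
        for (s, d) in spans:
            if d <= 0 or s < 0 or s + d > self.duration_s:
                raise ValueError(f"pause ({s}, {d}) outside [0, {self.duration_s}]")
        for (s1, d1), (s2, _) in zip(spans, spans[1:]):
            if s1 + d1 > s2:
                raise ValueError("pauses must not overlap")

    @property
    def stride_period_s(self) -> float:
        """One stride per foot every 120/cadence seconds (cadence/2 strides/min)."""
        if self.cadence_steps_per_min == 0:
            return float("inf")
        return 120.0 / self.cadence_steps_per_min


@dataclass
class GroundTruth:
    """What the generator actually scheduled, for validation."""

    distance_m: float
    stride_count_per_foot: dict[str, int]
    per_stride_m: dict[str, list[float]]
    stop_intervals: list[tuple[float, float]] = field(default_factory=list)


def _swing_windows(
    profile: GaitProfile, offset_s: float
) -> list[tuple[float, float]]:
    """Start/end times of swings that fully fit the session and avoid pauses."""
    if profile.cadence_steps_per_min == 0:
        return []
    t_stride = profile.stride_period_s
    t_stance = profile.stance_fraction * t_stride
    t_swing = t_stride - t_stance
    windows: list[tuple[float, float]] = []
    k = 0
    while True:
        start = offset_s + k * t_stride + t_stance
        end = start + t_swing
        k += 1
        if end > profile.duration_s + 1e-9:
            break
        if any(start < ps + pd and end > ps for ps, pd in profile.pauses):
            continue  # stride lost to a pause
        windows.append((start, end))
    return windows


def simulate_session(profile: GaitProfile) -> tuple[WalkSession, GroundTruth]:
    """Generate a synthetic session and its ground truth.

    Per-foot stride rate is cadence/2 strides per minute; ground-truth
    distance is the mean over feet of (stride count × stride length), where
    the stride count excludes strides lost to pauses or clipped by the
    session end (the trailing foot fits at most one stride fewer than the
    leading foot).
    """
    fs = profile.sampling_rate_hz
    n = int(round(profile.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(profile.seed)

    t_swing = (1.0 - profile.stance_fraction) * profile.stride_period_s
    amplitude = (
        2.0 * np.pi * profile.stride_length_m / t_swing**2
        if np.isfinite(t_swing)
        else 0.0
    )

    offsets = {
        "left_foot": 0.0,
        "right_foot": (
            profile.phase_offset_s
            if profile.phase_offset_s is not None
            else profile.stride_period_s / 2.0
        ),
    }
    if not np.isfinite(offsets["right_foot"]):
        offsets["right_foot"] = 0.0

    recordings: dict[str, ImuRecording] = {}
    counts: dict[str, int] = {}
    per_stride: dict[str, list[float]] = {}
    for loc, offset in offsets.items():
        accel = np.zeros((n, 3))
        accel[:, 2] = GRAVITY_MS2
        windows = _swing_windows(profile, offset)
        for start, end in windows:
            in_swing = (t >= start) & (t < end)
            accel[in_swing, 0] += amplitude * np.sin(
                2.0 * np.pi * (t[in_swing] - start) / t_swing
            )
        counts[loc] = len(windows)
        per_stride[loc] = [profile.stride_length_m] * len(windows)
        if profile.noise_sd_ms2 > 0:
            accel += rng.normal(0.0, profile.noise_sd_ms2, size=(n, 3))
        accel += np.asarray(profile.bias_ms2, dtype=np.float64)
        recordings[loc] = ImuRecording(loc, fs, accel)

    if profile.include_extra_sensors:
        for loc in ("left_wrist", "right_wrist", "sternum", "lumbar"):
            accel = np.zeros((n, 3))
            accel[:, 2] = GRAVITY_MS2
            if profile.noise_sd_ms2 > 0:
                accel += rng.normal(0.0, profile.noise_sd_ms2, size=(n, 3))
            recordings[loc] = ImuRecording(loc, fs, accel)

    session = WalkSession(
        recordings=recordings,
        duration_s=profile.duration_s,
        metadata={"synthetic": True, "seed": profile.seed},
    )
    truth = GroundTruth(
        distance_m=float(
            np.mean([c * profile.stride_length_m for c in counts.values()])
        ),
        stride_count_per_foot=counts,
        per_stride_m=per_stride,
        stop_intervals=[(s, s + d) for s, d in profile.pauses],
    )
    return session, truth


def inject_bias(
    session: WalkSession, bias_ms2: Sequence[float]
) -> WalkSession:
    """Add a constant per-axis offset to every sample of every recording.

    Emulates accelerometer bias, the drift source that double integration
    amplifies quadratically in time when no zero-velocity updates are
    applied.  The input session is not modified.
    """
    bias = np.asarray(bias_ms2, dtype=np.float64)
    if bias.shape != (3,):
        raise ValueError("bias_ms2 must have exactly three components")
    recordings = {
        loc: replace(rec, accel=rec.accel + bias)
        for loc, rec in session.recordings.items()
    }
    return replace(session, recordings=recordings)
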