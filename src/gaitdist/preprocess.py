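"""Acceleration cleaning: gravity removal and low-pass filtering.

Gravity is removed per axis by subtracting the axis mean over the whole
recording.  This assumes the sensor orientation is roughly constant over the
test, so the gravity projection onto each axis is (close to) a constant that
the mean captures; a convenient side effect is that any constant sensor bias
is removed with it.  Low-pass filtering uses a Butterworth filter applied
forward-backward (zero phase) so that the timing of stance intervals used
downstream is not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .imu_io import ImuRecording

__all__ = ["FilterParams", "remove_gravity", "lowpass", "preprocess_recording"]


@dataclass
class FilterParams:
    """Low-pass filter settings.

    cutoff_hz : float
        Cut-off frequency in Hz (default 60, i.e. nearly pass-through at a
        128 Hz sampling rate; kept configurable for lower rates or more
        aggressive smoothing).  Must be strictly below the Nyquist frequency.
    order : int
        Butterworth order (default 4).
    zero_phase : bool
        Apply the filter forward and backward (default), doubling the
        effective attenuation but eliminating phase lag.
    """

    cutoff_hz: float = 60.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        nyquist = sampling_rate_hz / 2.0
        if not (0 < self.cutoff_hz < nyquist):
            raise ValueError(
                f"cutoff_hz must lie in (0, {nyquist}) for fs="
                f"{sampling_rate_hz} Hz; got {self.cutoff_hz}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def remove_gravity(rec: ImuRecording) -> ImuRecording:
    """Subtract each axis's arithmetic mean (gravity + constant bias).

    Idempotent: a zero-mean recording is returned unchanged up to rounding.
    """
    if rec.n_samples < 1:
        raise ValueError("cannot remove gravity from an empty recording")
    accel = rec.accel - rec.accel.mean(axis=0, keepdims=True)
    return replace(rec, accel=accel)


def lowpass(rec: ImuRecording, params: FilterParams | None = None) -> ImuRecording:
    """Low-pass filter each axis with a Butterworth filter (DC gain 1).

    With ``zero_phase`` the filter runs forward and backward
    (``scipy.signal.filtfilt``), which squares the magnitude response; the
    single-pass variant uses ``lfilter``.
    """
    params = params or FilterParams()
    params.validate(rec.sampling_rate_hz)
    sos = signal.butter(
        params.order, params.cutoff_hz, btype="low", fs=rec.sampling_rate_hz,
        output="sos",
    )
    if params.zero_phase:
        accel = signal.sosfiltfilt(sos, rec.accel, axis=0)
    else:
        accel = signal.sosfilt(sos, rec.accel, axis=0)
    return replace(rec, accel=np.ascontiguousarray(accel))


def preprocess_recording(
    rec: ImuRecording, params: FilterParams | None = None
) -> ImuRecording:
    """Full cleaning step: gravity removal first, then low-pass filtering."""
    return lowpass(remove_gravity(rec), params)
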