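"""Distance from summary gait parameters: cadence × stride length.

The simple estimator: walked distance over a timed test equals stride
length times the number of strides taken.  Cadence is conventionally a step
rate (steps/min) and one stride spans two steps, so under the default
``stride_per_two_steps`` convention

    distance = (cadence / 2) · stride_length · duration_min.

The alternative ``stride_per_step`` convention multiplies the full step
count by the stride length (exactly twice the default); it exists because
vendor outputs do not always document whether their "cadence" counts steps
or strides.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

from .dwa import DistanceEstimate

__all__ = [
    "GaitSummary",
    "StepConvention",
    "compute_distance_mla",
    "summary_from_strides",
]

StepConvention = Literal["stride_per_two_steps", "stride_per_step"]


@dataclass
class GaitSummary:
    """Per-session spatiotemporal summary.

    cadence_steps_per_min : float
        Step rate in steps/min (one stride = two steps).
    stride_length_m : float
        Average stride length in metres.
    duration_min : float
        Test duration in minutes (default 2.0, the two-minute walk test).
    """

    cadence_steps_per_min: float
    stride_length_m: float
    duration_min: float = 2.0

    def __post_init__(self) -> None:
        if self.cadence_steps_per_min < 0:
            raise ValueError("cadence_steps_per_min must be >= 0")
        if self.stride_length_m < 0:
            raise ValueError("stride_length_m must be >= 0")
        if not self.duration_min > 0:
            raise ValueError("duration_min must be > 0")


def compute_distance_mla(
    summary: GaitSummary,
    step_convention: StepConvention = "stride_per_two_steps",
) -> DistanceEstimate:
    """Distance = stride rate × stride length × duration.

    ``stride_per_two_steps`` halves the cadence to obtain strides/min;
    ``stride_per_step`` treats every step as a full stride (always exactly
    twice the former).
    """
    if step_convention == "stride_per_two_steps":
        strides_per_min = summary.cadence_steps_per_min / 2.0
    elif step_convention == "stride_per_step":
        strides_per_min = summary.cadence_steps_per_min
    else:
        raise ValueError(f"unknown step_convention {step_convention!r}")
    total = strides_per_min * summary.stride_length_m * summary.duration_min
    return DistanceEstimate(
        total_m=float(total),
        per_foot_m={},
        per_stride_m={},
        algorithm="mla",
        params_used={"summary": asdict(summary), "step_convention": step_convention},
    )


def summary_from_strides(
    per_stride_m: Sequence[float],
    duration_min: float,
    foot_count: int = 1,
) -> GaitSummary:
    """Build a gait summary from detected per-stride displacements.

    ``per_stride_m`` pools stride displacements across ``foot_count`` feet;
    stride length is their arithmetic mean and cadence is
    ``2 × (strides per foot) / duration`` under the one-stride-per-two-steps
    convention.  Lets the summary-based estimator run on sessions without a
    vendor summary.  Raises on zero strides.
    """
    if len(per_stride_m) == 0:
        raise ValueError("need at least one stride to build a summary")
    if foot_count < 1:
        raise ValueError("foot_count must be >= 1")
    stride_length = float(sum(per_stride_m)) / len(per_stride_m)
    strides_per_foot = len(per_stride_m) / foot_count
    cadence = 2.0 * strides_per_foot / duration_min
    return GaitSummary(
        cadence_steps_per_min=cadence,
        stride_length_m=stride_length,
        duration_min=duration_min,
    )
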