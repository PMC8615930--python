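import numpy as np
import pytest

from gaitdist.simulate import GaitProfile, simulate_session


@pytest.fixture
def clean_profile():
    """Noiseless 120 s walk: cadence 120 steps/min, stride 1.25 m."""
    return GaitProfile(
        cadence_steps_per_min=120.0,
        stride_length_m=1.25,
        noise_sd_ms2=0.0,
        seed=11,
    )


@pytest.fixture
def clean_session(clean_profile):
    return simulate_session(clean_profile)


@pytest.fixture
def noisy_session():
    """Default study conditions: noise 0.05 m/s^2, cadence 110, stride 1.30."""
    return simulate_session(GaitProfile(seed=42))


@pytest.fixture
def tiny_session():
    """Short (4 s) noisy session for fast I/O tests."""
    return simulate_session(GaitProfile(duration_s=4.0, seed=3))[0]


def brute_force_rests(mag, threshold, min_samples):
    """Naive sample-by-sample threshold scan + run grouping (test oracle)."""
    runs = []
    start = None
    for i, v in enumerate(mag):
        if v < threshold:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i))
                start = None
    if start is not None:
        runs.append((start, len(mag)))
    return [(s, e) for s, e in runs if e - s >= min_samples]
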