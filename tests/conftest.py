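"""Shared fixtures: synthetic epochs with ground truth and hand-built bouts."""

from __future__ import annotations

import numpy as np
import pytest

from pitchkit.segmentation import BoutWindow, compute_speed, segment_epoch
from pitchkit.simulate import SwimSimParams, generate_epoch


def make_bout(pitch=None, x=None, z=None, fs=40.0, peak_speed=10.0) -> BoutWindow:
    """Build a BoutWindow directly from (partial) window arrays.

    Arrays default to zeros over the 2*(fs/4)+1 window; handy for unit tests
    of single kinematic formulas.
    """
    width = 2 * (int(fs) // 4) + 1

    def _arr(a):
        if a is None:
            return np.zeros(width)
        a = np.asarray(a, dtype=float)
        assert a.size == width, f"window must have {width} samples, got {a.size}"
        return a

    return BoutWindow(
        epoch_id="test",
        t_peak=0.0,
        peak_index=width // 2,
        fs=fs,
        speed=np.full(width, peak_speed),
        pitch=_arr(pitch),
        x=_arr(x),
        z=_arr(z),
        peak_speed=peak_speed,
    )


@pytest.fixture(scope="session")
def clean_epoch():
    """Noise-free 160 Hz epoch with its ground-truth table."""
    params = SwimSimParams(
        fs=160.0, duration=300.0, bout_rate=0.5, lift_noise_sd=0.0,
        pitch_noise_sd=0.0, seed=1,
    )
    return generate_epoch(params)


@pytest.fixture(scope="session")
def clean_epoch_40hz():
    params = SwimSimParams(
        fs=40.0, duration=300.0, bout_rate=0.5, lift_noise_sd=0.0,
        pitch_noise_sd=0.0, seed=2,
    )
    return generate_epoch(params)


@pytest.fixture(scope="session")
def noisy_epoch():
    """Epoch with the default noise levels, long enough to fill all bins."""
    params = SwimSimParams(fs=160.0, duration=480.0, bout_rate=0.5, seed=3)
    return generate_epoch(params)


@pytest.fixture(scope="session")
def clean_bouts(clean_epoch):
    epoch, _ = clean_epoch
    return segment_epoch(epoch)


@pytest.fixture(scope="session")
def clean_speed(clean_epoch):
    epoch, _ = clean_epoch
    return compute_speed(epoch)
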