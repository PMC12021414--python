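"""Synthetic swim epochs and tilt-trial responses with known ground truth.

The swim generator emulates the statistical structure the downstream
analysis assumes: discrete bouts of rapid translation (raised-cosine speed
pulses, half-width 150 ms, so a 5 mm/s threshold crossing yields exactly one
contiguous interval per bout), pre-bout posture distributions for climbs and
dives, an upward pitch rotation during the acceleration phase, and a depth
trace that follows the launch posture plus a speed-bin-dependent fin lift.

The construction is deliberately exact under the downstream estimators: the
pitch ramp is the integral of a raised-cosine angular-velocity bump whose
peak falls on the peak-speed sample, so the measured upward rotation equals
the drawn value; depth is built from the -100 ms reference pitch, so the
lift formula recovers the drawn lift; and the -250/-100/0/+100 ms marks all
land on exact grid points at both 40 and 160 Hz.  With all noise terms at
zero, every drawn parameter is recovered to numerical precision.

The tilt-trial generator emulates tuned and untuned cells: per-trial
integrated responses are a per-direction cell mean plus a *shared latent
direction signal* with zero-mean Gaussian cell loadings plus independent
noise.  Zero-mean loadings keep the expected directionality index of every
cell at 0 while the population remains linearly decodable — the
untuned-but-collectively-informative regime.

Randomness: a single seeded numpy PCG64 stream per call; with a fixed seed
output is bit-identical across runs.  The generator name is recorded in the
ground-truth table's ``attrs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochRecording, VALID_SAMPLING_RATES
from .kinematics import SPEED_BIN_NAMES, assign_speed_bin

logger = logging.getLogger(__name__)

#: half-widths of the three per-bout primitives, seconds
PITCH_RAMP_HALF = 0.25  # angular-velocity bump support
SPEED_PULSE_HALF = 0.15  # raised-cosine speed pulse
LIFT_BUMP_HALF = 0.10  # lift deposition, inside the -100...+100 ms window

#: minimum separation between bout peaks; closer candidate bouts are dropped
MIN_PEAK_SEPARATION = 0.6

#: peak-speed draws are truncated from below at this value [mm/s]
PEAK_SPEED_FLOOR = 5.5

#: upward-rotation draws are truncated from below at this value [deg]; the
#: peak-angular-velocity estimator cannot recover a downward ramp, and
#: near-zero rotations make lift/rotation ratios unstable
MIN_UPWARD_ROTATION = 0.5


@dataclass
class SwimSimParams:
    """Parameters of the swim-epoch generator.

    Distributions are (mean, sd) pairs.  ``lift_gain_per_bin`` maps the
    slow/medium/fast speed bins to fin-lift gains in mm per degree of upward
    rotation; the defaults sit near empirically reported control values.
    Bout rate is a convenience value, not a claim about real fish.  Upward
    rotations are truncated below at 0.5 deg (see MIN_UPWARD_ROTATION).

    The noise defaults emulate *tracking precision* (sub-pixel position,
    ~0.1 deg pitch), not biological trial-to-trial scatter: pitch noise
    perturbs the regressor of the coordination fit and lift noise is
    truncated by the positive-lift qualifying rule, so either one, made
    large, shifts the fitted slope away from the generative gain for any
    estimator.  Keeping them at measurement scale keeps gain recovery a
    well-posed claim; the cost is that synthetic fits are far cleaner than
    real ones (see the methods note).
    """

    fs: float = 160.0
    duration: float = 300.0
    bout_rate: float = 0.5
    peak_speed_dist: tuple[float, float] = (11.0, 4.0)
    climb_fraction: float = 0.6
    posture_climb: tuple[float, float] = (15.0, 8.0)
    posture_dive: tuple[float, float] = (-12.0, 8.0)
    upward_rotation_dist: tuple[float, float] = (6.0, 3.0)
    lift_gain_per_bin: tuple[float, float, float] = (0.03, 0.04, 0.07)
    lift_noise_sd: float = 0.04
    pitch_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs not in VALID_SAMPLING_RATES:
            raise ValueError(f"fs must be one of {VALID_SAMPLING_RATES}")
        if self.duration <= 1.0:
            raise ValueError("duration must exceed 1 s")
        if self.bout_rate < 0:
            raise ValueError("bout_rate must be non-negative")
        for name in ("peak_speed_dist", "posture_climb", "posture_dive",
                     "upward_rotation_dist"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be non-negative")
        if self.lift_noise_sd < 0 or self.pitch_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if not (0.0 <= self.climb_fraction <= 1.0):
            raise ValueError("climb_fraction must be a probability")
        if not np.all(np.isfinite(self.lift_gain_per_bin)):
            raise ValueError("lift gains must be finite")


def _cum_raised_cosine(tau: np.ndarray, half: float) -> np.ndarray:
    """Integral of the unit-peak raised cosine 0.5*(1+cos(pi t/half)).

    Zero at -half; equals ``half`` at +half.  Vectorized and clamped outside
    the support.
    """
    tau = np.asarray(tau, dtype=float)
    out = 0.5 * ((tau + half) + (half / np.pi) * np.sin(np.pi * tau / half))
    return np.where(tau <= -half, 0.0, np.where(tau >= half, half, out))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, max_tries: int = 10000) -> float:
    if sd == 0:
        if mean < floor:
            raise ValueError(f"degenerate draw below floor: {mean} < {floor}")
        return mean
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if v >= floor:
            return float(v)
    raise RuntimeError("truncated-normal rejection sampling failed")


def _peak_speed(amp: float, tan_ref: float, lift_total: float, fs: float) -> float:
    """Centered-difference speed at the peak sample for one bout."""
    dt = 1.0 / fs
    du = amp * (_cum_raised_cosine(dt, SPEED_PULSE_HALF)
                - _cum_raised_cosine(-dt, SPEED_PULSE_HALF))
    dphi = (_cum_raised_cosine(dt, LIFT_BUMP_HALF)
            - _cum_raised_cosine(-dt, LIFT_BUMP_HALF)) / LIFT_BUMP_HALF
    dz = tan_ref * du + lift_total * dphi
    return float(np.hypot(du, dz) / (2.0 * dt))


TRUTH_COLUMNS = [
    "peak_index", "t_peak", "posture", "upward_rotation", "lift",
    "lift_expected", "gain", "speed_bin", "peak_speed", "climb",
    "direction_sign",
]


def generate_epoch(
    params: SwimSimParams, epoch_id: str = "sim", **epoch_meta
) -> tuple[EpochRecording, pd.DataFrame]:
    """Generate one swim epoch plus its per-bout ground-truth table.

    Candidate bout times are Poisson in number and uniform in time; bouts
    closer than 0.6 s to an already-placed bout are dropped (logged), never
    merged.  Each bout draws a climb/dive posture, an upward rotation, a
    peak-speed amplitude (truncated at 5.5 mm/s) and a travel direction
    (+/-x at random); its lift is gain(speed bin) x rotation + noise.  The
    speed-bin assignment is iterated a few rounds because the lift bump
    itself feeds back on peak speed; the rare bout that oscillates between
    bins is dropped.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    z = np.zeros(n)
    pitch = np.zeros(n)

    margin = PITCH_RAMP_HALF + 0.1
    n_candidates = rng.poisson(params.duration * params.bout_rate)
    lo, hi = margin, params.duration - margin
    candidates = np.sort(rng.uniform(lo, hi, size=n_candidates)) if hi > lo else np.empty(0)
    peak_times: list[float] = []
    n_dropped_overlap = 0
    for c in candidates:
        if peak_times and c - peak_times[-1] < MIN_PEAK_SEPARATION:
            n_dropped_overlap += 1
            continue
        peak_times.append(float(c))
    if n_dropped_overlap:
        logger.info("dropped %d overlapping bout pulses", n_dropped_overlap)

    half_n = int(fs) // 4  # samples per side of the bout footprint
    gains = dict(zip(SPEED_BIN_NAMES, params.lift_gain_per_bin))
    rows = []
    x_cur = z_cur = 0.0
    prev_end = -1
    prev_pitch_end = None
    n_dropped_unstable = 0

    for pt in peak_times:
        kp = int(round(pt * fs))
        climb = bool(rng.random() < params.climb_fraction)
        mu, sd = params.posture_climb if climb else params.posture_dive
        p0 = float(np.clip(rng.normal(mu, sd), -45.0, 45.0))
        rot = _truncated_normal(rng, *params.upward_rotation_dist,
                                MIN_UPWARD_ROTATION)
        amp = _truncated_normal(rng, *params.peak_speed_dist, PEAK_SPEED_FLOOR)
        sx = 1.0 if rng.random() < 0.5 else -1.0
        lift_noise = float(rng.normal(0.0, params.lift_noise_sd)) if params.lift_noise_sd else 0.0

        # the lift formula reads pitch at -100 ms; build depth from that angle
        pitch_ref = p0 + rot * _pitch_ramp(-LIFT_BUMP_HALF)
        tan_ref = float(np.tan(np.radians(pitch_ref)))

        # iterate the speed-bin assignment: the lift bump feeds back on speed
        lift_total = 0.0
        speed_bin = None
        converged = False
        for _ in range(6):
            ps = _peak_speed(amp, tan_ref, lift_total, fs)
            new_bin = assign_speed_bin(ps)
            new_lift = gains[new_bin] * rot + lift_noise
            if new_bin == speed_bin and abs(new_lift - lift_total) < 1e-12:
                converged = True
                break
            speed_bin = new_bin
            lift_total = new_lift
        if not converged:
            ps = _peak_speed(amp, tan_ref, lift_total, fs)
            if assign_speed_bin(ps) != speed_bin:
                n_dropped_unstable += 1
                continue

        j0, j1 = kp - half_n, kp + half_n
        tau = (np.arange(j0, j1 + 1) - kp) / fs
        u = amp * _cum_raised_cosine(tau, SPEED_PULSE_HALF)
        phi = _cum_raised_cosine(tau, LIFT_BUMP_HALF) / LIFT_BUMP_HALF
        ramp = _pitch_ramp(tau)

        # settle the inter-bout gap: positions hold, pitch relaxes linearly
        gap = np.arange(prev_end + 1, j0)
        x[gap] = x_cur
        z[gap] = z_cur
        if gap.size:
            if prev_pitch_end is None:
                pitch[gap] = p0
            else:
                frac = (gap - prev_end) / (j0 - prev_end)
                pitch[gap] = prev_pitch_end + frac * (p0 - prev_pitch_end)

        x[j0 : j1 + 1] = x_cur + sx * u
        z[j0 : j1 + 1] = z_cur + tan_ref * u + lift_total * phi
        pitch[j0 : j1 + 1] = p0 + rot * ramp

        ps_final = _peak_speed(amp, tan_ref, lift_total, fs)
        rows.append(
            dict(
                peak_index=kp,
                t_peak=t[kp],
                posture=p0,
                upward_rotation=rot,
                lift=lift_total,
                lift_expected=gains[speed_bin] * rot,
                gain=gains[speed_bin],
                speed_bin=speed_bin,
                peak_speed=ps_final,
                climb=climb,
                direction_sign=sx,
            )
        )
        x_cur = x[j1]
        z_cur = z[j1]
        prev_pitch_end = p0 + 2.0 * rot
        prev_end = j1

    tail = np.arange(prev_end + 1, n)
    x[tail] = x_cur
    z[tail] = z_cur
    pitch[tail] = 0.0 if prev_pitch_end is None else prev_pitch_end

    if n_dropped_unstable:
        logger.info("dropped %d bin-unstable bouts", n_dropped_unstable)

    if params.pitch_noise_sd > 0:
        pitch = pitch + _band_limited_noise(rng, n, fs, params.pitch_noise_sd)

    epoch = EpochRecording(
        t=t, x=x, z=z, pitch=pitch, fs=fs, epoch_id=epoch_id, **epoch_meta
    )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth.attrs["generator"] = "numpy PCG64 (np.random.default_rng)"
    truth.attrs["n_dropped_overlap"] = n_dropped_overlap
    truth.attrs["n_dropped_unstable"] = n_dropped_unstable
    return epoch, truth


#: correlation scale of the pitch jitter process, seconds
PITCH_NOISE_TAU = 0.05


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float
) -> np.ndarray:
    """Smooth pitch jitter: white noise convolved with a 50 ms Gaussian
    kernel, rescaled to marginal sd ``sd``.

    A body has rotational inertia, so its pitch cannot jump degree-scale
    between adjacent frames; white per-sample noise would also make any
    derivative-based angular-velocity estimate meaningless at 160 Hz.
    """
    sigma = PITCH_NOISE_TAU * fs
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= np.sqrt(np.sum(k**2))  # unit output variance for unit input
    white = rng.normal(0.0, 1.0, size=n + 2 * half)
    return sd * np.convolve(white, k, mode="valid")


def _pitch_ramp(tau) -> np.ndarray | float:
    """Normalized pitch ramp G(tau): integral of a raised-cosine angular
    velocity bump of half-width 250 ms, scaled so G(-250 ms)=0 and G(0)=1.

    The angular velocity peaks exactly at tau=0 (the peak-speed sample), so
    the downstream centered-difference argmax lands on the peak sample and
    the measured rotation G(0)-G(-250 ms) equals the drawn value.  G
    continues to 2 at +250 ms — the trunk keeps rotating while decelerating.
    """
    scalar = np.isscalar(tau)
    out = _cum_raised_cosine(np.asarray(tau, dtype=float), PITCH_RAMP_HALF) / (
        PITCH_RAMP_HALF / 2.0
    )
    return float(out) if scalar else out


@dataclass
class CellSimParams:
    """Parameters of the tilt-trial response generator.

    ``shared_direction_signal_sd`` is the across-cells standard deviation of
    the latent per-direction offset (signal amplitude times a zero-mean unit
    Gaussian loading per cell).  With equal up/down means and this latent
    present, single cells stay untuned in expectation while the population
    carries linearly decodable direction information.
    """

    n_trials_per_direction: int = 21
    response_up: float = 10.0
    response_down: float = 10.0
    trial_noise_sd: float = 1.0
    shared_direction_signal_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_direction < 2:
            raise ValueError("need at least 2 trials per direction")
        if self.trial_noise_sd < 0 or self.shared_direction_signal_sd < 0:
            raise ValueError("sds must be non-negative")


def generate_cell_trials(
    params: CellSimParams, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trials x cells integrated responses plus per-trial direction labels.

    ``response[t, i] = mean_i(direction_t) + dir_t * s * w_i + noise`` with
    ``dir_t`` +1 for nose-up and -1 for nose-down trials, loadings
    ``w_i ~ N(0, 1)`` and ``s = shared_direction_signal_sd``.  Trials are
    ordered all-up then all-down.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(params.seed)
    n = params.n_trials_per_direction
    labels = np.array(["up"] * n + ["down"] * n, dtype=object)
    dir_sign = np.where(labels == "up", 1.0, -1.0)
    means = np.where(labels == "up", params.response_up, params.response_down)
    loadings = rng.normal(0.0, 1.0, size=n_cells)
    M = (
        means[:, None]
        + dir_sign[:, None] * params.shared_direction_signal_sd * loadings[None, :]
        + rng.normal(0.0, params.trial_noise_sd, size=(2 * n, n_cells))
    )
    return M, labels
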