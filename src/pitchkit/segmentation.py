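"""Swim-bout detection, peak-speed alignment, exclusion rules and bout matching.

Larval zebrafish locomote in discrete bouts of rapid translation.  A bout is
operationally a maximal contiguous interval where swim speed exceeds 5 mm/s
(strictly), indexed by the time of peak speed.  Each detected bout is cut into
a window spanning -250...+250 ms around its peak and screened by the standard
exclusion rules: peak speed below threshold, or more than 30 deg of pitch
rotation during the acceleration phase (-250...0 ms).  Experimental repeats
with fewer than 650 accepted bouts are dropped, and control/condition repeats
are subsampled to matched bout counts before any group comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EpochRecording

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = (
    "none",
    "low_peak_speed",
    "excess_rotation",
    "window_out_of_bounds",
)

SPEED_THRESHOLD = 5.0  # mm/s, strict
MAX_ROTATION = 30.0  # deg over -250...0 ms, strict
MIN_BOUTS_PER_REPEAT = 650


@dataclass
class BoutWindow:
    """A peak-speed-aligned slice of an epoch covering -250...+250 ms.

    The grid is centered on the peak-speed sample with exactly fs/4 samples on
    each side (10 at 40 Hz, 40 at 160 Hz), so the window has 2*(fs/4)+1
    samples and the -250 ms, -100 ms, 0 ms and +100 ms marks all fall on
    exact grid points.
    """

    epoch_id: str
    t_peak: float
    peak_index: int
    fs: float
    speed: np.ndarray
    pitch: np.ndarray
    x: np.ndarray
    z: np.ndarray
    peak_speed: float
    excluded: bool = False
    exclusion_reason: str = "none"

    @property
    def center(self) -> int:
        return self.speed.size // 2

    @property
    def half_width(self) -> int:
        return int(self.fs) // 4


def compute_speed(epoch: EpochRecording) -> np.ndarray:
    """Swim speed [mm/s] from centered differences of x and z.

    ``speed[i] = sqrt(dx^2 + dz^2) * fs`` with centered differences in the
    interior and one-sided differences at the ends.  No smoothing is applied
    by default; the most literal reading of a bare threshold crossing.
    """
    if epoch.n_samples < 3:
        raise ValueError("epoch must contain at least 3 samples")
    dt = 1.0 / epoch.fs
    vx = np.gradient(epoch.x, dt)
    vz = np.gradient(epoch.z, dt)
    return np.hypot(vx, vz)


def detect_bouts(speed: np.ndarray, threshold: float = SPEED_THRESHOLD) -> np.ndarray:
    """Peak-speed sample indices, one per maximal supra-threshold interval.

    The comparison is strict (``speed > threshold``): a pulse peaking exactly
    at the threshold yields no bout.  Within each contiguous interval the
    peak is the argmax of speed, ties broken toward the earlier sample.
    """
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold
    if not above.any():
        return np.empty(0, dtype=int)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    peaks = [int(s + np.argmax(speed[s:e])) for s, e in zip(starts, ends)]
    return np.asarray(peaks, dtype=int)


def extract_bout_windows(
    epoch: EpochRecording, peaks: np.ndarray, speed: np.ndarray | None = None
) -> list[BoutWindow]:
    """Cut +/-250 ms windows around each peak.

    Peaks whose window would run past either end of the epoch are kept but
    flagged ``window_out_of_bounds`` and excluded (the slice is padded with
    NaN so the window shape is invariant).
    """
    if speed is None:
        speed = compute_speed(epoch)
    half = int(epoch.fs) // 4
    windows: list[BoutWindow] = []
    n = epoch.n_samples
    for peak in np.asarray(peaks, dtype=int):
        lo, hi = peak - half, peak + half + 1
        out_of_bounds = lo < 0 or hi > n
        if out_of_bounds:
            width = 2 * half + 1
            sl_lo, sl_hi = max(lo, 0), min(hi, n)
            pad_lo = sl_lo - lo

            def _pad(arr: np.ndarray) -> np.ndarray:
                out = np.full(width, np.nan)
                out[pad_lo : pad_lo + (sl_hi - sl_lo)] = arr[sl_lo:sl_hi]
                return out

            windows.append(
                BoutWindow(
                    epoch_id=epoch.epoch_id,
                    t_peak=float(epoch.t[peak]),
                    peak_index=int(peak),
                    fs=epoch.fs,
                    speed=_pad(speed),
                    pitch=_pad(epoch.pitch),
                    x=_pad(epoch.x),
                    z=_pad(epoch.z),
                    peak_speed=float(speed[peak]),
                    excluded=True,
                    exclusion_reason="window_out_of_bounds",
                )
            )
            continue
        windows.append(
            BoutWindow(
                epoch_id=epoch.epoch_id,
                t_peak=float(epoch.t[peak]),
                peak_index=int(peak),
                fs=epoch.fs,
                speed=speed[lo:hi].copy(),
                pitch=epoch.pitch[lo:hi].copy(),
                x=epoch.x[lo:hi].copy(),
                z=epoch.z[lo:hi].copy(),
                peak_speed=float(speed[peak]),
            )
        )
    return windows


def apply_exclusions(
    bout: BoutWindow,
    min_peak_speed: float = SPEED_THRESHOLD,
    max_rotation: float = MAX_ROTATION,
) -> BoutWindow:
    """Flag a bout per the exclusion rules; returns the same object.

    ``low_peak_speed`` iff peak speed < 5 mm/s; ``excess_rotation`` iff
    |pitch(0) - pitch(-250 ms)| > 30 deg (both boundaries strict; a bout
    rotating exactly 30 deg is accepted).  Out-of-bounds windows keep their
    existing flag.
    """
    if bout.exclusion_reason == "window_out_of_bounds":
        return bout
    if bout.peak_speed < min_peak_speed:
        bout.excluded = True
        bout.exclusion_reason = "low_peak_speed"
        return bout
    rotation = abs(bout.pitch[bout.center] - bout.pitch[0])
    if rotation > max_rotation:
        bout.excluded = True
        bout.exclusion_reason = "excess_rotation"
        return bout
    bout.excluded = False
    bout.exclusion_reason = "none"
    return bout


def segment_epoch(
    epoch: EpochRecording,
    threshold: float = SPEED_THRESHOLD,
    max_rotation: float = MAX_ROTATION,
) -> list[BoutWindow]:
    """Detect, window and screen all bouts of one epoch."""
    speed = compute_speed(epoch)
    peaks = detect_bouts(speed, threshold=threshold)
    windows = extract_bout_windows(epoch, peaks, speed)
    for w in windows:
        apply_exclusions(w, min_peak_speed=threshold, max_rotation=max_rotation)
    return windows


@dataclass
class RepeatBoutSet:
    """Accepted bouts of one experimental repeat plus exclusion bookkeeping."""

    repeat_id: str
    group: str
    bouts: list[BoutWindow] = field(default_factory=list)
    n_raw: int = 0
    n_excluded_by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return len(self.bouts)


def build_repeat(
    epochs: list[EpochRecording],
    repeat_id: str,
    group: str,
    threshold: float = SPEED_THRESHOLD,
    max_rotation: float = MAX_ROTATION,
) -> RepeatBoutSet:
    """Segment all epochs of a repeat and collect accepted bouts."""
    rs = RepeatBoutSet(repeat_id=repeat_id, group=group)
    counts = {reason: 0 for reason in EXCLUSION_REASONS if reason != "none"}
    for epoch in epochs:
        for w in segment_epoch(epoch, threshold=threshold, max_rotation=max_rotation):
            rs.n_raw += 1
            if w.excluded:
                counts[w.exclusion_reason] += 1
            else:
                rs.bouts.append(w)
    rs.n_excluded_by_reason = counts
    return rs


def gate_repeat(repeat: RepeatBoutSet, min_bouts: int = MIN_BOUTS_PER_REPEAT) -> bool:
    """Keep a repeat iff it contains at least ``min_bouts`` accepted bouts.

    The boundary is strict on the low side: 649 bouts drop, 650 keep.
    """
    keep = repeat.n_accepted >= min_bouts
    logger.info(
        "gate_repeat %s (%s): %d accepted bouts -> %s",
        repeat.repeat_id,
        repeat.group,
        repeat.n_accepted,
        "keep" if keep else "drop",
    )
    return keep


def match_bout_numbers(
    control: RepeatBoutSet, condition: RepeatBoutSet, seed: int
) -> tuple[RepeatBoutSet, RepeatBoutSet]:
    """Equalize bout counts across the two groups of one repeat.

    The larger group is subsampled without replacement to the smaller group's
    size, with a seeded generator for reproducibility.  Order within the kept
    subsample follows the original bout order.
    """
    rng = np.random.default_rng(seed)
    n = min(control.n_accepted, condition.n_accepted)

    def _subsample(rs: RepeatBoutSet) -> RepeatBoutSet:
        if rs.n_accepted == n:
            return rs
        idx = np.sort(rng.choice(rs.n_accepted, size=n, replace=False))
        return RepeatBoutSet(
            repeat_id=rs.repeat_id,
            group=rs.group,
            bouts=[rs.bouts[i] for i in idx],
            n_raw=rs.n_raw,
            n_excluded_by_reason=dict(rs.n_excluded_by_reason),
        )

    # draw for control first so the stream layout is fixed
    return _subsample(control), _subsample(condition)


class BoutSegmenter(BaseEstimator, TransformerMixin):
    """Transformer-style wrapper around the bout segmentation pipeline.

    ``transform`` maps an :class:`~pitchkit.io.EpochRecording` (or a list of
    them) to screened :class:`BoutWindow` lists, so segmentation composes with
    sklearn-style parameter handling (``get_params``/``set_params``).
    """

    def __init__(
        self,
        threshold: float = SPEED_THRESHOLD,
        max_rotation: float = MAX_ROTATION,
        min_bouts: int = MIN_BOUTS_PER_REPEAT,
    ):
        self.threshold = threshold
        self.max_rotation = max_rotation
        self.min_bouts = min_bouts

    def fit(self, X=None, y=None) -> "BoutSegmenter":
        self.n_features_in_ = 0  # stateless; nothing is estimated
        return self

    def transform(self, X):
        if isinstance(X, EpochRecording):
            return segment_epoch(
                X, threshold=self.threshold, max_rotation=self.max_rotation
            )
        return [
            segment_epoch(e, threshold=self.threshold, max_rotation=self.max_rotation)
            for e in X
        ]
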