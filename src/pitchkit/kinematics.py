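"""Per-bout kinematic parameters: posture, trajectory, upward rotation, lift.

Conventions (all angles in degrees, nose-up positive; depth z in mm, up
positive):

* *Posture* is the pitch at -250 ms relative to peak speed — the orientation
  from which the bout is launched.
* *Trajectory* is the direction of the displacement vector at peak speed,
  ``atan2(dz, |dx|)``; the sign is carried entirely by depth, because fish
  swim in both horizontal directions and only up/down matters.  Climbs have
  trajectory > 0, dives otherwise (a trajectory of exactly 0 counts as a
  dive; both definitions in the source convention are strict, so a tie rule
  is required and this one is configurable).
* *Upward rotation* is the pitch change from -250 ms to the moment of peak
  angular velocity within the acceleration phase (-250...0 ms) — the trunk's
  contribution to a climb.
* *Lift* is the depth change across the bout in excess of what the posture
  predicts from horizontal travel — the fins' contribution.  It uses the x
  distance covered from -100 to +100 ms and the pitch at -100 ms:
  ``lift = dz_observed - |dx| * tan(pitch(-100 ms))``.

Peak speed assigns each accepted bout to a speed bin:
slow [5, 7.5), medium [7.5, 15), fast [15, inf) mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import BoutWindow

SPEED_BIN_EDGES = (5.0, 7.5, 15.0)
SPEED_BIN_NAMES = ("slow", "medium", "fast")


@dataclass
class BoutKinematics:
    """Derived scalars for one accepted bout."""

    epoch_id: str
    t_peak: float
    posture: float  # deg, pitch at -250 ms
    trajectory: float  # deg, direction of travel at peak speed (NaN if undefined)
    direction_class: str  # climb | dive | undefined
    upward_rotation: float  # deg
    t_peak_angvel: float  # ms relative to peak speed, in [-250, 0]
    lift: float  # mm
    expected_dz: float  # mm
    observed_dz: float  # mm
    peak_speed: float  # mm/s
    speed_bin: str


def posture(bout: BoutWindow) -> float:
    """Pitch angle [deg] at the -250 ms sample (exact grid point)."""
    return float(bout.pitch[0])


def trajectory(bout: BoutWindow) -> float:
    """Direction of travel [deg] at peak speed.

    Computed as ``atan2(dz, |dx|)`` over the two frames bracketing the
    peak-speed sample.  Returns NaN when both displacements are zero — the
    bout is then dropped from direction-classified analyses.
    """
    c = bout.center
    dx = bout.x[c + 1] - bout.x[c - 1]
    dz = bout.z[c + 1] - bout.z[c - 1]
    if dx == 0.0 and dz == 0.0:
        return float("nan")
    return float(np.degrees(np.arctan2(dz, abs(dx))))


def classify_direction(traj: float, tie: str = "dive") -> str:
    """climb iff trajectory > 0 deg, else dive; NaN -> "undefined".

    Both class definitions are strict inequalities, so exactly 0 needs a tie
    rule; the default (and documented) choice is dive.
    """
    if np.isnan(traj):
        return "undefined"
    if traj > 0.0:
        return "climb"
    if traj < 0.0:
        return "dive"
    return tie


def upward_rotation(bout: BoutWindow) -> tuple[float, float]:
    """(rotation [deg], time of peak angular velocity [ms]).

    Angular velocity is the centered difference of pitch times fs; its peak
    is searched over the acceleration phase -250...0 ms, ties broken toward
    the *later* sample (so a constant-rate ramp reports its full extent).
    The rotation is pitch at that moment minus pitch at -250 ms.
    """
    c = bout.center
    dt = 1.0 / bout.fs
    angvel = np.gradient(bout.pitch, dt)[: c + 1]
    j = angvel.size - 1 - int(np.argmax(angvel[::-1]))
    rotation = float(bout.pitch[j] - bout.pitch[0])
    t_ms = (j - c) * dt * 1000.0
    return rotation, float(t_ms)


def lift(bout: BoutWindow) -> tuple[float, float, float]:
    """(lift, expected_dz, observed_dz) in mm.

    ``observed_dz = z(+100 ms) - z(-100 ms)``;
    ``expected_dz = |x(+100 ms) - x(-100 ms)| * tan(pitch(-100 ms))``.
    The horizontal distance enters as a magnitude so the expectation's sign
    comes from the posture alone.
    """
    c = bout.center
    off = int(bout.fs) // 10  # 100 ms in samples: 4 at 40 Hz, 16 at 160 Hz
    pitch_ref = bout.pitch[c - off]
    if abs(pitch_ref) >= 90.0:
        raise ValueError(f"degenerate tangent: |pitch(-100 ms)| = {abs(pitch_ref)} >= 90 deg")
    observed = float(bout.z[c + off] - bout.z[c - off])
    expected = float(abs(bout.x[c + off] - bout.x[c - off]) * np.tan(np.radians(pitch_ref)))
    return observed - expected, expected, observed


def assign_speed_bin(peak_speed: float) -> str:
    """Half-open speed bins [5, 7.5) slow, [7.5, 15) medium, [15, inf) fast."""
    if peak_speed < SPEED_BIN_EDGES[0]:
        raise ValueError(
            f"peak speed {peak_speed} mm/s is below the 5 mm/s floor; such bouts "
            "should have been excluded upstream"
        )
    if peak_speed < SPEED_BIN_EDGES[1]:
        return "slow"
    if peak_speed < SPEED_BIN_EDGES[2]:
        return "medium"
    return "fast"


def compute_kinematics(bout: BoutWindow, tie: str = "dive") -> BoutKinematics:
    traj = trajectory(bout)
    rotation, t_angvel = upward_rotation(bout)
    lift_mm, expected, observed = lift(bout)
    return BoutKinematics(
        epoch_id=bout.epoch_id,
        t_peak=bout.t_peak,
        posture=posture(bout),
        trajectory=traj,
        direction_class=classify_direction(traj, tie=tie),
        upward_rotation=rotation,
        t_peak_angvel=t_angvel,
        lift=lift_mm,
        expected_dz=expected,
        observed_dz=observed,
        peak_speed=bout.peak_speed,
        speed_bin=assign_speed_bin(bout.peak_speed),
    )


def kinematics_table(bouts: list[BoutWindow], tie: str = "dive") -> pd.DataFrame:
    """One row of :class:`BoutKinematics` fields per accepted bout."""
    rows = [vars(compute_kinematics(b, tie=tie)) for b in bouts if not b.excluded]
    columns = [f.name for f in BoutKinematics.__dataclass_fields__.values()]
    return pd.DataFrame(rows, columns=columns)
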