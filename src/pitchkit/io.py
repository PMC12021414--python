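"""Reading and writing of epoch recordings, tilt-trial sets and result tables.

An *epoch* is one continuous tracked recording of a freely swimming larva:
horizontal position ``x`` [mm], depth ``z`` [mm, positive up] and pitch angle
[deg, positive nose-up] on a uniform time grid at 40 or 160 Hz.  Epochs are
stored as plain comma-separated tables with ``# key=value`` metadata comment
lines, one epoch per file, so that every input to the pipeline can be
inspected with a text editor.  A YAML manifest groups epoch files into
experimental repeats and carries the analysis thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_SAMPLING_RATES = (40.0, 160.0)
VALID_GROUPS = ("control", "condition")

_EPOCH_MAGIC = "pitchkit-epoch v1"
_TABLE_MAGIC = "pitchkit-table"
_TRIALS_MAGIC = "pitchkit-tilt-trials v1"

#: tolerance on the uniformity of the time grid, in seconds
_GRID_TOL = 1e-9


@dataclass
class EpochRecording:
    """One continuous tracked swim recording.

    Attributes
    ----------
    t, x, z, pitch : ndarray
        Time [s], horizontal position [mm], depth [mm, up positive] and
        pitch angle [deg, nose-up positive] on a uniform grid.
    fs : float
        Sampling rate in Hz; the apparatus runs at 40 or 160 Hz.
    """

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    pitch: np.ndarray
    fs: float
    epoch_id: str = "epoch"
    fish_id: str = ""
    repeat_id: str = ""
    group: str = "control"
    day_phase: str | None = None

    def __post_init__(self) -> None:
        for name in ("t", "x", "z", "pitch"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.fs not in VALID_SAMPLING_RATES:
            raise ValueError(f"fs must be one of {VALID_SAMPLING_RATES}, got {self.fs}")
        n = self.t.size
        if any(getattr(self, name).size != n for name in ("x", "z", "pitch")):
            raise ValueError("t, x, z, pitch must have equal length")
        for name in ("t", "x", "z", "pitch"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite value in column {name!r} at row {row}")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time grid must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > _GRID_TOL:
                raise ValueError(
                    f"time grid is not uniform at 1/fs = {1.0 / self.fs} s "
                    f"(tolerance {_GRID_TOL} s); resample upstream, not here"
                )
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / fs)."""
        return self.t.size / self.fs


def write_epoch(epoch: EpochRecording, path: str | Path) -> Path:
    """Write an epoch to a delimited text file with metadata comment lines.

    Floats are written with Python's shortest round-trip repr, so
    ``read_epoch(write_epoch(e)) == e`` exactly.
    """
    path = Path(path)
    meta = {
        "fs": epoch.fs,
        "epoch_id": epoch.epoch_id,
        "fish_id": epoch.fish_id,
        "repeat_id": epoch.repeat_id,
        "group": epoch.group,
        "day_phase": "" if epoch.day_phase is None else epoch.day_phase,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_EPOCH_MAGIC}\n")
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write("t,x,z,pitch\n")
        for ti, xi, zi, pi in zip(epoch.t, epoch.x, epoch.z, epoch.pitch):
            fh.write(f"{float(ti)!r},{float(xi)!r},{float(zi)!r},{float(pi)!r}\n")
    return path


def _read_meta_comments(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_epoch(path: str | Path) -> EpochRecording:
    """Read and validate an epoch table written by :func:`write_epoch`.

    Missing columns, NaN entries (reported with their row index) and
    non-uniform time grids are errors; nothing is silently repaired.
    """
    path = Path(path)
    meta = _read_meta_comments(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["t", "x", "z", "pitch"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: NaN in column {col!r} at row {int(bad[0])}")
    if "fs" not in meta:
        raise ValueError(f"{path}: missing 'fs' metadata line")
    day_phase = meta.get("day_phase") or None
    return EpochRecording(
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        z=df["z"].to_numpy(),
        pitch=df["pitch"].to_numpy(),
        fs=float(meta["fs"]),
        epoch_id=meta.get("epoch_id", path.stem),
        fish_id=meta.get("fish_id", ""),
        repeat_id=meta.get("repeat_id", ""),
        group=meta.get("group", "control"),
        day_phase=day_phase,
    )


def filter_day_bouts(
    epochs: Sequence[EpochRecording], constant_darkness: bool = False
) -> list[EpochRecording]:
    """Restrict epochs to the circadian day.

    Night-phase epochs are removed.  Epochs lacking a ``day_phase`` label are
    an error unless ``constant_darkness`` asserts that the experiment ran in
    constant darkness, in which case every epoch passes.
    """
    if constant_darkness:
        return list(epochs)
    unlabeled = [e.epoch_id for e in epochs if e.day_phase is None]
    if unlabeled:
        raise ValueError(
            f"epochs without day_phase labels: {unlabeled}; pass "
            "constant_darkness=True only for constant-darkness experiments"
        )
    kept = [e for e in epochs if e.day_phase == "day"]
    logger.info("filter_day_bouts: kept %d of %d epochs", len(kept), len(epochs))
    if not kept:
        logger.warning("filter_day_bouts: no day-phase epochs remain")
    return kept


@dataclass
class TiltTrialSet:
    """Per-cell tilt-evoked fluorescence traces with trial direction labels.

    ``traces`` is trials x time in arbitrary fluorescence units; ``direction``
    holds one of {"up", "down"} per trial.  ``fs_imaging`` is the volumetric
    imaging rate (3.82 volumes/s in the reference protocol).
    """

    traces: np.ndarray
    direction: np.ndarray
    fs_imaging: float = 3.82
    baseline_window: float = 15.0
    cell_id: str = ""
    fish_id: str = ""
    age: int | None = None
    protocol: str = "eccentric_30"

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.direction = np.asarray(self.direction, dtype=object)
        if self.traces.shape[0] != self.direction.size:
            raise ValueError("one direction label per trial is required")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        if self.fs_imaging <= 0:
            raise ValueError("fs_imaging must be positive")
        bad = set(self.direction) - {"up", "down"}
        if bad:
            raise ValueError(f"unknown trial directions: {sorted(bad)}")
        if self.protocol not in ("eccentric_30", "return_19"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    def n_trials(self, direction: str) -> int:
        return int(np.sum(self.direction == direction))


def write_tilt_trials(trials: TiltTrialSet, path: str | Path) -> Path:
    path = Path(path)
    n_time = trials.traces.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_TRIALS_MAGIC}\n")
        fh.write(f"# fs_imaging={trials.fs_imaging!r}\n")
        fh.write(f"# baseline_window={trials.baseline_window!r}\n")
        fh.write(f"# cell_id={trials.cell_id}\n")
        fh.write(f"# fish_id={trials.fish_id}\n")
        fh.write(f"# age={'' if trials.age is None else trials.age}\n")
        fh.write(f"# protocol={trials.protocol}\n")
        fh.write("trial,direction," + ",".join(f"f{i}" for i in range(n_time)) + "\n")
        for i, (row, d) in enumerate(zip(trials.traces, trials.direction)):
            fh.write(f"{i},{d}," + ",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_tilt_trials(path: str | Path) -> TiltTrialSet:
    path = Path(path)
    meta = _read_meta_comments(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    f_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    f_cols.sort(key=lambda c: int(c[1:]))
    age = meta.get("age") or None
    return TiltTrialSet(
        traces=df[f_cols].to_numpy(),
        direction=df["direction"].to_numpy(),
        fs_imaging=float(meta.get("fs_imaging", 3.82)),
        baseline_window=float(meta.get("baseline_window", 15.0)),
        cell_id=meta.get("cell_id", path.stem),
        fish_id=meta.get("fish_id", ""),
        age=None if age is None else int(age),
        protocol=meta.get("protocol", "eccentric_30"),
    )


#: analysis thresholds a manifest may override; values are the pipeline defaults
DEFAULT_THRESHOLDS = {
    "speed_threshold": 5.0,  # mm/s, strict
    "max_rotation": 30.0,  # deg over the acceleration phase, strict
    "min_bouts_per_repeat": 650,
    "di_cutoff": 0.35,
    "n_boot_median": 1000,
    "n_boot_slope": 100,
    "alpha": 0.05,
}


@dataclass
class ManifestEntry:
    path: Path
    group: str
    repeat_id: str = ""
    fish_id: str = ""
    age: int | None = None


@dataclass
class Manifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))


def load_manifest(path: str | Path) -> Manifest:
    """Load a YAML manifest; every referenced file must exist."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds", {}))
    entries = []
    for item in raw.get("epochs", []):
        p = (path.parent / item["path"]).resolve()
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
        group = item.get("group", "control")
        if group not in VALID_GROUPS:
            raise ValueError(f"manifest group must be one of {VALID_GROUPS}: {group!r}")
        entries.append(
            ManifestEntry(
                path=p,
                group=group,
                repeat_id=str(item.get("repeat_id", "")),
                fish_id=str(item.get("fish_id", "")),
                age=item.get("age"),
            )
        )
    return Manifest(entries=entries, thresholds=thresholds)


def write_table(df: pd.DataFrame, path: str | Path, name: str) -> Path:
    """Write a result table as delimited text with a schema version line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_TABLE_MAGIC} {name} v1\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
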