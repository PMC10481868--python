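"""Domain containers for gaze/head streams, classified events and trial metrics.

Streams are stored as column arrays (one array per field) rather than lists of
sample objects: trials at 90 Hz hold a few hundred samples each and every
downstream operation is vectorized over them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "Sex",
    "PUNCH_TYPES",
    "TrialKey",
    "GazeStream",
    "HeadStream",
    "VelocitySeries",
    "GazeEvent",
    "GazeTrialMetrics",
    "EulerSeries",
    "HeadTrialMetrics",
]


class Condition(str, Enum):
    """The two viewing modes under comparison."""

    VIDEO_2D = "2D"
    VR_360_3D = "3D360VR"


class Sex(str, Enum):
    F = "F"
    M = "M"


#: The four punch types shown as stimuli, six videos of each per condition.
PUNCH_TYPES = ("straight", "jab", "uppercut", "hook")

#: (participant_id, condition value, video_id) — the unit of analysis.
TrialKey = tuple[str, str, str]


def _as_float_array(x, ndim: int) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != ndim:
        raise ValueError(f"expected {ndim}-d array, got shape {a.shape}")
    return a


@dataclass
class GazeStream:
    """Time-stamped gaze directions for one trial.

    ``t_ms`` is trial-relative (first sample at 0) and strictly increasing.
    ``dirs`` holds unit 3-vectors in the headset frame wherever ``valid`` is
    True; invalid rows (tracker dropout, blink, degenerate vector) are kept in
    place so that event segmentation can see where the gaps are.
    """

    t_ms: np.ndarray
    dirs: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = _as_float_array(self.t_ms, 1)
        self.dirs = _as_float_array(self.dirs, 2)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if self.dirs.shape != (n, 3) or self.valid.shape != (n,):
            raise ValueError("t_ms, dirs and valid must have matching lengths")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])


@dataclass
class HeadStream:
    """Time-stamped head orientations (unit quaternions, scalar-first w,x,y,z)."""

    t_ms: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = _as_float_array(self.t_ms, 1)
        self.quat = _as_float_array(self.quat, 2)
        n = len(self.t_ms)
        if self.quat.shape != (n, 4):
            raise ValueError("quat must be (n, 4) scalar-first")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])


@dataclass
class VelocitySeries:
    """Angular speed between consecutive gaze samples.

    One entry per inter-sample interval: ``t_mid_ms`` is the interval midpoint,
    ``v_deg_s`` the great-circle angle between the bounding directions divided
    by the elapsed time. ``t_edges_ms`` keeps the original sample times so that
    event boundaries can be expressed in sample time. Intervals touching an
    invalid sample are invalid unless they were bridged across a short gap.
    """

    t_mid_ms: np.ndarray
    v_deg_s: np.ndarray
    valid: np.ndarray
    t_edges_ms: np.ndarray

    def __post_init__(self) -> None:
        self.t_mid_ms = _as_float_array(self.t_mid_ms, 1)
        self.v_deg_s = _as_float_array(self.v_deg_s, 1)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.t_edges_ms = _as_float_array(self.t_edges_ms, 1)
        n = len(self.v_deg_s)
        if len(self.t_mid_ms) != n or len(self.valid) != n or len(self.t_edges_ms) != n + 1:
            raise ValueError("inconsistent velocity-series lengths")

    def __len__(self) -> int:
        return len(self.v_deg_s)


@dataclass(frozen=True)
class GazeEvent:
    """A classified interval of a trial: fixation, saccade or unclassified."""

    kind: str  # "fixation" | "saccade" | "unclassified"
    onset_ms: float
    offset_ms: float
    peak_v_deg_s: float = math.nan

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class GazeTrialMetrics:
    """Per-trial gaze dependent variables.

    Counts are normalized to a reference video duration so trials of different
    lengths sit on one scale. ``search_rate`` is fixation count divided by the
    total fixation time (ms^-1); it and ``mean_fix_dur_ms`` are NaN when the
    trial contains no fixation.
    """

    n_fixations_norm: float
    mean_fix_dur_ms: float
    n_saccades_norm: float
    search_rate: float


@dataclass
class EulerSeries:
    """Unwrapped intrinsic yaw→pitch→roll angles, degrees, per head sample."""

    t_ms: np.ndarray
    roll_deg: np.ndarray
    pitch_deg: np.ndarray
    yaw_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass(frozen=True)
class HeadTrialMetrics:
    """Duration-normalized per-axis head excursion (degrees)."""

    roll_exc_deg: float
    pitch_exc_deg: float
    yaw_exc_deg: float
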