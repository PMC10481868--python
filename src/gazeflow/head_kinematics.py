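"""Head-orientation kinematics: Euler decomposition and per-axis excursion.

Axis convention (a fixed contract of this package): the world frame is
x-forward, y-left, z-up; orientations decompose intrinsically in the order
yaw (about vertical z) → pitch (about lateral y) → roll (about forward x).
Angles are reported in degrees and sequentially unwrapped per axis so that
path lengths are not inflated by ±180° wrap-around.

Excursion is the cumulative absolute angular path per axis, rescaled to a
reference video duration — a trial twice as long as the reference contributes
half its raw path. A net-range mode (max − min) is available behind a switch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError
from .types import EulerSeries, HeadStream, HeadTrialMetrics

__all__ = [
    "ExcursionParams",
    "quat_to_euler",
    "euler_to_quat",
    "axis_excursion",
    "head_trial_metrics",
]

#: scipy code for intrinsic yaw(z) → pitch(y) → roll(x)
_EULER_ORDER = "ZYX"


@dataclass(frozen=True)
class ExcursionParams:
    """Excursion options: minimum step size (deg, 0 = off), path vs range mode."""

    min_step_deg: float = 0.0
    mode: str = "path"  # "path" | "range"
    ref_duration_ms: float = 3600.0


def quat_to_euler(stream: HeadStream) -> EulerSeries:
    """Decompose unit quaternions into unwrapped yaw/pitch/roll (degrees).

    Emits a warning (values still returned) when any pitch sample comes
    within 1° of the ±90° gimbal singularity, where yaw and roll become
    poorly separated.
    """
    rot = Rotation.from_quat(stream.quat, scalar_first=True)
    ypr = rot.as_euler(_EULER_ORDER, degrees=True)  # columns: yaw, pitch, roll
    yaw = np.unwrap(ypr[:, 0], period=360.0)
    pitch = ypr[:, 1]  # bounded in [-90, 90] by the decomposition
    roll = np.unwrap(ypr[:, 2], period=360.0)
    if np.any(np.abs(pitch) > 89.0):
        warnings.warn(
            "pitch within 1 deg of gimbal singularity; yaw/roll may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return EulerSeries(t_ms=stream.t_ms, roll_deg=roll, pitch_deg=pitch, yaw_deg=yaw)


def euler_to_quat(yaw_deg, pitch_deg, roll_deg) -> np.ndarray:
    """Compose yaw/pitch/roll (degrees) into scalar-first unit quaternions."""
    ang = np.stack(
        [np.asarray(yaw_deg, float), np.asarray(pitch_deg, float), np.asarray(roll_deg, float)],
        axis=-1,
    )
    return Rotation.from_euler(_EULER_ORDER, ang, degrees=True).as_quat(scalar_first=True)


def _excursion_1d(angles: np.ndarray, min_step_deg: float, mode: str) -> float:
    if mode == "range":
        return float(np.max(angles) - np.min(angles))
    steps = np.abs(np.diff(angles))
    if min_step_deg > 0:
        steps = steps[steps >= min_step_deg]
    return float(steps.sum())


def axis_excursion(
    e: EulerSeries,
    duration_ms: float,
    ref_duration_ms: float = 3600.0,
    *,
    min_step_deg: float = 0.0,
    mode: str = "path",
) -> HeadTrialMetrics:
    """Duration-normalized excursion per axis (degrees).

    Per axis, the raw excursion is the summed absolute step size over the
    unwrapped series (or max − min in ``range`` mode), multiplied by
    ``ref_duration_ms / duration_ms``.
    """
    if len(e) < 2:
        raise InsufficientDataError("need at least 2 head samples for excursion")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if mode not in ("path", "range"):
        raise ValueError(f"unknown excursion mode: {mode!r}")
    scale = ref_duration_ms / duration_ms
    return HeadTrialMetrics(
        roll_exc_deg=_excursion_1d(e.roll_deg, min_step_deg, mode) * scale,
        pitch_exc_deg=_excursion_1d(e.pitch_deg, min_step_deg, mode) * scale,
        yaw_exc_deg=_excursion_1d(e.yaw_deg, min_step_deg, mode) * scale,
    )


def head_trial_metrics(
    stream: HeadStream,
    duration_ms: float | None = None,
    params: ExcursionParams = ExcursionParams(),
) -> HeadTrialMetrics:
    """Convenience chain: quaternions → Euler series → excursion metrics."""
    e = quat_to_euler(stream)
    dur = stream.duration_ms if duration_ms is None else duration_ms
    return axis_excursion(
        e,
        dur,
        params.ref_duration_ms,
        min_step_deg=params.min_step_deg,
        mode=params.mode,
    )
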