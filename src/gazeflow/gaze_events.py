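"""Adaptive velocity-threshold (I-VT) gaze-event classification.

The chain is: angular speed between consecutive gaze directions → an adaptive
saccade threshold at five times the median trial speed → maximal same-side
runs gated by duration (saccades last at most 50 ms, fixations more than
100 ms; everything else is left unclassified) → per-trial summary metrics.

Tracker dropouts shorter than a blink-scale limit are bridged by assuming
constant angular velocity across the gap; longer dropouts split the
segmentation and are reported as gaps, not events.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .types import GazeEvent, GazeStream, GazeTrialMetrics, VelocitySeries

__all__ = [
    "EventDetectionParams",
    "angular_velocity",
    "saccade_threshold",
    "classify_events",
    "gaze_trial_metrics",
    "detect_events",
]

FIXATION = "fixation"
SACCADE = "saccade"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class EventDetectionParams:
    """Tunable parameters of the event detector.

    saccade_max_ms / fixation_min_ms are the duration gates; the velocity
    threshold is ``threshold_multiplier`` times the median trial speed.
    ``gap_bridge_ms`` is the longest invalid run that is interpolated over
    (blink-scale); ``ref_duration_ms`` the video duration counts are
    normalized to. ``smoothing`` enables an optional 3-sample median filter
    on the speed trace (off by default).
    """

    saccade_max_ms: float = 50.0
    fixation_min_ms: float = 100.0
    threshold_multiplier: float = 5.0
    gap_bridge_ms: float = 75.0
    ref_duration_ms: float = 3600.0
    smoothing: bool = False


def _angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    dots = np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def angular_velocity(stream: GazeStream, *, gap_bridge_ms: float = 75.0) -> VelocitySeries:
    """Angular speed (deg/s) over each inter-sample interval of a trial.

    Speed is the great-circle angle between consecutive unit gaze directions
    divided by the elapsed time. Intervals bounded by an invalid sample are
    invalid, except that invalid runs no longer than ``gap_bridge_ms`` with
    valid samples on both sides are bridged: the angle between the flanking
    valid directions is spread uniformly over the gap (linear interpolation of
    the subtended angle), and the bridged intervals count as valid.
    """
    if len(stream) < 2 or int(stream.valid.sum()) < 2:
        raise InsufficientDataError("need at least 2 valid samples to compute velocity")
    t = stream.t_ms
    dirs = stream.dirs
    dt_s = np.diff(t) / 1000.0
    v = np.full(len(t) - 1, np.nan)
    valid_iv = stream.valid[:-1] & stream.valid[1:]
    both = valid_iv
    v[both] = _angle_deg(dirs[:-1][both], dirs[1:][both]) / dt_s[both]

    # Bridge short invalid runs bounded by valid samples on both sides.
    valid_iv = valid_iv.copy()
    n_iv = len(v)
    i = 0
    while i < n_iv:
        if valid_iv[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_iv and not valid_iv[j + 1]:
            j += 1
        # invalid intervals i..j; bounding samples i and j+1
        if stream.valid[i] and stream.valid[j + 1]:
            gap_ms = t[j + 1] - t[i]
            if gap_ms <= gap_bridge_ms:
                ang = _angle_deg(dirs[i : i + 1], dirs[j + 1 : j + 2])[0]
                v[i : j + 1] = ang / (gap_ms / 1000.0)
                valid_iv[i : j + 1] = True
        i = j + 1

    t_mid = 0.5 * (t[:-1] + t[1:])
    return VelocitySeries(t_mid_ms=t_mid, v_deg_s=v, valid=valid_iv, t_edges_ms=t)


def saccade_threshold(v: VelocitySeries, *, multiplier: float = 5.0) -> float:
    """Adaptive saccade threshold: ``multiplier`` × median valid speed (deg/s)."""
    speeds = v.v_deg_s[v.valid]
    if speeds.size == 0:
        raise InsufficientDataError("no valid velocity intervals")
    return multiplier * float(np.median(speeds))


def _median3(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return x.copy()
    out = x.copy()
    stacked = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def classify_events(
    v: VelocitySeries,
    threshold: float,
    *,
    saccade_max_ms: float = 50.0,
    fixation_min_ms: float = 100.0,
) -> list[GazeEvent]:
    """Segment a velocity series into fixation/saccade/unclassified events.

    Within each contiguous stretch of valid intervals, maximal runs with speed
    strictly above the threshold become saccades when the run lasts at most
    ``saccade_max_ms`` (otherwise unclassified); runs at or below the
    threshold become fixations when they last more than ``fixation_min_ms``
    (otherwise unclassified). Speeds exactly at the threshold count as below.
    Invalid stretches (unbridged gaps) split runs and are not events, so the
    returned events plus the gaps tile the trial. Event boundaries are the
    bounding sample times.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    events: list[GazeEvent] = []
    t = v.t_edges_ms
    n = len(v)
    i = 0
    while i < n:
        if not v.valid[i]:
            i += 1
            continue
        above = v.v_deg_s[i] > threshold
        j = i
        while j + 1 < n and v.valid[j + 1] and (v.v_deg_s[j + 1] > threshold) == above:
            j += 1
        onset, offset = float(t[i]), float(t[j + 1])
        dur = offset - onset
        peak = float(np.max(v.v_deg_s[i : j + 1]))
        if above:
            kind = SACCADE if dur <= saccade_max_ms else UNCLASSIFIED
        else:
            kind = FIXATION if dur > fixation_min_ms else UNCLASSIFIED
        events.append(GazeEvent(kind=kind, onset_ms=onset, offset_ms=offset, peak_v_deg_s=peak))
        i = j + 1
    return events


def gaze_trial_metrics(
    events: list[GazeEvent],
    duration_ms: float,
    ref_duration_ms: float = 3600.0,
) -> GazeTrialMetrics:
    """Per-trial gaze metrics from a classified event list.

    Fixation and saccade counts are rescaled by ``ref_duration_ms /
    duration_ms`` so that trials of different video lengths are comparable.
    The search rate is the raw fixation count divided by the summed fixation
    duration (ms^-1). With no fixations the duration-based metrics are NaN.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    scale = ref_duration_ms / duration_ms
    fix_durs = np.array([e.duration_ms for e in events if e.kind == FIXATION])
    n_sacc = sum(1 for e in events if e.kind == SACCADE)
    n_fix = len(fix_durs)
    if n_fix:
        mean_dur = float(fix_durs.mean())
        search_rate = n_fix / float(fix_durs.sum())
    else:
        mean_dur = float("nan")
        search_rate = float("nan")
    return GazeTrialMetrics(
        n_fixations_norm=n_fix * scale,
        mean_fix_dur_ms=mean_dur,
        n_saccades_norm=n_sacc * scale,
        search_rate=search_rate,
    )


def detect_events(
    stream: GazeStream, params: EventDetectionParams = EventDetectionParams()
) -> tuple[list[GazeEvent], float]:
    """Run the full detection chain on one trial; returns (events, threshold)."""
    v = angular_velocity(stream, gap_bridge_ms=params.gap_bridge_ms)
    if params.smoothing:
        sm = v.v_deg_s.copy()
        sm[v.valid] = _median3(v.v_deg_s[v.valid])
        v = VelocitySeries(v.t_mid_ms, sm, v.valid, v.t_edges_ms)
    thr = saccade_threshold(v, multiplier=params.threshold_multiplier)
    events = classify_events(
        v,
        thr,
        saccade_max_ms=params.saccade_max_ms,
        fixation_min_ms=params.fixation_min_ms,
    )
    return events, thr
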