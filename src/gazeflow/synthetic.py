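"""Synthetic study generator with ground truth for every pipeline stage.

Emulates a two-condition within-subject viewing study: 32 participants (16
per sex), two viewing modes (flat 2D video vs stereoscopic 360° VR), 24
trials per condition (six per punch type), gaze sampled at 90 Hz with trials
averaging 3.6 s. Condition effects are built in where the study design
expects them — fixation durations (shorter in VR), roll and pitch head
excursion (larger in VR), and sense of presence (higher in VR) — while yaw
excursion, the remaining questionnaire items and heart rate are generated
condition-invariant.

Gaze trials alternate fixations and saccades: fixation durations are
lognormal (right-skewed, positive), moment-matched to the configured
mean/SD; within a fixation the gaze direction jitters isotropically around
an anchor; saccades traverse a great-circle arc with a symmetric triangular
velocity profile whose peak sits well above the adaptive detection
threshold (a fixed main-sequence coupling: amplitude = duration × peak
velocity / 2). Head traces are smoothed-random-walk angle series per axis,
rescaled so the trial's true duration-normalized excursion exactly equals
the drawn target. Participant random intercepts are added to every channel.
Everything is reproducible from (config, seed).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigError, DataError
from .head_kinematics import euler_to_quat
from .types import PUNCH_TYPES, Condition, GazeEvent, GazeStream, HeadStream, TrialKey
from .workload import SIMTLX_ITEMS

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_study",
    "generate_metrics_table",
    "recovery_report",
    "write_study",
]

C2D = Condition.VIDEO_2D.value
CVR = Condition.VR_360_3D.value
AXES = ("roll", "pitch", "yaw")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level generating parameters; defaults are the reference study
    conditions (group means/SDs per viewing mode).

    Between-participant SDs split each marginal SD into a shared participant
    intercept and a within-participant remainder, so the marginal spread of a
    single observation matches the configured SD.
    """

    n_participants: int = 32  # half F, half M
    trials_per_condition: int = 24  # 6 per punch type
    sample_rate_hz: float = 90.0
    trial_duration_mean_ms: float = 3600.0
    trial_duration_sd_ms: float = 400.0

    fixation_dur_mean_ms: dict = field(
        default_factory=lambda: {C2D: 457.5, CVR: 365.8}
    )
    fixation_dur_sd_ms: dict = field(default_factory=lambda: {C2D: 198.8, CVR: 170.1})
    fixation_between_sd_ms: float = 80.0
    fixation_min_gate_ms: float = 100.0  # detector gate the ground truth must satisfy

    saccade_dur_range_ms: tuple = (20.0, 50.0)
    saccade_peak_v_deg_s: float = 400.0
    fixation_noise_deg: float = 0.1  # isotropic per-component jitter SD

    head_excursion_mean_deg: dict = field(
        default_factory=lambda: {
            "roll": {C2D: 39.9, CVR: 55.7},
            "pitch": {C2D: 41.8, CVR: 71.2},
            "yaw": {C2D: 45.0, CVR: 45.0},  # no condition effect on yaw
        }
    )
    head_excursion_sd_deg: dict = field(
        default_factory=lambda: {
            "roll": {C2D: 18.8, CVR: 22.3},
            "pitch": {C2D: 16.6, CVR: 35.1},
            "yaw": {C2D: 19.0, CVR: 19.0},
        }
    )
    head_between_sd_deg: dict = field(
        default_factory=lambda: {"roll": 9.0, "pitch": 10.0, "yaw": 8.5}
    )

    presence_mean: dict = field(default_factory=lambda: {C2D: 7.8, CVR: 15.1})
    presence_sd: dict = field(default_factory=lambda: {C2D: 5.4, CVR: 3.4})
    presence_between_sd: float = 2.0
    simtlx_item_means: dict = field(
        default_factory=lambda: {
            "mental_demand": 9.0,
            "physical_demand": 5.0,
            "temporal_demand": 8.0,
            "frustration": 5.0,
            "task_complexity": 7.0,
            "situational_stress": 6.0,
            "distraction": 4.0,
            "perceptual_constraints": 6.0,
            "task_performance": 12.0,
        }
    )
    simtlx_item_sd: float = 3.5
    simtlx_between_sd: float = 1.5

    hr_mean_bpm: dict = field(
        default_factory=lambda: {
            ("F", C2D): 96.6,
            ("F", CVR): 95.1,
            ("M", C2D): 90.5,
            ("M", CVR): 90.4,
        }
    )
    hr_sd_bpm: float = 11.5
    hr_between_sd_bpm: float = 9.0

    ref_duration_ms: float = 3600.0

    def validate(self) -> None:
        if self.n_participants < 2 or self.n_participants % 2:
            raise ConfigError("n_participants must be an even number >= 2")
        if self.trials_per_condition % len(PUNCH_TYPES):
            raise ConfigError("trials_per_condition must be a multiple of 4 punch types")
        for cond, mu in self.fixation_dur_mean_ms.items():
            if mu <= self.fixation_min_gate_ms + 20:
                raise ConfigError(
                    f"fixation mean {mu} ms ({cond}) infeasible: below the fixation gate"
                )
            if self.fixation_dur_sd_ms[cond] <= self.fixation_between_sd_ms:
                raise ConfigError("fixation between-SD must be below the marginal SD")
        for axis in AXES:
            for cond in (C2D, CVR):
                if self.head_excursion_sd_deg[axis][cond] <= self.head_between_sd_deg[axis]:
                    raise ConfigError(f"head between-SD must be below marginal SD ({axis})")
        for scale in (
            self.trial_duration_mean_ms,
            self.trial_duration_sd_ms,
            self.saccade_peak_v_deg_s,
            self.fixation_noise_deg,
            self.sample_rate_hz,
        ):
            if scale <= 0:
                raise ConfigError("all scale parameters must be positive")


@dataclass
class GroundTruth:
    """Generating truth per trial: event list, head excursions, and the
    config the study was drawn from."""

    events: pd.DataFrame  # participant_id, condition, video_id, kind, onset_ms, offset_ms
    excursions: pd.DataFrame  # ..., roll_exc_deg, pitch_exc_deg, yaw_exc_deg (true targets)
    config: GeneratorConfig

    def events_for(self, key: TrialKey) -> list[GazeEvent]:
        pid, cond, vid = key
        g = self.events
        m = (
            (g["participant_id"] == pid)
            & (g["condition"] == cond)
            & (g["video_id"] == vid)
        )
        return [
            GazeEvent(kind=k, onset_ms=a, offset_ms=b)
            for k, a, b in zip(g.loc[m, "kind"], g.loc[m, "onset_ms"], g.loc[m, "offset_ms"])
        ]


@dataclass
class SyntheticStudy:
    manifest: pd.DataFrame
    gaze: dict
    head: dict
    simtlx: pd.DataFrame
    heart_rate: pd.DataFrame
    ground_truth: GroundTruth


def _lognormal_mv(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws moment-matched to the requested mean and SD."""
    cv2 = (sd / mean) ** 2
    s2 = np.log1p(cv2)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mu, np.sqrt(s2), size=size)


def _within_sd(marginal: float, between: float) -> float:
    return float(np.sqrt(max(marginal**2 - between**2, 1e-12)))


def _draw_fixation_dur(rng, mean, sd, floor_ms):
    for _ in range(100):
        d = float(_lognormal_mv(rng, mean, sd))
        if d > floor_ms:
            return d
    return floor_ms + 1.0


def _assemble_events(rng, cfg: GeneratorConfig, fix_mean: float, fix_sd: float):
    """Alternate fixation/saccade intervals until the drawn trial duration is
    filled, starting and ending with a complete fixation. The nominal target
    is shifted down by half a mean fixation so realized durations center on
    the configured trial mean."""
    floor = cfg.fixation_min_gate_ms + 10.0
    nominal = float(
        _lognormal_mv(
            rng,
            max(cfg.trial_duration_mean_ms - 0.5 * fix_mean, 0.25 * cfg.trial_duration_mean_ms),
            cfg.trial_duration_sd_ms,
        )
    )
    events = []  # (kind, duration_ms, peak_v or nan)
    cum = 0.0
    while True:
        d = _draw_fixation_dur(rng, fix_mean, fix_sd, floor)
        events.append(("fixation", d, np.nan))
        cum += d
        if cum >= nominal:
            break
        sd_ms = float(rng.uniform(*cfg.saccade_dur_range_ms))
        peak = cfg.saccade_peak_v_deg_s * float(rng.uniform(0.85, 1.15))
        events.append(("saccade", sd_ms, peak))
        cum += sd_ms
    return events, cum


def _gaze_trial(rng, cfg: GeneratorConfig, events, duration_ms: float) -> GazeStream:
    """Sample the gaze direction stream for one trial's event sequence."""
    dt = 1000.0 / cfg.sample_rate_hz
    n = int(np.floor(duration_ms / dt)) + 1
    t = np.arange(n) * dt

    onsets = np.concatenate([[0.0], np.cumsum([d for _, d, _ in events])])
    # anchor positions (azimuth, elevation in deg) for each fixation
    az, el = 0.0, 0.0
    anchors = []
    for kind, d, peak in events:
        if kind == "fixation":
            anchors.append((az, el))
        else:
            amp = peak * (d / 1000.0) / 2.0  # triangular profile: area under v
            theta = rng.uniform(0, 2 * np.pi)
            if abs(el + amp * np.sin(theta)) > 40.0:
                theta = -theta
            az += amp * np.cos(theta)
            el += amp * np.sin(theta)
            el = float(np.clip(el, -60.0, 60.0))

    pos = np.zeros((n, 2))
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(events) - 1)
    fix_counter = -1
    for e_i, (kind, d, peak) in enumerate(events):
        mask = idx == e_i
        m = int(mask.sum())
        if kind == "fixation":
            fix_counter += 1
            if m:
                a = anchors[fix_counter]
                pos[mask] = np.asarray(a) + rng.normal(0.0, cfg.fixation_noise_deg, size=(m, 2))
        else:
            if m:
                a = np.asarray(anchors[fix_counter])
                b = np.asarray(anchors[fix_counter + 1])
                tau = (t[mask] - onsets[e_i]) / d
                frac = np.where(tau < 0.5, 2 * tau**2, 1 - 2 * (1 - tau) ** 2)
                pos[mask] = a + (b - a)[None, :] * frac[:, None]

    az_r = np.radians(pos[:, 0])
    el_r = np.radians(pos[:, 1])
    dirs = np.column_stack(
        [np.cos(el_r) * np.cos(az_r), np.cos(el_r) * np.sin(az_r), np.sin(el_r)]
    )
    return GazeStream(t_ms=t, dirs=dirs, valid=np.ones(n, dtype=bool))


def _head_trial(rng, cfg: GeneratorConfig, duration_ms: float, targets: dict) -> HeadStream:
    """Smoothed-random-walk angle series per axis, rescaled so the
    duration-normalized path length equals the drawn target exactly."""
    dt = 1000.0 / cfg.sample_rate_hz
    n = int(np.floor(duration_ms / dt)) + 1
    t = np.arange(n) * dt
    series = {}
    for axis in AXES:
        path_needed = targets[axis] * duration_ms / cfg.ref_duration_ms
        for _ in range(5):
            e = rng.normal(size=n)
            v = lfilter([1.0], [1.0, -0.9], e)  # AR(1)-smoothed increments
            x = np.cumsum(v)
            x -= x[0]
            pl = np.abs(np.diff(x)).sum()
            x = x * (path_needed / pl) if pl > 0 else x
            if axis != "pitch" or np.max(np.abs(x)) < 80.0:
                break
        series[axis] = x
    quat = euler_to_quat(series["yaw"], series["pitch"], series["roll"])
    return HeadStream(t_ms=t, quat=quat)


def generate_study(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study (raw streams + tables + truth)."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_p = cfg.n_participants
    half = n_p // 2
    pids = [f"P{i + 1:02d}" for i in range(n_p)]
    sexes = ["F"] * half + ["M"] * half
    # counterbalanced: alternating start condition within each sex block
    first_cond = [C2D if i % 2 == 0 else CVR for i in range(n_p)]

    fix_within = {c: _within_sd(cfg.fixation_dur_sd_ms[c], cfg.fixation_between_sd_ms) for c in (C2D, CVR)}
    head_within = {
        ax: {c: _within_sd(cfg.head_excursion_sd_deg[ax][c], cfg.head_between_sd_deg[ax]) for c in (C2D, CVR)}
        for ax in AXES
    }

    manifest_rows = []
    gt_event_rows = []
    gt_exc_rows = []
    gaze: dict[TrialKey, GazeStream] = {}
    head: dict[TrialKey, HeadStream] = {}
    simtlx_rows = []
    hr_rows = []

    n_per_punch = cfg.trials_per_condition // len(PUNCH_TYPES)
    for p_i, (pid, sex) in enumerate(zip(pids, sexes)):
        b_fix = rng.normal(0.0, cfg.fixation_between_sd_ms)
        b_head = {ax: rng.normal(0.0, cfg.head_between_sd_deg[ax]) for ax in AXES}
        b_presence = rng.normal(0.0, cfg.presence_between_sd)
        b_items = {it: rng.normal(0.0, cfg.simtlx_between_sd) for it in cfg.simtlx_item_means}
        b_hr = rng.normal(0.0, cfg.hr_between_sd_bpm)

        cond_order = [first_cond[p_i], CVR if first_cond[p_i] == C2D else C2D]
        for cond in cond_order:
            punches = np.repeat(PUNCH_TYPES, n_per_punch)
            rng.shuffle(punches)
            fix_mean_pc = max(cfg.fixation_dur_mean_ms[cond] + b_fix, cfg.fixation_min_gate_ms + 40)
            for t_i, punch in enumerate(punches):
                vid = f"{cond}-{punch}-{t_i + 1:02d}"
                key: TrialKey = (pid, cond, vid)
                events, duration = _assemble_events(rng, cfg, fix_mean_pc, fix_within[cond])
                gaze[key] = _gaze_trial(rng, cfg, events, duration)
                targets = {}
                for ax in AXES:
                    mean_ax = max(cfg.head_excursion_mean_deg[ax][cond] + b_head[ax], 2.0)
                    targets[ax] = float(_lognormal_mv(rng, mean_ax, head_within[ax][cond]))
                head[key] = _head_trial(rng, cfg, duration, targets)

                manifest_rows.append(
                    {
                        "participant_id": pid,
                        "sex": sex,
                        "condition": cond,
                        "punch_type": punch,
                        "video_id": vid,
                        "duration_ms": duration,
                        "order_first_condition": first_cond[p_i],
                    }
                )
                onset = 0.0
                for kind, d, _ in events:
                    gt_event_rows.append(
                        {
                            "participant_id": pid,
                            "condition": cond,
                            "video_id": vid,
                            "kind": kind,
                            "onset_ms": onset,
                            "offset_ms": onset + d,
                        }
                    )
                    onset += d
                gt_exc_rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "video_id": vid,
                        "roll_exc_deg": targets["roll"],
                        "pitch_exc_deg": targets["pitch"],
                        "yaw_exc_deg": targets["yaw"],
                    }
                )

            pres_within = _within_sd(cfg.presence_sd[cond], cfg.presence_between_sd)
            presence = float(
                np.clip(round(rng.normal(cfg.presence_mean[cond] + b_presence, pres_within), 1), 0, 20)
            )
            simtlx_rows.append(
                {"participant_id": pid, "condition": cond, "item": "sense_of_presence", "score": presence}
            )
            item_within = _within_sd(cfg.simtlx_item_sd, cfg.simtlx_between_sd)
            for it, mu in cfg.simtlx_item_means.items():
                val = float(np.clip(round(rng.normal(mu + b_items[it], item_within), 1), 0, 20))
                simtlx_rows.append(
                    {"participant_id": pid, "condition": cond, "item": it, "score": val}
                )
            hr_within = _within_sd(cfg.hr_sd_bpm, cfg.hr_between_sd_bpm)
            hr_rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "mean_bpm": float(rng.normal(cfg.hr_mean_bpm[(sex, cond)] + b_hr, hr_within)),
                }
            )

    gt = GroundTruth(
        events=pd.DataFrame(gt_event_rows),
        excursions=pd.DataFrame(gt_exc_rows),
        config=cfg,
    )
    return SyntheticStudy(
        manifest=pd.DataFrame(manifest_rows),
        gaze=gaze,
        head=head,
        simtlx=pd.DataFrame(simtlx_rows),
        heart_rate=pd.DataFrame(hr_rows),
        ground_truth=gt,
    )


def generate_metrics_table(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> pd.DataFrame:
    """Fast path: draw per-trial summary metrics directly from the generating
    model, skipping raw-stream synthesis. Used for simulation studies of the
    inference stage (calibration, power), where only the trial-level
    distributions matter. The per-trial mean fixation duration is a mean over
    the trial's expected fixation count, so its spread shrinks accordingly.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_p = cfg.n_participants
    half = n_p // 2
    sacc_mean = float(np.mean(cfg.saccade_dur_range_ms))
    rows = []
    for p_i in range(n_p):
        pid = f"P{p_i + 1:02d}"
        sex = "F" if p_i < half else "M"
        b_fix = rng.normal(0.0, cfg.fixation_between_sd_ms)
        b_head = {ax: rng.normal(0.0, cfg.head_between_sd_deg[ax]) for ax in AXES}
        for cond in (C2D, CVR):
            mu_fix = cfg.fixation_dur_mean_ms[cond] + b_fix
            w_fix = _within_sd(cfg.fixation_dur_sd_ms[cond], cfg.fixation_between_sd_ms)
            m_fix = max(cfg.trial_duration_mean_ms / (cfg.fixation_dur_mean_ms[cond] + sacc_mean), 1.0)
            for t_i in range(cfg.trials_per_condition):
                row = {
                    "participant_id": pid,
                    "sex": sex,
                    "condition": cond,
                    "trial": t_i,
                    "mean_fix_dur_ms": rng.normal(mu_fix, w_fix / np.sqrt(m_fix)),
                }
                for ax in AXES:
                    mean_ax = max(cfg.head_excursion_mean_deg[ax][cond] + b_head[ax], 2.0)
                    w_ax = _within_sd(cfg.head_excursion_sd_deg[ax][cond], cfg.head_between_sd_deg[ax])
                    row[f"{ax}_exc_deg"] = float(_lognormal_mv(rng, mean_ax, w_ax))
                rows.append(row)
    return pd.DataFrame(rows)


def _match_events(true_ev: list, det_ev: list, kind: str):
    """Greedy one-to-one matching of same-kind events by mutual >= 50%
    temporal overlap; returns (tp, fn, fp)."""
    trues = [e for e in true_ev if e.kind == kind]
    dets = [e for e in det_ev if e.kind == kind]
    used = [False] * len(dets)
    tp = 0
    for te in trues:
        best, best_i = 0.0, -1
        for i, de in enumerate(dets):
            if used[i]:
                continue
            inter = min(te.offset_ms, de.offset_ms) - max(te.onset_ms, de.onset_ms)
            if inter <= 0:
                continue
            if inter >= 0.5 * te.duration_ms and inter >= 0.5 * de.duration_ms and inter > best:
                best, best_i = inter, i
        if best_i >= 0:
            used[best_i] = True
            tp += 1
    return tp, len(trues) - tp, sum(1 for u in used if not u)


def recovery_report(
    study: SyntheticStudy,
    detected_events: dict,
    head_metrics: pd.DataFrame | None = None,
) -> dict:
    """Compare pipeline output against the generating truth.

    Returns fixation/saccade F1, the relative bias of the mean detected
    fixation duration, and (when head metrics are supplied) per-axis mean
    relative excursion error plus a per-condition effect-recovery table.
    """
    gt = study.ground_truth
    keys = set(detected_events)
    truth_keys = {
        (r.participant_id, r.condition, r.video_id)
        for r in study.manifest.itertuples(index=False)
    }
    if keys - truth_keys:
        raise DataError("detected events contain trial keys absent from the study")

    tp_f = fn_f = fp_f = tp_s = fn_s = fp_s = 0
    true_durs, det_durs = [], []
    for key in keys:
        true_ev = gt.events_for(key)
        det_ev = detected_events[key]
        a, b, c = _match_events(true_ev, det_ev, "fixation")
        tp_f, fn_f, fp_f = tp_f + a, fn_f + b, fp_f + c
        a, b, c = _match_events(true_ev, det_ev, "saccade")
        tp_s, fn_s, fp_s = tp_s + a, fn_s + b, fp_s + c
        true_durs.extend(e.duration_ms for e in true_ev if e.kind == "fixation")
        det_durs.extend(e.duration_ms for e in det_ev if e.kind == "fixation")

    def f1(tp, fn, fp):
        return 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) else 0.0

    report = {
        "fixation_f1": f1(tp_f, fn_f, fp_f),
        "saccade_f1": f1(tp_s, fn_s, fp_s),
        "fixation_duration_bias": (
            (np.mean(det_durs) - np.mean(true_durs)) / np.mean(true_durs)
            if det_durs and true_durs
            else np.nan
        ),
    }

    if head_metrics is not None:
        merged = head_metrics.merge(
            gt.excursions,
            on=["participant_id", "condition", "video_id"],
            suffixes=("", "_true"),
        )
        for ax in AXES:
            est = merged[f"{ax}_exc_deg"]
            true = merged[f"{ax}_exc_deg_true"]
            report[f"{ax}_excursion_rel_error"] = float(np.mean(np.abs(est - true) / true))
        report["condition_means"] = (
            merged.groupby("condition")[[f"{ax}_exc_deg" for ax in AXES]].mean().to_dict()
        )
    return report


def _streams_to_frame(streams: dict, kind: str) -> pd.DataFrame:
    frames = []
    for (pid, cond, vid), s in streams.items():
        base = {"participant_id": pid, "condition": cond, "video_id": vid}
        if kind == "gaze":
            df = pd.DataFrame(
                {
                    **base,
                    "t_ms": s.t_ms,
                    "dir_x": s.dirs[:, 0],
                    "dir_y": s.dirs[:, 1],
                    "dir_z": s.dirs[:, 2],
                    "valid": s.valid.astype(int),
                }
            )
        else:
            df = pd.DataFrame(
                {
                    **base,
                    "t_ms": s.t_ms,
                    "qw": s.quat[:, 0],
                    "qx": s.quat[:, 1],
                    "qy": s.quat[:, 2],
                    "qz": s.quat[:, 3],
                }
            )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write a generated study to disk in the CSV dialects the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.manifest.to_csv(out / "manifest.csv", index=False)
    _streams_to_frame(study.gaze, "gaze").to_csv(out / "gaze.csv", index=False)
    _streams_to_frame(study.head, "head").to_csv(out / "head.csv", index=False)
    study.simtlx.to_csv(out / "simtlx.csv", index=False)
    study.heart_rate.to_csv(out / "heart_rate.csv", index=False)
    study.ground_truth.events.to_csv(out / "ground_truth_events.csv", index=False)
    study.ground_truth.excursions.to_csv(out / "ground_truth_excursions.csv", index=False)
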