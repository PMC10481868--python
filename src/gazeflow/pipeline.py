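"""End-to-end orchestration: streams → events → metrics → models → report.

A run consumes either an on-disk session directory (manifest.csv, gaze.csv,
head.csv, simtlx.csv, heart_rate.csv) or a synthetic study generated in
memory, and produces per-trial metrics, per-condition summaries, one mixed
model per dependent variable (4 gaze + 3 head metrics at trial grain, 10
SIM-TLX items and heart rate at participant grain), and Tukey post-hoc
contrasts for models whose condition term is significant. Each model is
tested item-wise at alpha; a Holm-adjusted column is included for
transparency but is not the headline inference.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import session_io
from .errors import GazeflowError
from .gaze_events import EventDetectionParams, detect_events, gaze_trial_metrics
from .head_kinematics import ExcursionParams, head_trial_metrics
from .mixed_models import ModelSpec, fit_lmm, holm_adjust, tukey_posthoc
from .synthetic import GeneratorConfig, SyntheticStudy, generate_study
from .workload import SIMTLX_ITEMS, condition_summaries, records_to_frame, validate_simtlx

__version__ = "0.1.0"

logger = logging.getLogger("gazeflow")

GAZE_METRICS = ("n_fixations_norm", "mean_fix_dur_ms", "n_saccades_norm", "search_rate")
HEAD_METRICS = ("roll_exc_deg", "pitch_exc_deg", "yaw_exc_deg")


@dataclass
class RunReport:
    """Everything a run produced, plus provenance to reproduce it."""

    metrics: pd.DataFrame
    events: pd.DataFrame
    condition_means: pd.DataFrame
    estimates: pd.DataFrame
    posthoc: pd.DataFrame
    provenance: dict

    def summary_dict(self) -> dict:
        cond_means = [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in rec.items()}
            for rec in self.condition_means.to_dict(orient="records")
        ]
        return {
            "provenance": self.provenance,
            "condition_means": cond_means,
            "condition_effects": self.estimates[
                self.estimates["term"].str.fullmatch(r"condition\[[^]]+\]")
            ].to_dict(orient="records"),
        }


def _sanitize(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        o = dataclasses.asdict(o)
    if isinstance(o, dict):
        return {str(k): _sanitize(v) for k, v in o.items()}
    if isinstance(o, (list, tuple, set)):
        return [_sanitize(v) for v in o]
    if isinstance(o, (str, int, float, bool)) or o is None:
        return o
    return str(o)


def _config_hash(obj) -> str:
    payload = json.dumps(_sanitize(obj), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_study(data_dir: Path) -> SyntheticStudy:
    manifest = session_io.read_manifest(data_dir / "manifest.csv")
    gaze = session_io.read_gaze_log(data_dir / "gaze.csv", manifest)
    head = session_io.read_head_log(data_dir / "head.csv", manifest)
    simtlx = session_io.read_simtlx(data_dir / "simtlx.csv")
    hr = session_io.read_heart_rate(data_dir / "heart_rate.csv")
    return SyntheticStudy(
        manifest=manifest, gaze=gaze, head=head, simtlx=simtlx, heart_rate=hr, ground_truth=None
    )


def compute_trial_tables(
    study: SyntheticStudy,
    detection: EventDetectionParams = EventDetectionParams(),
    excursion: ExcursionParams = ExcursionParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Stage 2: event detection + per-trial metrics for every trial.

    Returns (metrics table, long event table, detected events per trial key).
    """
    metric_rows = []
    event_rows = []
    detected = {}
    for rec in study.manifest.itertuples(index=False):
        key = (rec.participant_id, rec.condition, rec.video_id)
        try:
            events, thr = detect_events(study.gaze[key], detection)
            hm = head_trial_metrics(study.head[key], rec.duration_ms, excursion)
        except KeyError as exc:
            raise GazeflowError(f"stage events: missing stream for trial {key}") from exc
        except GazeflowError as exc:
            raise GazeflowError(f"stage events: trial {key}: {exc}") from exc
        detected[key] = events
        gm = gaze_trial_metrics(events, rec.duration_ms, detection.ref_duration_ms)
        metric_rows.append(
            {
                "participant_id": rec.participant_id,
                "condition": rec.condition,
                "video_id": rec.video_id,
                "sex": rec.sex,
                "punch_type": rec.punch_type,
                "duration_ms": rec.duration_ms,
                "n_fixations_norm": gm.n_fixations_norm,
                "mean_fix_dur_ms": gm.mean_fix_dur_ms,
                "n_saccades_norm": gm.n_saccades_norm,
                "search_rate": gm.search_rate,
                "roll_exc_deg": hm.roll_exc_deg,
                "pitch_exc_deg": hm.pitch_exc_deg,
                "yaw_exc_deg": hm.yaw_exc_deg,
            }
        )
        for e in events:
            event_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "condition": rec.condition,
                    "video_id": rec.video_id,
                    "kind": e.kind,
                    "onset_ms": e.onset_ms,
                    "offset_ms": e.offset_ms,
                    "peak_v_deg_s": e.peak_v_deg_s,
                }
            )
    return pd.DataFrame(metric_rows), pd.DataFrame(event_rows), detected


def _fit_family(metrics: pd.DataFrame, simtlx_wide: pd.DataFrame, hr: pd.DataFrame, alpha: float):
    """Stage 4: one mixed model per dependent variable."""
    estimates = []
    posthoc_rows = []
    fits = {}

    def run_model(frame: pd.DataFrame, response: str, grain: str):
        spec = ModelSpec(response=response, alpha=alpha)
        fit = fit_lmm(frame, spec)
        fits[response] = fit
        for est in fit.estimates:
            estimates.append({"response": response, "grain": grain, **est.__dict__})
        cond_term = next(
            e for e in fit.estimates if e.term.startswith("condition[") and ":" not in e.term
        )
        if cond_term.p < alpha:
            ph = tukey_posthoc(fit, "condition")
            ph.insert(0, "response", response)
            posthoc_rows.append(ph)

    for m in GAZE_METRICS + HEAD_METRICS:
        run_model(metrics, m, "trial")
        logger.info("fitted trial-grain model for %s (n=%d rows)", m, len(metrics))
    for item in SIMTLX_ITEMS:
        run_model(simtlx_wide, item, "participant")
    run_model(hr, "mean_bpm", "participant")

    est_df = pd.DataFrame(estimates)
    cond_mask = est_df["term"].str.fullmatch(r"condition\[[^]]+\]")
    est_df["p_holm"] = np.nan
    est_df.loc[cond_mask, "p_holm"] = holm_adjust(est_df.loc[cond_mask, "p"].to_numpy())
    post_df = (
        pd.concat(posthoc_rows, ignore_index=True)
        if posthoc_rows
        else pd.DataFrame(columns=["response", "contrast", "estimate", "se", "df", "p_adj"])
    )
    return est_df, post_df, fits


def run_pipeline(
    *,
    data_dir: str | Path | None = None,
    synth_config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    detection: EventDetectionParams = EventDetectionParams(),
    excursion: ExcursionParams = ExcursionParams(),
    alpha: float = 0.05,
) -> RunReport:
    """Run the full chain and optionally write the results bundle.

    Exactly one of ``data_dir`` (a session directory on disk) or
    ``synth_config`` (generate a synthetic study with ``seed``) must be
    provided. With ``out_dir`` set, writes events.csv, metrics.csv,
    estimates.csv, posthoc.csv, condition_means.csv and summary.json.
    """
    if (data_dir is None) == (synth_config is None):
        raise GazeflowError("provide exactly one of data_dir or synth_config")
    if data_dir is not None:
        study = _load_study(Path(data_dir))
        source = str(data_dir)
    else:
        study = generate_study(synth_config, seed)
        source = "synthetic"
    logger.info("stage load: %d trials", len(study.manifest))

    metrics, events, _ = compute_trial_tables(study, detection, excursion)
    logger.info("stage metrics: %d rows", len(metrics))

    records = validate_simtlx(study.simtlx)
    simtlx_wide = records_to_frame(records)
    sex_map = study.manifest.drop_duplicates("participant_id").set_index("participant_id")["sex"]
    simtlx_wide["sex"] = simtlx_wide["participant_id"].map(sex_map)
    hr = study.heart_rate.copy()
    hr["sex"] = hr["participant_id"].map(sex_map)

    metric_cols = list(GAZE_METRICS + HEAD_METRICS)
    cond_means = (
        metrics.groupby("condition")[metric_cols].agg(["mean", "std"]).round(6)
    )
    cond_means.columns = [f"{m}_{s}" for m, s in cond_means.columns]
    cond_means = cond_means.reset_index()
    simtlx_summary = condition_summaries(records)

    est_df, post_df, _fits = _fit_family(metrics, simtlx_wide, hr, alpha)
    logger.info("stage models: %d estimates", len(est_df))

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "source": source,
        "config_hash": _config_hash(
            {
                "detection": detection,
                "excursion": excursion,
                "synth": synth_config,
                "alpha": alpha,
            }
        ),
    }
    report = RunReport(
        metrics=metrics,
        events=events,
        condition_means=cond_means,
        estimates=est_df,
        posthoc=post_df,
        provenance=provenance,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        session_io.write_metrics_table(out / "metrics.csv", metrics)
        events.to_csv(out / "events.csv", index=False)
        est_df.to_csv(out / "estimates.csv", index=False)
        post_df.to_csv(out / "posthoc.csv", index=False)
        cond_means.to_csv(out / "condition_means.csv", index=False)
        simtlx_summary.to_csv(out / "simtlx_summary.csv", index=False)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
    return report
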