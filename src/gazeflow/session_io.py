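"""Readers and writers for the on-disk study artifacts.

Everything is long-format CSV (UTF-8, "." decimal separator): one gaze file
and one head file per session keyed by participant/condition/video columns, a
trial manifest, a SIM-TLX table, a heart-rate table, and the per-trial
metrics output. A column-mapping dict lets the readers adapt to externally
produced logs whose headers differ from the defaults.

Readers validate into the domain containers and never silently drop samples:
rows with non-finite or degenerate gaze directions are kept and flagged
invalid so downstream gap handling sees them. Timestamps are converted to
trial-relative milliseconds (first sample → 0) on read.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ValidationError
from .types import PUNCH_TYPES, Condition, GazeStream, HeadStream, Sex, TrialKey

__all__ = [
    "GAZE_COLUMNS",
    "HEAD_COLUMNS",
    "METRIC_COLUMNS",
    "read_manifest",
    "write_manifest",
    "read_gaze_log",
    "read_head_log",
    "read_simtlx",
    "read_heart_rate",
    "read_metrics_table",
    "write_metrics_table",
    "load_yaml_config",
]

KEY_COLUMNS = ["participant_id", "condition", "video_id"]
GAZE_COLUMNS = KEY_COLUMNS + ["t_ms", "dir_x", "dir_y", "dir_z", "valid"]
HEAD_COLUMNS = KEY_COLUMNS + ["t_ms", "qw", "qx", "qy", "qz"]
HEAD_EULER_COLUMNS = KEY_COLUMNS + ["t_ms", "yaw_deg", "pitch_deg", "roll_deg"]
MANIFEST_COLUMNS = [
    "participant_id",
    "sex",
    "condition",
    "punch_type",
    "video_id",
    "duration_ms",
    "order_first_condition",
]
METRIC_COLUMNS = KEY_COLUMNS + [
    "sex",
    "punch_type",
    "duration_ms",
    "n_fixations_norm",
    "mean_fix_dur_ms",
    "n_saccades_norm",
    "search_rate",
    "roll_exc_deg",
    "pitch_exc_deg",
    "yaw_exc_deg",
]

_QUAT_NORM_TOL = 1e-2


def _read_csv(path: str | Path, required: Iterable[str], column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the trial manifest."""
    df = _read_csv(path, [c for c in MANIFEST_COLUMNS if c != "order_first_condition"])
    conditions = {c.value for c in Condition}
    sexes = {s.value for s in Sex}
    bad_cond = set(df["condition"].unique()) - conditions
    if bad_cond:
        raise ValidationError(f"manifest: unknown condition value(s): {sorted(bad_cond)}")
    bad_sex = set(df["sex"].unique()) - sexes
    if bad_sex:
        raise ValidationError(f"manifest: unknown sex value(s): {sorted(bad_sex)}")
    bad_punch = set(df["punch_type"].unique()) - set(PUNCH_TYPES)
    if bad_punch:
        raise ValidationError(f"manifest: unknown punch type(s): {sorted(bad_punch)}")
    if (df["duration_ms"] <= 0).any():
        bad = df.loc[df["duration_ms"] <= 0, "video_id"].iloc[0]
        raise ValidationError(f"manifest: non-positive duration for video {bad}")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        raise ValidationError("manifest: duplicate (participant, condition, video) rows")
    return df.reset_index(drop=True)


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def _iter_trials(df: pd.DataFrame, name: str):
    for key, g in df.groupby(KEY_COLUMNS, sort=False):
        t = g["t_ms"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DataError(f"{name}: non-monotonic timestamps in trial {key}")
        yield tuple(map(str, key)), g, t - t[0]


def read_gaze_log(
    path: str | Path,
    manifest: pd.DataFrame | None = None,
    column_map: Mapping[str, str] | None = None,
) -> dict[TrialKey, GazeStream]:
    """Read a long-format gaze log into per-trial :class:`GazeStream` objects.

    Directions are re-normalized to unit length; rows whose direction is
    non-finite or too short to normalize are retained with ``valid=False``.
    An explicit ``valid`` column, if present, is ANDed in.
    """
    df = _read_csv(path, [c for c in GAZE_COLUMNS if c != "valid"], column_map)
    streams: dict[TrialKey, GazeStream] = {}
    for key, g, t in _iter_trials(df, "gaze log"):
        dirs = g[["dir_x", "dir_y", "dir_z"]].to_numpy(dtype=float)
        valid = np.ones(len(g), dtype=bool)
        if "valid" in g.columns:
            valid &= g["valid"].astype(bool).to_numpy()
        finite = np.isfinite(dirs).all(axis=1)
        norms = np.where(finite, np.linalg.norm(np.nan_to_num(dirs), axis=1), 0.0)
        usable = finite & (norms > 1e-8)
        valid &= usable
        dirs = np.where(usable[:, None], dirs / np.where(usable, norms, 1.0)[:, None], 0.0)
        streams[key] = GazeStream(t_ms=t, dirs=dirs, valid=valid)
    if manifest is not None:
        _check_keys(streams, manifest, "gaze log")
    return streams


def read_head_log(
    path: str | Path,
    manifest: pd.DataFrame | None = None,
    column_map: Mapping[str, str] | None = None,
) -> dict[TrialKey, HeadStream]:
    """Read a head-orientation log into per-trial :class:`HeadStream` objects.

    Accepts either scalar-first quaternion columns (qw..qz, renormalized;
    norms further than 1e-2 from 1 are a data error) or Euler columns
    (yaw/pitch/roll in degrees), converted with the package's fixed intrinsic
    yaw→pitch→roll convention.
    """
    df = _read_csv(path, KEY_COLUMNS + ["t_ms"], column_map)
    has_quat = all(c in df.columns for c in ("qw", "qx", "qy", "qz"))
    has_euler = all(c in df.columns for c in ("yaw_deg", "pitch_deg", "roll_deg"))
    if not (has_quat or has_euler):
        raise FormatError("head log: need quaternion columns qw,qx,qy,qz or Euler columns yaw_deg,pitch_deg,roll_deg")
    streams: dict[TrialKey, HeadStream] = {}
    for key, g, t in _iter_trials(df, "head log"):
        if has_quat:
            q = g[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
            if not np.isfinite(q).all():
                raise DataError(f"head log: non-finite quaternion in trial {key}")
            norms = np.linalg.norm(q, axis=1)
            if np.any(np.abs(norms - 1.0) > _QUAT_NORM_TOL):
                raise DataError(f"head log: quaternion norm outside 1±{_QUAT_NORM_TOL} in trial {key}")
            q = q / norms[:, None]
        else:
            from .head_kinematics import euler_to_quat

            ang = g[["yaw_deg", "pitch_deg", "roll_deg"]].to_numpy(dtype=float)
            if not np.isfinite(ang).all():
                raise DataError(f"head log: non-finite Euler angle in trial {key}")
            q = euler_to_quat(ang[:, 0], ang[:, 1], ang[:, 2])
        streams[key] = HeadStream(t_ms=t, quat=q)
    if manifest is not None:
        _check_keys(streams, manifest, "head log")
    return streams


def _check_keys(streams: dict, manifest: pd.DataFrame, name: str) -> None:
    expected = {tuple(map(str, k)) for k in manifest[KEY_COLUMNS].itertuples(index=False)}
    extra = set(streams) - expected
    if extra:
        raise DataError(f"{name}: trial keys absent from manifest: {sorted(extra)[:3]}...")


def read_simtlx(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the long-format SIM-TLX table (participant_id, condition, item, score)."""
    return _read_csv(path, ["participant_id", "condition", "item", "score"], column_map)


def read_heart_rate(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the per-participant per-condition mean heart-rate table."""
    df = _read_csv(path, ["participant_id", "condition", "mean_bpm"], column_map)
    bad = ~df["mean_bpm"].between(30, 220, inclusive="neither")
    if bad.any():
        who = df.loc[bad, "participant_id"].iloc[0]
        raise ValidationError(f"heart rate: implausible mean_bpm for participant {who}")
    return df


def write_metrics_table(path: str | Path, rows: pd.DataFrame) -> None:
    """Write the per-trial metrics table; NaN (e.g. undefined search rate) is
    serialized as an empty field and survives the round trip."""
    if len(rows) == 0:
        raise ValidationError("refusing to write an empty metrics table")
    missing = [c for c in METRIC_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"metrics table: missing column(s): {', '.join(missing)}")
    rows.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, METRIC_COLUMNS)


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML parameter file into a plain dict (empty file → {})."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"config {path}: expected a mapping at top level")
    return data
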