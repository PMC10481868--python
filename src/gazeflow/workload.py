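"""SIM-TLX workload questionnaire validation and summaries.

The SIM-TLX asks for ten ratings after each viewing condition, each marked on
a 0–20 visual-analogue scale: mental demand, physical demand, temporal
demand, frustration, task complexity, situational stress, distraction,
perceptual constraints, task performance, and sense of presence. The ten
items are analyzed separately (no composite index, no pairwise weighting).
Mean heart rate per participant and condition is carried along as a control
variable for exercise intensity.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "SIMTLX_ITEMS",
    "SimTlxRecord",
    "validate_simtlx",
    "records_to_frame",
    "condition_summaries",
    "heart_rate_summaries",
]

SIMTLX_ITEMS = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "frustration",
    "task_complexity",
    "situational_stress",
    "distraction",
    "perceptual_constraints",
    "task_performance",
    "sense_of_presence",
)

SCALE_MIN, SCALE_MAX = 0.0, 20.0


@dataclass(frozen=True)
class SimTlxRecord:
    """One participant's complete questionnaire for one condition."""

    participant_id: str
    condition: str
    scores: dict  # item name -> score in [0, 20]


def validate_simtlx(rows: pd.DataFrame) -> list[SimTlxRecord]:
    """Validate long-format responses into one complete record per
    participant × condition.

    Raises :class:`ValidationError` naming the participant and item for any
    out-of-range score, unknown item, duplicate, or incomplete questionnaire.
    """
    required = {"participant_id", "condition", "item", "score"}
    missing = required - set(rows.columns)
    if missing:
        raise ValidationError(f"SIM-TLX table missing column(s): {', '.join(sorted(missing))}")
    records: list[SimTlxRecord] = []
    for (pid, cond), g in rows.groupby(["participant_id", "condition"], sort=False):
        scores: dict[str, float] = {}
        for item, score in zip(g["item"], g["score"]):
            if item not in SIMTLX_ITEMS:
                raise ValidationError(f"participant {pid} ({cond}): unknown SIM-TLX item {item!r}")
            if item in scores:
                raise ValidationError(f"participant {pid} ({cond}): duplicate item {item!r}")
            score = float(score)
            if not (SCALE_MIN <= score <= SCALE_MAX):
                raise ValidationError(
                    f"participant {pid} ({cond}): item {item!r} score {score} outside [0, 20]"
                )
            scores[item] = score
        absent = [it for it in SIMTLX_ITEMS if it not in scores]
        if absent:
            raise ValidationError(
                f"participant {pid} ({cond}): missing item(s) {', '.join(absent)}"
            )
        records.append(SimTlxRecord(str(pid), str(cond), scores))
    return records


def records_to_frame(records: list[SimTlxRecord]) -> pd.DataFrame:
    """Wide per-record frame: one row per participant × condition, one column per item."""
    return pd.DataFrame(
        [
            {"participant_id": r.participant_id, "condition": r.condition, **r.scores}
            for r in records
        ]
    )


def condition_summaries(records: list[SimTlxRecord]) -> pd.DataFrame:
    """Per-item arithmetic mean and sample SD (ddof=1) for each condition.

    Returns a frame indexed by (condition, item) with ``mean``, ``sd`` and
    ``n`` columns; invariant to the order of the input records.
    """
    if not records:
        raise ValidationError("no SIM-TLX records to summarize")
    wide = records_to_frame(records)
    long = wide.melt(
        id_vars=["participant_id", "condition"], var_name="item", value_name="score"
    )
    out = (
        long.groupby(["condition", "item"])["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def heart_rate_summaries(hr: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of per-participant mean heart rate per condition (and by sex
    when a ``sex`` column is present)."""
    keys = ["condition"] + (["sex"] if "sex" in hr.columns else [])
    return (
        hr.groupby(keys)["mean_bpm"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
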