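"""Time-based EMA prompting protocol: schedules, validity, compliance.

The protocol emulated here prompts participants 6 times per day inside
predefined one-hour frames between 09:00 and 22:00, for 7 consecutive
days (42 scheduled prompts per participant).  A prompt expires 20 minutes
after the trigger; reminders fire at +5 and +10 minutes and are metadata
only (the activity windows are anchored at the trigger).

Delivered triggers are validated the way a study team would clean them:
any trigger outside every predefined frame, and any trigger beyond the
sixth of a day, is flagged invalid and excluded downstream.  Participants
enter the analysis only if they answered at least one-third of their
scheduled prompts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_COLUMNS",
    "FrameSchedule",
    "build_frames",
    "draw_trigger",
    "validate_triggers",
    "compliance_threshold",
    "compliance_filter",
    "completion_rate",
    "mean_completed_per_participant",
    "protocol_descriptives",
    "read_ema_csv",
    "write_ema_csv",
]

#: CSV column names of the 7 analysed EMA items, in questionnaire order.
ITEM_COLUMNS = ["relax", "satisf", "irrit", "down", "fatigue", "intention", "selfeff"]

REMINDER_OFFSETS_MIN = (5.0, 10.0)
EXPIRY_MIN = 20.0


def _parse_clock(s: str) -> int:
    """'HH:MM' -> minutes after midnight."""
    h, m = s.split(":")
    return int(h) * 60 + int(m)


@dataclass(frozen=True)
class FrameSchedule:
    """Prompting frames for one day, as (start, end) minutes after midnight."""

    frames: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.frames:
            if end <= start:
                raise ValueError(f"empty frame ({start}, {end})")
            if start < prev_end:
                raise ValueError("frames overlap")
            prev_end = end

    def contains(self, minute_of_day: float) -> bool:
        return any(s <= minute_of_day < e for s, e in self.frames)


def build_frames(
    day_window=("09:00", "22:00"),
    n_frames: int = 6,
    frame_duration: int = 60,
) -> FrameSchedule:
    """Evenly spaced prompting frames spanning the day window.

    The first frame opens at the window start and the last closes at the
    window end; the remaining slack is split into equal gaps between
    consecutive frames (6 x 60 min in 09:00-22:00 gives 84-min gaps,
    i.e. frame starts every 144 min).  An explicit frame list can be
    passed straight to :class:`FrameSchedule` instead.
    """
    w0, w1 = (_parse_clock(s) if isinstance(s, str) else int(s) for s in day_window)
    total = w1 - w0
    if n_frames < 1 or n_frames * frame_duration > total:
        raise ValueError(
            f"{n_frames} frames of {frame_duration} min do not fit in a "
            f"{total}-min day window"
        )
    if n_frames == 1:
        starts = [w0]
    else:
        gap = (total - n_frames * frame_duration) / (n_frames - 1)
        starts = [w0 + i * (frame_duration + gap) for i in range(n_frames)]
    frames = tuple((float(s), float(s + frame_duration)) for s in starts)
    return FrameSchedule(frames)


def draw_trigger(frame, day: pd.Timestamp, rng: np.random.Generator) -> dict:
    """Draw one trigger uniformly inside a frame of a given day.

    Returns trigger, reminder and expiry timestamps (reminders at +5 and
    +10 min, expiry at +20 min after the trigger).
    """
    start, end = frame
    minute = rng.uniform(start, end)
    day = pd.Timestamp(day).normalize()
    trigger = day + pd.to_timedelta(minute, unit="m")
    return {
        "trigger_time": trigger,
        "reminder1": trigger + pd.Timedelta(minutes=REMINDER_OFFSETS_MIN[0]),
        "reminder2": trigger + pd.Timedelta(minutes=REMINDER_OFFSETS_MIN[1]),
        "expiry_time": trigger + pd.Timedelta(minutes=EXPIRY_MIN),
    }


def validate_triggers(
    prompts: pd.DataFrame,
    schedule: FrameSchedule,
    max_per_day: int = 6,
) -> pd.DataFrame:
    """Flag technically faulty triggers as invalid.

    A trigger is invalid if it lies outside every predefined frame (e.g.
    a night-time delivery) or if it is the (max_per_day+1)-th or later
    trigger of its participant-day in time order.  Returns a copy with
    status set to ``invalid`` for flagged rows.
    """
    out = prompts.copy()
    tt = pd.to_datetime(out["trigger_time"])
    minute_of_day = tt.dt.hour * 60 + tt.dt.minute + tt.dt.second / 60.0
    outside = ~minute_of_day.map(schedule.contains)

    order = tt.groupby(
        [out["participant_id"], tt.dt.normalize()], sort=False
    ).rank(method="first")
    excess = order > max_per_day

    out.loc[outside | excess, "status"] = "invalid"
    return out


def compliance_threshold(min_fraction: float = 1 / 3, scheduled: int = 42) -> int:
    """Minimum completed prompts to retain a participant (ceil of fraction)."""
    return math.ceil(min_fraction * scheduled)


def compliance_filter(
    completed_per_participant: pd.Series,
    min_fraction: float = 1 / 3,
    scheduled: int = 42,
) -> pd.Index:
    """Participants retained: completed >= ceil(min_fraction * scheduled)."""
    threshold = compliance_threshold(min_fraction, scheduled)
    keep = completed_per_participant >= threshold
    return completed_per_participant.index[keep]


def completion_rate(completed: int, valid_delivered: int) -> float:
    """Completion rate in percent, rounded to 2 decimals (e.g. 77.33)."""
    if valid_delivered == 0:
        raise ZeroDivisionError("no valid prompts delivered; rate undefined")
    return round(100.0 * completed / valid_delivered, 2)


def mean_completed_per_participant(completed: int, n_participants: int) -> float:
    """Mean completed questionnaires per participant, rounded to 1 decimal."""
    return round(completed / n_participants, 1)


def _quartiles(x: pd.Series) -> dict:
    x = x.dropna()
    if x.empty:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    return {
        "median": float(x.median()),
        "q1": float(x.quantile(0.25)),
        "q3": float(x.quantile(0.75)),
    }


def protocol_descriptives(prompts: pd.DataFrame) -> dict:
    """Protocol summary over validated prompts.

    Counts delivered/valid/completed prompts, the completion rate (% of
    valid triggers answered), mean completed per participant, and the
    median and quartiles of response latency and completion duration.
    """
    n_delivered = len(prompts)
    valid = prompts[prompts["status"] != "invalid"]
    completed = valid[valid["status"] == "completed"]
    n_valid = len(valid)
    n_completed = len(completed)
    n_participants = prompts["participant_id"].nunique()
    summary = {
        "n_delivered": n_delivered,
        "n_invalid": n_delivered - n_valid,
        "n_valid": n_valid,
        "n_completed": n_completed,
        "completion_rate_pct": completion_rate(n_completed, n_valid),
        "mean_completed_per_participant": mean_completed_per_participant(
            n_completed, n_participants
        ),
    }
    if "latency_min" in completed.columns:
        summary["latency_min"] = _quartiles(completed["latency_min"])
    if "completion_duration_min" in completed.columns:
        summary["completion_duration_min"] = _quartiles(
            completed["completion_duration_min"]
        )
    return summary


def read_ema_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["trigger_time"])
    required = {"participant_id", "trigger_time", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EMA CSV missing columns: {sorted(missing)}")
    return df


def write_ema_csv(prompts: pd.DataFrame, path) -> None:
    prompts.to_csv(path, index=False)
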