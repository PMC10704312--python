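"""Join answered EMA prompts to subsequent minute-level activity.

Each completed prompt is linked to the classified accelerometer minutes
in the 15, 30, 60 and 120 minutes after its trigger.  The window starts
at the first full minute boundary strictly after the trigger (the
trigger's own partially elapsed minute is excluded), and per window the
LPA, MVPA and TPA (= LPA + MVPA) minute counts, their dichotomised
any-activity flags, and the fraction of non-missing minutes (coverage)
are recorded.  Windows with coverage below ``coverage_min`` (default:
complete coverage required) have their outcomes set missing; no
imputation is performed.  Overlapping windows of consecutive prompts are
kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import accelerometry as acc

__all__ = [
    "DEFAULT_WINDOWS",
    "window_start",
    "extract_window",
    "dichotomize",
    "build_dataset",
    "pa_descriptives",
]

DEFAULT_WINDOWS = (15, 30, 60, 120)


def window_start(trigger_time) -> pd.Timestamp:
    """First minute boundary strictly after the trigger."""
    return pd.Timestamp(trigger_time).floor("min") + pd.Timedelta(minutes=1)


def dichotomize(count):
    """0 vs at least 1 minute of activity; NaN propagates."""
    arr = np.asarray(count, dtype=float)
    out = np.where(np.isnan(arr), np.nan, (arr >= 1).astype(float))
    if arr.ndim == 0:
        return float(out[()])
    return out


class _ParticipantMinutes:
    """Sorted per-participant minute lookup for fast window extraction."""

    def __init__(self, minutes: pd.DataFrame):
        ts = pd.to_datetime(minutes["minute_start"]).to_numpy()
        order = np.argsort(ts)
        self.ts = ts[order].astype("datetime64[m]").astype(np.int64)
        intensity = minutes["intensity"].to_numpy()[order]
        self.is_lpa = intensity == acc.LPA
        self.is_mvpa = intensity == acc.MVPA
        self.present = intensity != acc.MISSING

    def counts(self, trigger_time, duration):
        start = window_start(trigger_time)
        s = np.datetime64(start, "m").astype(np.int64)
        lo = np.searchsorted(self.ts, s, side="left")
        hi = np.searchsorted(self.ts, s + duration, side="left")
        sl = slice(lo, hi)
        covered = int(self.present[sl].sum())
        return {
            "lpa": int(self.is_lpa[sl].sum()),
            "mvpa": int(self.is_mvpa[sl].sum()),
            "coverage": covered / duration,
        }


def extract_window(minutes: pd.DataFrame, trigger_time, duration: int) -> dict:
    """LPA/MVPA counts and coverage in the ``duration`` minutes after a trigger.

    ``minutes`` is a classified minute series for one participant.  A
    trigger entirely outside the wear period simply yields zero coverage.
    """
    return _ParticipantMinutes(minutes).counts(trigger_time, duration)


def build_dataset(
    responses: pd.DataFrame,
    minutes: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    coverage_min: float = 1.0,
) -> pd.DataFrame:
    """One linked-observation row per completed EMA response.

    Outcome columns ``lpa_d``, ``mvpa_d``, ``tpa_d``, ``any_*_d`` and
    ``coverage_d`` per window length ``d``; outcomes are NaN where
    coverage < ``coverage_min``.  Raises if the EMA file names
    participants absent from the minute file.
    """
    completed = responses[responses["status"] == "completed"].reset_index(drop=True)
    ema_pids = set(completed["participant_id"])
    acc_pids = set(minutes["participant_id"])
    orphans = sorted(ema_pids - acc_pids)
    if orphans:
        raise ValueError(
            f"participants in EMA data without accelerometer data: {orphans}")

    lookups = {
        pid: _ParticipantMinutes(grp)
        for pid, grp in minutes.groupby("participant_id", sort=False)
        if pid in ema_pids
    }
    item_cols = [c for c in responses.columns
                 if c not in ("participant_id", "trigger_time", "status",
                              "latency_min", "completion_duration_min", "day",
                              "frame_index", "reminder1", "reminder2",
                              "expiry_time")]
    out = completed[["participant_id", "trigger_time"] + item_cols].copy()
    for d in windows:
        res = [lookups[pid].counts(t, d)
               for pid, t in zip(completed["participant_id"],
                                 completed["trigger_time"])]
        cov = np.array([r["coverage"] for r in res])
        lpa = np.array([r["lpa"] for r in res], dtype=float)
        mvpa = np.array([r["mvpa"] for r in res], dtype=float)
        ok = cov >= coverage_min
        lpa[~ok] = np.nan
        mvpa[~ok] = np.nan
        out[f"lpa_{d}"] = lpa
        out[f"mvpa_{d}"] = mvpa
        out[f"tpa_{d}"] = lpa + mvpa
        for intensity in ("lpa", "mvpa", "tpa"):
            out[f"any_{intensity}_{d}"] = dichotomize(out[f"{intensity}_{d}"])
        out[f"coverage_{d}"] = cov
    return out


def pa_descriptives(dataset: pd.DataFrame, window: int, intensity: str) -> dict:
    """Descriptive summary of one activity outcome: the familiar
    mean (SD) / median (range) / Q1-Q3 / %-zero row."""
    col = f"{intensity}_{window}"
    x = dataset[col].dropna()
    if x.empty:
        raise ValueError(f"no non-missing observations for {col}")
    return {
        "window": window,
        "intensity": intensity,
        "n": int(len(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "median": float(x.median()),
        "min": float(x.min()),
        "max": float(x.max()),
        "q1": float(x.quantile(0.25)),
        "q3": float(x.quantile(0.75)),
        "pct_zero": float(100.0 * (x == 0).mean()),
    }
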