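"""Raw wrist-accelerometer signal to per-minute ENMO and intensity classes.

The processing chain mirrors the common wrist-accelerometry convention for
older adults: per-sample Euclidean-norm-minus-one (ENMO, in mg, negative
values clamped to zero), averaged over 1-second epochs and then 1-minute
epochs, and each minute classified as sedentary, light (LPA) or
moderate-to-vigorous (MVPA) activity with the Sanders cut points
(sedentary <= 57 mg, MVPA >= 104 mg, LPA in between).

Epochs are aligned to wall-clock boundaries so that minutes can be joined
deterministically to EMA prompt timestamps. Minutes with no samples are
*missing*, never zero; no non-wear detection is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SED",
    "LPA",
    "MVPA",
    "MISSING",
    "CutPoints",
    "compute_enmo",
    "aggregate_samples",
    "aggregate_epochs",
    "classify_minute",
    "process_raw",
    "read_raw_csv",
    "read_minute_csv",
    "write_minute_csv",
]

SED = "SED"
LPA = "LPA"
MVPA = "MVPA"
MISSING = "MISSING"


@dataclass(frozen=True)
class CutPoints:
    """ENMO thresholds (mg) mapping a minute to an intensity class.

    Boundary ties follow the explicit inequalities of the cut-point
    definition: exactly 57 mg is sedentary, exactly 104 mg is MVPA.
    """

    sedentary_max: float = 57.0
    mvpa_min: float = 104.0

    def __post_init__(self) -> None:
        if not (0 < self.sedentary_max < self.mvpa_min):
            raise ValueError(
                f"require 0 < sedentary_max < mvpa_min, "
                f"got {self.sedentary_max} and {self.mvpa_min}"
            )


def compute_enmo(x, y, z):
    """Per-sample ENMO in mg: ``max(0, sqrt(x^2+y^2+z^2) - 1) * 1000``.

    Inputs are triaxial accelerations in gravitational units (g).
    Non-finite samples are rejected with the offending record index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    bad = ~(np.isfinite(x) & np.isfinite(y) & np.isfinite(z))
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite accelerometer sample at record {idx}")
    norm = np.sqrt(x * x + y * y + z * z)
    return np.maximum(norm - 1.0, 0.0) * 1000.0


def _floor_to_epoch(ts: pd.Series, epoch_s: int) -> pd.Series:
    return ts.dt.floor(f"{epoch_s}s")


def aggregate_samples(
    timestamps: pd.Series, values: np.ndarray, epoch_seconds: int
) -> pd.DataFrame:
    """Mean of per-sample values within clock-aligned epochs.

    Epochs containing no samples are simply absent from the output (they
    are missing, not zero).  Returns columns ``epoch_start`` and ``enmo_mg``.
    """
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)).reset_index(drop=True))
    vals = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    epoch = _floor_to_epoch(ts, epoch_seconds)
    out = vals.groupby(epoch, sort=True).mean()
    return pd.DataFrame({"epoch_start": out.index, "enmo_mg": out.to_numpy()})


def aggregate_epochs(
    epochs: pd.DataFrame, source_seconds: int, target_seconds: int
) -> pd.DataFrame:
    """Aggregate a finer epoch series (e.g. 1 s) to a coarser one (e.g. 60 s).

    The mean is taken over the source epochs contained in each target epoch.
    Source epochs must be clock-aligned, unique and finer than the target.
    """
    if target_seconds % source_seconds != 0 or target_seconds <= source_seconds:
        raise ValueError(
            f"target epoch ({target_seconds}s) must be a strict multiple "
            f"of source epoch ({source_seconds}s)"
        )
    ts = pd.to_datetime(epochs["epoch_start"])
    if ts.duplicated().any():
        raise ValueError("overlapping source epochs (duplicate epoch_start)")
    aligned = ts == ts.dt.floor(f"{source_seconds}s")
    if not aligned.all():
        idx = int(np.flatnonzero(~aligned.to_numpy())[0])
        raise ValueError(f"source epoch {idx} not aligned to {source_seconds}s boundary")
    target = ts.dt.floor(f"{target_seconds}s")
    out = epochs["enmo_mg"].astype(float).groupby(target.to_numpy(), sort=True).mean()
    return pd.DataFrame({"epoch_start": out.index, "enmo_mg": out.to_numpy()})


def classify_minute(enmo_mg, cuts: CutPoints = CutPoints()):
    """Map minute ENMO (mg) to SED / LPA / MVPA; NaN maps to MISSING.

    Vectorised; accepts a scalar or array and returns the same shape
    (a plain string for scalar input).
    """
    arr = np.asarray(enmo_mg, dtype=float)
    out = np.full(arr.shape, LPA, dtype=object)
    out[arr <= cuts.sedentary_max] = SED
    out[arr >= cuts.mvpa_min] = MVPA
    out[~np.isfinite(arr)] = MISSING
    if arr.ndim == 0:
        return str(out[()])
    return out


def process_raw(
    raw: pd.DataFrame, cuts: CutPoints = CutPoints()
) -> pd.DataFrame:
    """Full chain: raw triaxial samples -> classified per-minute series.

    `raw` has columns participant_id, timestamp, x_g, y_g, z_g, with
    timestamps strictly increasing within each participant.  Per
    participant: sample ENMO -> 1-s epoch means -> 1-min epoch means ->
    intensity class.  Returns participant_id, minute_start, enmo_mg,
    intensity.
    """
    frames = []
    for pid, grp in raw.groupby("participant_id", sort=True):
        ts = pd.to_datetime(grp["timestamp"]).reset_index(drop=True)
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(
                f"timestamps not strictly increasing for participant {pid}"
            )
        enmo = compute_enmo(grp["x_g"], grp["y_g"], grp["z_g"])
        sec = aggregate_samples(ts, enmo, 1)
        minute = aggregate_epochs(sec, 1, 60)
        minute.insert(0, "participant_id", pid)
        frames.append(minute)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"epoch_start": "minute_start"})
    out["intensity"] = classify_minute(out["enmo_mg"].to_numpy(), cuts)
    return out


def read_raw_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"participant_id", "timestamp", "x_g", "y_g", "z_g"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw-sample CSV missing columns: {sorted(missing)}")
    return raw


def read_minute_csv(path, cuts: CutPoints = CutPoints()) -> pd.DataFrame:
    """Read a minute-level CSV; (re)derive the intensity column if absent."""
    df = pd.read_csv(path, parse_dates=["minute_start"])
    required = {"participant_id", "minute_start", "enmo_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"minute CSV missing columns: {sorted(missing)}")
    if "intensity" not in df.columns:
        df["intensity"] = classify_minute(df["enmo_mg"].to_numpy(), cuts)
    return df


def write_minute_csv(minutes: pd.DataFrame, path) -> None:
    minutes.to_csv(path, index=False)
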