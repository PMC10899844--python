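"""Multi-timescale feature extraction from CGM streams.

At each eligible reading time (the *anchor*) the stream is summarized over
three trailing windows — one hour, one day, one week — with the window
taken half-open on the left: ``(anchor - duration, anchor]``, so the anchor
reading itself is included. Windowed statistics are device usage fraction,
fractions of readings above 270 / below 70 mg/dL, mean, population standard
deviation, largest single-step rise and fall, and longest runs of strictly
increasing / decreasing consecutive readings. Static covariates (current
reading, clock time, demographics, most recent HbA1c) are attached to every
row. An optional extended set adds the %-coefficient of variation and the
fraction of readings below 54 mg/dL per window.

Anchors are eligible only when a full week of history exists and the
one-week device usage fraction is at least ``usage_threshold`` (default
80%). "Fraction of time" metrics are fractions of *observed readings*, not
wall-clock integrals; at uniform cadence the two coincide up to dropout.

Sparse windows (fewer than two readings, e.g. right after a sensor swap)
yield explicit missing values for the delta-based statistics — never a
silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .data_io import CGMStream, Cohort

LOW_THRESHOLD = 70.0
HIGH_THRESHOLD = 270.0
VERY_LOW_THRESHOLD = 54.0

STATIC_COLUMNS = [
    "current_reading",
    "time_of_day",
    "day_of_week",
    "gender",
    "diagnosis_age",
    "prior_cgm_use",
    "age",
    "years_since_diagnosis",
    "hba1c_latest",
]

WINDOWED_KINDS = [
    "usage_fraction",
    "frac_time_high",
    "frac_time_low",
    "mean_glucose",
    "sd_glucose",
    "largest_increase",
    "largest_decrease",
    "max_consec_inc",
    "max_consec_dec",
]
EXTENDED_KINDS = ["cv_percent", "frac_below_54"]


@dataclass(frozen=True)
class WindowSpec:
    label: str
    duration_minutes: float

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise ValueError("window duration must be positive")


DEFAULT_WINDOWS = [
    WindowSpec("one_hour", 60.0),
    WindowSpec("one_day", 1440.0),
    WindowSpec("one_week", 10080.0),
]


def feature_columns(windows=None, extended: bool = False) -> list[str]:
    """Ordered model-feature column names (excludes identifiers)."""
    windows = DEFAULT_WINDOWS if windows is None else windows
    cols = list(STATIC_COLUMNS)
    kinds = WINDOWED_KINDS + (EXTENDED_KINDS if extended else [])
    for w in windows:
        cols.extend(f"{kind}_{w.label}" for kind in kinds)
    return cols


def window_slice(stream: CGMStream, anchor, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Readings with timestamp in ``(anchor - duration, anchor]``.

    ``anchor`` must be an existing reading time in the stream.
    """
    anchor = np.datetime64(anchor, "s")
    secs = stream.times_seconds
    a = anchor.astype("datetime64[s]").astype(np.int64)
    i = np.searchsorted(secs, a)
    if i >= len(secs) or secs[i] != a:
        raise ValueError(f"anchor {anchor} is not a reading time of user {stream.user_id}")
    left = np.searchsorted(secs, a - spec.duration_minutes * 60.0, side="right")
    return stream.times[left : i + 1], stream.glucose[left : i + 1]


def usage_fraction(values: np.ndarray, spec: WindowSpec, cadence_minutes: float) -> float:
    """Observed readings over those expected at nominal cadence, capped at 1."""
    expected = spec.duration_minutes / cadence_minutes
    return min(1.0, len(values) / expected)


def threshold_fractions(
    values: np.ndarray,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
    extended_low: float = VERY_LOW_THRESHOLD,
) -> tuple[float, float, float]:
    """(fraction < low, fraction > high, fraction < extended_low) of readings.

    Strict inequalities, matching the event definitions <70 / >270 mg/dL.
    Empty input yields missing values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return (np.nan, np.nan, np.nan)
    n = values.size
    return (
        float((values < low).sum()) / n,
        float((values > high).sum()) / n,
        float((values < extended_low).sum()) / n,
    )


def trend_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, population SD, largest rise/fall between consecutive readings,
    and longest strictly increasing / decreasing runs.

    Delta-based outputs are missing with fewer than two readings; ties
    (zero delta) break runs.
    """
    values = np.asarray(values, dtype=float)
    out = {
        "mean": np.nan,
        "sd": np.nan,
        "largest_increase": np.nan,
        "largest_decrease": np.nan,
        "max_consec_inc": np.nan,
        "max_consec_dec": np.nan,
    }
    if values.size == 0:
        return out
    out["mean"] = float(values.mean())
    if values.size < 2:
        return out
    out["sd"] = float(values.std(ddof=0))
    d = np.diff(values)
    out["largest_increase"] = float(max(d.max(), 0.0))
    out["largest_decrease"] = float(max(-d.min(), 0.0))

    def longest_run(mask: np.ndarray) -> int:
        best = run = 0
        for m in mask:
            run = run + 1 if m else 0
            best = max(best, run)
        return best

    out["max_consec_inc"] = float(longest_run(d > 0))
    out["max_consec_dec"] = float(longest_run(d < 0))
    return out


def _static_frame(stream: CGMStream, profile, anchor_idx: np.ndarray) -> pd.DataFrame:
    secs = stream.times_seconds[anchor_idx]
    days = secs // 86400
    df = pd.DataFrame(
        {
            "user_id": stream.user_id,
            "anchor_time": stream.times[anchor_idx],
            "current_reading": stream.glucose[anchor_idx],
            "time_of_day": (secs % 86400) / 3600.0,
            "day_of_week": ((days + 3) % 7).astype(np.int64),  # epoch day 0 = Thursday
            "gender": profile.gender,
            "diagnosis_age": profile.age_diagnosis,
            "prior_cgm_use": int(profile.prior_cgm_use),
            "age": profile.age_enrollment,
            "years_since_diagnosis": profile.years_since_diagnosis,
        }
    )
    if profile.hba1c_history:
        df["hba1c_latest"] = [
            profile.hba1c_at(t) for t in stream.times[anchor_idx]
        ]
    else:
        df["hba1c_latest"] = profile.hba1c_latest
    return df


def build_features(
    cohort: Cohort,
    windows=None,
    usage_threshold: float = 0.8,
    extended: bool = False,
    anchor_stride: int = 1,
    history_days: float = 7.0,
) -> pd.DataFrame:
    """One feature row per eligible reading across the cohort.

    Eligibility requires a full ``history_days`` of elapsed wear before the
    anchor and a one-week usage fraction of at least ``usage_threshold``.
    ``anchor_stride`` keeps every k-th eligible reading (1 = all), for
    scaling experiments down; it never changes any computed value.
    """
    windows = DEFAULT_WINDOWS if windows is None else windows
    frames: list[pd.DataFrame] = []
    week = next((w for w in windows if w.label == "one_week"), WindowSpec("one_week", 10080.0))
    for uid in cohort.user_ids:
        stream = cohort.streams[uid]
        if len(stream) == 0:
            continue
        secs = stream.times_seconds
        g = stream.glucose
        all_idx = np.arange(len(stream), dtype=np.int64)
        eligible = secs - secs[0] >= history_days * 86400.0
        idx = all_idx[eligible]
        if idx.size == 0:
            continue
        week_stats = _kernels.window_stats(
            secs, g, idx, week.duration_minutes * 60.0,
            LOW_THRESHOLD, HIGH_THRESHOLD, VERY_LOW_THRESHOLD,
        )
        expected_week = week.duration_minutes / stream.cadence_minutes
        week_usage = np.minimum(1.0, week_stats[:, 0] / expected_week)
        idx = idx[week_usage >= usage_threshold]
        if anchor_stride > 1:
            idx = idx[::anchor_stride]
        if idx.size == 0:
            continue
        df = _static_frame(stream, cohort.profiles[uid], idx)
        for w in windows:
            stats = _kernels.window_stats(
                secs, g, idx, w.duration_minutes * 60.0,
                LOW_THRESHOLD, HIGH_THRESHOLD, VERY_LOW_THRESHOLD,
            )
            expected = w.duration_minutes / stream.cadence_minutes
            df[f"usage_fraction_{w.label}"] = np.minimum(1.0, stats[:, 0] / expected)
            df[f"frac_time_high_{w.label}"] = stats[:, 4]
            df[f"frac_time_low_{w.label}"] = stats[:, 3]
            df[f"mean_glucose_{w.label}"] = stats[:, 1]
            df[f"sd_glucose_{w.label}"] = stats[:, 2]
            df[f"largest_increase_{w.label}"] = stats[:, 6]
            df[f"largest_decrease_{w.label}"] = stats[:, 7]
            df[f"max_consec_inc_{w.label}"] = stats[:, 8]
            df[f"max_consec_dec_{w.label}"] = stats[:, 9]
            if extended:
                df[f"cv_percent_{w.label}"] = 100.0 * stats[:, 2] / stats[:, 1]
                df[f"frac_below_54_{w.label}"] = stats[:, 5]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["user_id", "anchor_time"] + feature_columns(windows, extended))
    return pd.concat(frames, ignore_index=True)
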