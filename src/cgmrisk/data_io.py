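"""Core data model for CGM streams and user metadata, plus plain-CSV I/O.

A cohort is a set of users, each with a continuous-glucose-monitor (CGM)
stream — timestamped interstitial glucose readings in mg/dL at a nominal
5-minute cadence — and a static profile (demographics and the most recent
HbA1c). Timestamps are timezone-naive local clock time because time-of-day
is a downstream model feature and must reflect the user's day.

File formats are deliberately minimal: one CSV for all streams
(``user_id,timestamp,glucose_mg_dl``, ISO-8601 timestamps) and one CSV for
profiles. No vendor export dialects are parsed and no imputation or
denoising happens at this layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sanity bounds on a physically plausible sensor reading (mg/dL).
GLUCOSE_MIN = 0.0
GLUCOSE_MAX = 1000.0

STREAM_COLUMNS = ["user_id", "timestamp", "glucose_mg_dl"]
PROFILE_COLUMNS = [
    "user_id",
    "gender",
    "age_enrollment",
    "age_diagnosis",
    "prior_cgm_use",
    "hba1c_latest",
]


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class CohortValidationError(ValueError):
    """Stream/profile cross-references are inconsistent."""


@dataclass
class CGMStream:
    """One user's ordered glucose trace.

    Parameters
    ----------
    user_id : str
        Opaque identifier.
    times : np.ndarray of datetime64[s]
        Strictly increasing reading timestamps.
    glucose : np.ndarray of float64
        Glucose in mg/dL, aligned with ``times``.
    cadence_minutes : float
        Nominal device reporting interval (Dexcom-style default 5 min).
    """

    user_id: str
    times: np.ndarray
    glucose: np.ndarray
    cadence_minutes: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose, dtype=np.float64)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must be aligned")
        if self.times.size > 1 and not (np.diff(self.times.astype(np.int64)) > 0).all():
            raise ValueError(f"stream {self.user_id!r}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def times_seconds(self) -> np.ndarray:
        """Timestamps as int64 epoch seconds (convenient for window math)."""
        return self.times.astype(np.int64)


@dataclass
class UserProfile:
    """Static per-user covariates: demographics and most recent HbA1c."""

    user_id: str
    gender: str
    age_enrollment: float
    age_diagnosis: float
    prior_cgm_use: bool
    hba1c_latest: float
    hba1c_history: list[tuple[np.datetime64, float]] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.hba1c_latest < 20.0):
            raise ValueError(
                f"profile {self.user_id!r}: hba1c_latest {self.hba1c_latest} outside (0, 20)"
            )
        if self.age_diagnosis > self.age_enrollment + 1.0:
            raise ValueError(
                f"profile {self.user_id!r}: diagnosis age exceeds enrollment age"
            )

    @property
    def years_since_diagnosis(self) -> float:
        return self.age_enrollment - self.age_diagnosis

    def hba1c_at(self, when: np.datetime64) -> float:
        """Most recent HbA1c at or before ``when``; falls back to the latest value."""
        if not self.hba1c_history:
            return self.hba1c_latest
        best = None
        for t, v in self.hba1c_history:
            if np.datetime64(t, "s") <= np.datetime64(when, "s"):
                best = v
        return self.hba1c_latest if best is None else best


@dataclass
class Cohort:
    """Streams and profiles keyed by user_id; keys must match exactly."""

    streams: dict[str, CGMStream] = field(default_factory=dict)
    profiles: dict[str, UserProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        s, p = set(self.streams), set(self.profiles)
        if s != p:
            missing_profile = sorted(s - p)
            missing_stream = sorted(p - s)
            raise CohortValidationError(
                f"stream/profile mismatch: users without profile {missing_profile}, "
                f"users without stream {missing_stream}"
            )

    @property
    def user_ids(self) -> list[str]:
        return sorted(self.streams)

    def __len__(self) -> int:
        return len(self.streams)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column {col!r}")


def read_cohort(stream_path, profile_path, cadence_minutes: float = 5.0) -> Cohort:
    """Read and validate a cohort from a stream CSV and a profile CSV.

    Rows violating the glucose sanity bound (0, 1000) are dropped with a
    logged count. Duplicate timestamps within a user keep the last-seen
    reading (device re-transmission artifact). Unparseable timestamps raise
    with the offending line numbers.
    """
    streams_df = pd.read_csv(stream_path, dtype={"user_id": str})
    _require_columns(streams_df, STREAM_COLUMNS, "stream")
    ts = pd.to_datetime(streams_df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() & streams_df["timestamp"].notna()
    if bad.any():
        # +2: 1-based line numbers plus the header line
        lines = [int(i) + 2 for i in streams_df.index[bad][:5]]
        raise SchemaError(f"unparseable timestamps in stream file at lines {lines}")
    streams_df["timestamp"] = ts

    glucose = pd.to_numeric(streams_df["glucose_mg_dl"], errors="coerce")
    in_range = (glucose > GLUCOSE_MIN) & (glucose < GLUCOSE_MAX)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.warning("read_cohort: dropped %d readings outside sanity bounds", n_dropped)
    streams_df = streams_df.loc[in_range].copy()
    streams_df["glucose_mg_dl"] = glucose[in_range]

    profiles_df = pd.read_csv(profile_path, dtype={"user_id": str})
    _require_columns(profiles_df, PROFILE_COLUMNS, "profile")

    profiles: dict[str, UserProfile] = {}
    for row in profiles_df.itertuples(index=False):
        profiles[row.user_id] = UserProfile(
            user_id=row.user_id,
            gender=str(row.gender),
            age_enrollment=float(row.age_enrollment),
            age_diagnosis=float(row.age_diagnosis),
            prior_cgm_use=bool(row.prior_cgm_use),
            hba1c_latest=float(row.hba1c_latest),
        )

    streams: dict[str, CGMStream] = {}
    for user_id, grp in streams_df.groupby("user_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        dup = grp["timestamp"].duplicated(keep="last")
        if dup.any():
            logger.warning(
                "read_cohort: user %s had %d duplicate timestamps (kept last)",
                user_id,
                int(dup.sum()),
            )
            grp = grp.loc[~dup]
        streams[str(user_id)] = CGMStream(
            user_id=str(user_id),
            times=grp["timestamp"].to_numpy().astype("datetime64[s]"),
            glucose=grp["glucose_mg_dl"].to_numpy(dtype=np.float64),
            cadence_minutes=cadence_minutes,
        )

    return Cohort(streams=streams, profiles=profiles)


def write_cohort(cohort: Cohort, stream_path, profile_path) -> None:
    """Write a cohort to the two plain-CSV files; round-trips exactly."""
    frames = []
    for user_id in cohort.user_ids:
        st = cohort.streams[user_id]
        frames.append(
            pd.DataFrame(
                {
                    "user_id": user_id,
                    "timestamp": st.times.astype("datetime64[s]"),
                    "glucose_mg_dl": st.glucose,
                }
            )
        )
    streams_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=STREAM_COLUMNS)
    )
    if len(streams_df):
        streams_df["timestamp"] = streams_df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    streams_df.to_csv(stream_path, index=False)

    prof_rows = []
    for user_id in cohort.user_ids:
        p = cohort.profiles[user_id]
        prof_rows.append(
            {
                "user_id": p.user_id,
                "gender": p.gender,
                "age_enrollment": p.age_enrollment,
                "age_diagnosis": p.age_diagnosis,
                "prior_cgm_use": p.prior_cgm_use,
                "hba1c_latest": p.hba1c_latest,
            }
        )
    pd.DataFrame(prof_rows, columns=PROFILE_COLUMNS).to_csv(profile_path, index=False)


def detect_gaps(stream: CGMStream, min_gap_minutes: float) -> list[tuple[np.datetime64, np.datetime64]]:
    """Maximal intervals between consecutive readings spaced more than ``min_gap_minutes``.

    Returns ``(last reading before gap, first reading after gap)`` pairs,
    disjoint and ordered. Streams with fewer than two readings have no gaps.
    """
    if len(stream) < 2:
        return []
    secs = stream.times_seconds
    deltas = np.diff(secs)
    idx = np.nonzero(deltas > min_gap_minutes * 60.0)[0]
    return [(stream.times[i], stream.times[i + 1]) for i in idx]
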