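"""Ahead-of-time binary targets and prediction-event-horizon statistics.

A feature row anchored at reading time ``t`` receives ``y_hypo = 1`` if any
reading in the lookahead window ``(t, t + horizon]`` (default 60 minutes)
falls below 70 mg/dL, and ``y_hyper = 1`` if any exceeds 270 mg/dL. Anchors
already inside an event (reading <70 or >270) are removed so the models are
scored on genuine ahead-of-time prediction, and anchors whose lookahead
contains no readings at all (sensor gap) are dropped rather than labeled
negative — absence of data is not evidence of absence of an event.

``extract_events`` turns a stream into maximal low/high excursions;
``prediction_horizons`` measures, for each event, how far ahead of onset a
model's sustained positive prediction began.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .data_io import CGMStream, Cohort
from .features import HIGH_THRESHOLD, LOW_THRESHOLD

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlycemicEvent:
    user_id: str
    event_type: str  # "hypo" | "hyper"
    onset: np.datetime64
    end: np.datetime64


class LabelConfigError(ValueError):
    pass


def label_examples(
    features: pd.DataFrame, cohort: Cohort, horizon_minutes: float = 60.0
) -> pd.DataFrame:
    """Attach ``y_hypo``/``y_hyper`` targets to feature rows.

    Returns the surviving rows with three added columns: ``y_hypo``,
    ``y_hyper`` and ``horizon_readings`` (number of readings observed in the
    lookahead). In-event anchors and empty-lookahead anchors are dropped,
    with dropped counts logged.
    """
    if horizon_minutes <= 0:
        raise LabelConfigError("horizon must be positive")
    if features.empty:
        out = features.copy()
        for c in ("y_hypo", "y_hyper", "horizon_readings"):
            out[c] = pd.Series(dtype=float)
        return out

    parts = []
    for uid, grp in features.groupby("user_id", sort=True):
        stream = cohort.streams[uid]
        secs = stream.times_seconds
        anchors = grp["anchor_time"].to_numpy().astype("datetime64[s]").astype(np.int64)
        idx = np.searchsorted(secs, anchors)
        if (idx >= len(secs)).any() or (secs[np.minimum(idx, len(secs) - 1)] != anchors).any():
            raise ValueError(f"feature anchors not found in stream for user {uid}")
        ext = _kernels.lookahead_extrema(secs, stream.glucose, idx, horizon_minutes * 60.0)
        part = grp.copy()
        part["horizon_readings"] = ext[:, 0].astype(np.int64)
        part["y_hypo"] = (ext[:, 1] < LOW_THRESHOLD).astype(np.int64)
        part["y_hyper"] = (ext[:, 2] > HIGH_THRESHOLD).astype(np.int64)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)

    in_event = (out["current_reading"] < LOW_THRESHOLD) | (
        out["current_reading"] > HIGH_THRESHOLD
    )
    empty_lookahead = out["horizon_readings"] == 0
    n_event, n_empty = int(in_event.sum()), int((empty_lookahead & ~in_event).sum())
    if n_event or n_empty:
        logger.info(
            "label_examples: dropped %d in-event anchors, %d empty-lookahead anchors",
            n_event,
            n_empty,
        )
    return out.loc[~in_event & ~empty_lookahead].reset_index(drop=True)


def extract_events(stream: CGMStream) -> list[GlycemicEvent]:
    """Maximal consecutive runs of readings <70 (hypo) or >270 (hyper)."""
    events: list[GlycemicEvent] = []
    for kind, mask in (
        ("hypo", stream.glucose < LOW_THRESHOLD),
        ("hyper", stream.glucose > HIGH_THRESHOLD),
    ):
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0] - 1
        events.extend(
            GlycemicEvent(stream.user_id, kind, stream.times[i], stream.times[j])
            for i, j in zip(starts, ends)
        )
    events.sort(key=lambda e: (e.onset.astype(np.int64), e.event_type))
    return events


def events_to_frame(events: list[GlycemicEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"user_id": e.user_id, "event_type": e.event_type, "onset": e.onset, "end": e.end}
            for e in events
        ],
        columns=["user_id", "event_type", "onset", "end"],
    )


def prediction_horizons(
    events: list[GlycemicEvent],
    predictions: pd.DataFrame,
    threshold: float = 0.5,
    lookback_minutes: float = 60.0,
    mode: str = "sustained",
) -> tuple[pd.DataFrame, dict]:
    """Ahead-of-time warning horizon for each event.

    ``predictions`` needs columns ``user_id``, ``anchor_time``,
    ``probability``; these are the model's scores at the eligible anchors.
    For each event, anchors in ``[onset - lookback, onset)`` are examined.
    In the default ``"sustained"`` mode the horizon is measured from the
    start of the final contiguous run of firing anchors leading into the
    event (a lone early spike does not count as a warning); ``"first"``
    measures from the earliest firing anchor in the lookback. Events with no
    qualifying firing anchor are counted as missed.

    Returns (per-event table, summary dict with mean/median horizon in
    minutes over detected events and the fraction of events predicted).
    """
    if mode not in ("sustained", "first"):
        raise ValueError("mode must be 'sustained' or 'first'")
    rows = []
    by_user = {uid: grp for uid, grp in predictions.groupby("user_id")}
    for ev in events:
        grp = by_user.get(ev.user_id)
        horizon = np.nan
        if grp is not None:
            t = grp["anchor_time"].to_numpy().astype("datetime64[s]").astype(np.int64)
            order = np.argsort(t, kind="mergesort")
            t = t[order]
            p = grp["probability"].to_numpy()[order]
            onset = ev.onset.astype("datetime64[s]").astype(np.int64)
            sel = (t >= onset - lookback_minutes * 60.0) & (t < onset)
            if sel.any():
                ts, ps = t[sel], p[sel]
                fired = ps >= threshold
                if mode == "first":
                    if fired.any():
                        horizon = (onset - ts[fired][0]) / 60.0
                else:
                    # walk back from the last pre-onset anchor while it fires
                    k = len(fired) - 1
                    if fired[k]:
                        while k > 0 and fired[k - 1]:
                            k -= 1
                        horizon = (onset - ts[k]) / 60.0
        rows.append(
            {
                "user_id": ev.user_id,
                "event_type": ev.event_type,
                "onset": ev.onset,
                "horizon_minutes": horizon,
                "detected": bool(np.isfinite(horizon)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["user_id", "event_type", "onset", "horizon_minutes", "detected"]
    )
    detected = table.loc[table["detected"], "horizon_minutes"]
    summary = {
        "n_events": int(len(table)),
        "n_detected": int(table["detected"].sum()),
        "fraction_detected": float(table["detected"].mean()) if len(table) else np.nan,
        "mean_horizon_minutes": float(detected.mean()) if len(detected) else np.nan,
        "median_horizon_minutes": float(detected.median()) if len(detected) else np.nan,
        "defined": bool(len(detected)),
    }
    return table, summary
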