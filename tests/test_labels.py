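import numpy as np
import pandas as pd
import pytest

from cgmrisk.data_io import Cohort
from cgmrisk.features import build_features
from cgmrisk.labels import (
    GlycemicEvent,
    LabelConfigError,
    extract_events,
    label_examples,
    prediction_horizons,
)

from .conftest import T0, make_cohort, make_stream


def _label_one(minutes, glucose, **kw):
    """Features (no eligibility filtering) + labels for one constructed trace."""
    cohort = make_cohort([make_stream(minutes, glucose)])
    feats = build_features(cohort, usage_threshold=0.0, history_days=0.0)
    return label_examples(feats, cohort, **kw)


class TestLabelExamples:
    def test_hypo_in_lookahead_labels_positive(self):
        lab = _label_one([0, 20, 40, 55], [150, 120, 95, 68])
        row = lab[lab["current_reading"] == 150].iloc[0]
        assert (row["y_hypo"], row["y_hyper"]) == (1, 0)

    def test_in_event_anchor_removed(self):
        lab = _label_one([0, 5, 10, 15], [65, 150, 300, 150])
        assert 65 not in lab["current_reading"].values
        assert 300 not in lab["current_reading"].values

    def test_flat_trace_all_negative_no_removals(self):
        n = 288
        lab = _label_one(np.arange(0, 5 * n, 5), np.full(n, 150.0))
        # only trailing rows with an empty lookahead are dropped
        assert len(lab) == n - 1
        assert (lab["y_hypo"] == 0).all() and (lab["y_hyper"] == 0).all()

    def test_empty_lookahead_dropped_not_labeled(self):
        # 90-min gap after the 3rd reading: its lookahead holds no readings
        lab = _label_one([0, 5, 10, 100, 105], [150, 150, 150, 60, 150])
        assert 10 * 60 not in (
            lab["anchor_time"].to_numpy().astype("datetime64[s]").astype(np.int64)
            - T0.astype(np.int64)
        )
        assert (lab["horizon_readings"] >= 1).all()

    def test_boundary_values_are_in_range(self):
        # readings exactly at 70 and 270 are neither hypo nor hyper
        lab = _label_one([0, 5, 10, 15], [70, 270, 150, 150])
        assert len(lab) == 3  # last row dropped (empty lookahead)
        assert (lab["y_hypo"] == 0).all() and (lab["y_hyper"] == 0).all()

    def test_horizon_config_validated(self, labeled_table):
        with pytest.raises(LabelConfigError):
            _label_one([0, 5], [150, 150], horizon_minutes=0)

    def test_no_labeled_anchor_in_event(self, labeled_table):
        g = labeled_table["current_reading"]
        assert ((g >= 70) & (g <= 270)).all()

    def test_shorter_horizon_labels_subset(self):
        minutes = np.arange(0, 120, 5)
        glucose = np.linspace(200, 60, len(minutes))
        lab60 = _label_one(minutes, glucose, horizon_minutes=60)
        lab30 = _label_one(minutes, glucose, horizon_minutes=30)
        merged = lab30.merge(lab60, on="anchor_time", suffixes=("_30", "_60"))
        assert (merged["y_hypo_30"] <= merged["y_hypo_60"]).all()


class TestExtractEvents:
    def test_single_dip_event_onset(self):
        s = make_stream(np.arange(0, 50, 5), [150, 120, 90, 65, 62, 68, 90, 150, 150, 150])
        evs = extract_events(s)
        assert len(evs) == 1
        assert evs[0].event_type == "hypo"
        assert evs[0].onset == T0 + np.timedelta64(15 * 60, "s")
        assert evs[0].end == T0 + np.timedelta64(25 * 60, "s")

    def test_no_crossings_no_events(self):
        s = make_stream(np.arange(0, 50, 5), np.full(10, 150.0))
        assert extract_events(s) == []

    def test_two_dips_split_by_recovery(self):
        s = make_stream(np.arange(0, 45, 5), [65, 65, 80, 65, 65, 150, 280, 150, 280])
        evs = extract_events(s)
        assert [e.event_type for e in evs] == ["hypo", "hypo", "hyper", "hyper"]

    def test_labels_consistent_with_events(self, sim_cohort, labeled_table):
        """y_hypo=1 at an anchor iff a hypo event (onset or in-event reading)
        falls inside its 60-minute lookahead."""
        cohort, _ = sim_cohort
        for uid in cohort.user_ids[:3]:
            stream = cohort.streams[uid]
            evs = extract_events(stream)
            in_event = {
                kind: np.sort(
                    np.concatenate(
                        [
                            stream.times_seconds[
                                (stream.times >= e.onset) & (stream.times <= e.end)
                            ]
                            for e in evs
                            if e.event_type == kind
                        ]
                    )
                    if any(e.event_type == kind for e in evs)
                    else np.array([], dtype=np.int64)
                )
                for kind in ("hypo", "hyper")
            }
            sub = labeled_table[labeled_table["user_id"] == uid]
            anchors = sub["anchor_time"].to_numpy().astype("datetime64[s]").astype(np.int64)
            for kind in ("hypo", "hyper"):
                ts = in_event[kind]
                lo = np.searchsorted(ts, anchors, side="right")
                hi = np.searchsorted(ts, anchors + 3600, side="right")
                expected = (hi > lo).astype(int)
                assert np.array_equal(sub[f"y_{kind}"].to_numpy(), expected)


def _mk_preds(minutes, probs, user_id="u0"):
    return pd.DataFrame(
        {
            "user_id": user_id,
            "anchor_time": T0 + (np.asarray(minutes) * 60).astype("timedelta64[s]"),
            "probability": probs,
        }
    )


class TestPredictionHorizons:
    def test_sustained_firing_horizon(self):
        onset = T0 + np.timedelta64(720 * 60, "s")  # 12:00
        ev = GlycemicEvent("u0", "hypo", onset, onset)
        minutes = np.arange(600, 720, 5)
        probs = np.where(minutes >= 675, 0.9, 0.1)  # fires from 11:15 onward
        table, summary = prediction_horizons([ev], _mk_preds(minutes, probs))
        assert table["horizon_minutes"].iloc[0] == 45.0
        assert summary["mean_horizon_minutes"] == 45.0
        assert summary["fraction_detected"] == 1.0

    def test_never_firing_counts_missed(self):
        onset = T0 + np.timedelta64(720 * 60, "s")
        ev = GlycemicEvent("u0", "hypo", onset, onset)
        minutes = np.arange(600, 720, 5)
        table, summary = prediction_horizons([ev], _mk_preds(minutes, np.full(len(minutes), 0.1)))
        assert not table["detected"].iloc[0]
        assert summary["n_detected"] == 0
        assert not summary["defined"]

    def test_isolated_early_spike_ignored_in_sustained_mode(self):
        onset = T0 + np.timedelta64(720 * 60, "s")
        ev = GlycemicEvent("u0", "hypo", onset, onset)
        minutes = np.arange(660, 720, 5)
        probs = np.full(len(minutes), 0.1)
        probs[0] = 0.99  # lone spike at 11:00
        probs[-3:] = 0.9  # sustained alarm from 11:45
        table, _ = prediction_horizons([ev], _mk_preds(minutes, probs))
        assert table["horizon_minutes"].iloc[0] == 15.0
        table_f, _ = prediction_horizons([ev], _mk_preds(minutes, probs), mode="first")
        assert table_f["horizon_minutes"].iloc[0] == 60.0

    def test_oracle_horizons_bounded(self, sim_cohort, labeled_table):
        """A perfect-foresight predictor yields horizons in (0, 60] minutes."""
        cohort, _ = sim_cohort
        preds = labeled_table[["user_id", "anchor_time"]].copy()
        preds["probability"] = labeled_table["y_hypo"].astype(float)
        events = [
            e for uid in cohort.user_ids for e in extract_events(cohort.streams[uid])
            if e.event_type == "hypo"
        ]
        assert events
        table, summary = prediction_horizons(events, preds)
        h = table.loc[table["detected"], "horizon_minutes"]
        assert (h > 0).all() and (h <= 60).all()
        assert summary["mean_horizon_minutes"] <= 60.0

    def test_empty_event_list(self):
        table, summary = prediction_horizons([], _mk_preds([0], [0.1]))
        assert table.empty and not summary["defined"]
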