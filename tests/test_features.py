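import math

import numpy as np
import pandas as pd
import pytest

from cgmrisk.data_io import CGMStream, Cohort
from cgmrisk.features import (
    DEFAULT_WINDOWS,
    WindowSpec,
    build_features,
    feature_columns,
    threshold_fractions,
    trend_stats,
    usage_fraction,
    window_slice,
)

from .conftest import T0, make_cohort, make_profile, make_stream

ONE_HOUR = WindowSpec("one_hour", 60.0)


def naive_window_features(times_s, glucose, i, duration_s, cadence_min):
    """Independent naive-loop recomputation of every windowed feature.

    Mirrors the mathematical definitions with plain Python loops and the
    same left-to-right accumulation order, so agreement is exact.
    """
    vals = []
    for j in range(i + 1):
        if times_s[i] - duration_s < times_s[j] <= times_s[i]:
            vals.append(glucose[j])
    count = len(vals)
    out = {"usage_fraction": min(1.0, count / (duration_s / 60.0 / cadence_min))}
    s = 0.0
    for v in vals:
        s += v
    mean = s / count
    n_low = sum(1 for v in vals if v < 70.0)
    n_high = sum(1 for v in vals if v > 270.0)
    n_vlow = sum(1 for v in vals if v < 54.0)
    out["mean_glucose"] = mean
    out["frac_time_low"] = n_low / count
    out["frac_time_high"] = n_high / count
    out["frac_below_54"] = n_vlow / count
    if count < 2:
        out.update(
            sd_glucose=np.nan, largest_increase=np.nan, largest_decrease=np.nan,
            max_consec_inc=np.nan, max_consec_dec=np.nan, cv_percent=np.nan,
        )
        return out
    ss = 0.0
    for v in vals:
        ss += v * v
    var = ss / count - mean * mean
    if var < 0.0:
        var = 0.0
    sd = math.sqrt(var)
    out["sd_glucose"] = sd
    out["cv_percent"] = 100.0 * sd / mean
    max_inc = max_dec = 0.0
    run_inc = run_dec = best_inc = best_dec = 0
    for a, b in zip(vals, vals[1:]):
        d = b - a
        if d > 0:
            run_inc += 1
            run_dec = 0
            max_inc = max(max_inc, d)
        elif d < 0:
            run_dec += 1
            run_inc = 0
            max_dec = max(max_dec, -d)
        else:
            run_inc = run_dec = 0
        best_inc = max(best_inc, run_inc)
        best_dec = max(best_dec, run_dec)
    out["largest_increase"] = max_inc
    out["largest_decrease"] = max_dec
    out["max_consec_inc"] = float(best_inc)
    out["max_consec_dec"] = float(best_dec)
    return out


class TestWindowSlice:
    def test_one_hour_window_is_left_open(self):
        s = make_stream(np.arange(0, 65, 5), 100 + np.arange(13))
        times, vals = window_slice(s, s.times[-1], ONE_HOUR)
        # the reading exactly 60 min before the anchor is excluded
        assert len(vals) == 12
        assert vals[0] == 101

    def test_anchor_at_first_reading(self):
        s = make_stream(np.arange(0, 65, 5), 100 + np.arange(13))
        _, vals = window_slice(s, s.times[0], ONE_HOUR)
        assert list(vals) == [100]

    def test_window_spanning_gap_not_imputed(self):
        s = make_stream([0, 5, 50, 55], [100, 101, 102, 103])
        _, vals = window_slice(s, s.times[-1], ONE_HOUR)
        assert len(vals) == 4

    def test_non_reading_anchor_rejected(self):
        s = make_stream([0, 5], [100, 101])
        with pytest.raises(ValueError, match="anchor"):
            window_slice(s, T0 + np.timedelta64(90, "s"), ONE_HOUR)


class TestSimpleStats:
    def test_usage_fraction_full_week(self):
        week = WindowSpec("one_week", 10080.0)
        assert usage_fraction(np.zeros(2016), week, 5.0) == 1.0
        assert usage_fraction(np.zeros(1613), week, 5.0) == pytest.approx(0.8001, abs=1e-4)
        assert usage_fraction(np.zeros(1613), week, 5.0) >= 0.8
        assert usage_fraction(np.array([]), week, 5.0) == 0.0
        assert usage_fraction(np.zeros(5000), week, 5.0) == 1.0  # capped

    def test_threshold_fractions_worked_case(self):
        fl, fh, f54 = threshold_fractions(np.array([60.0, 65.0, 150.0, 280.0]))
        assert (fl, fh, f54) == (0.5, 0.25, 0.0)
        assert threshold_fractions(np.full(8, 150.0)) == (0.0, 0.0, 0.0)
        assert threshold_fractions(np.full(8, 50.0)) == (1.0, 0.0, 1.0)
        assert all(np.isnan(v) for v in threshold_fractions(np.array([])))

    def test_trend_stats_worked_case(self):
        st = trend_stats(np.array([100.0, 110.0, 105.0, 120.0, 90.0]))
        assert st["largest_increase"] == 15
        assert st["largest_decrease"] == 30
        assert st["max_consec_inc"] == 1
        assert st["max_consec_dec"] == 1
        assert st["mean"] == 105

    def test_trend_stats_degenerate_cases(self):
        st = trend_stats(np.full(12, 150.0))
        assert st["sd"] == 0 and st["largest_increase"] == 0 and st["max_consec_inc"] == 0
        rising = trend_stats(100 + 5.0 * np.arange(12))
        assert rising["max_consec_inc"] == 11 and rising["largest_decrease"] == 0
        single = trend_stats(np.array([140.0]))
        assert single["mean"] == 140 and np.isnan(single["sd"])


class TestOracleEquivalence:
    def test_windowed_features_match_naive_loops_exactly(self):
        """Every windowed feature equals a brute-force recomputation on >=1000
        randomized windows, bit for bit."""
        rng = np.random.default_rng(123)
        streams = []
        for u in range(2):
            n = 3 * 288
            keep = rng.uniform(size=n) > 0.25  # ragged sampling
            minutes = np.arange(n)[keep] * 5
            glucose = np.round(rng.uniform(45, 350, size=keep.sum()), 1)
            streams.append(make_stream(minutes, glucose, user_id=f"u{u}"))
        cohort = make_cohort(streams)
        feats = build_features(
            cohort, usage_threshold=0.0, extended=True, history_days=0.0
        )
        assert len(feats) >= 1000
        kinds = [
            "usage_fraction", "frac_time_high", "frac_time_low", "mean_glucose",
            "sd_glucose", "largest_increase", "largest_decrease",
            "max_consec_inc", "max_consec_dec", "cv_percent", "frac_below_54",
        ]
        checked = 0
        for stream in streams:
            secs = stream.times_seconds
            sub = feats[feats.user_id == stream.user_id].reset_index(drop=True)
            anchor_s = sub["anchor_time"].to_numpy().astype("datetime64[s]").astype(np.int64)
            idx = np.searchsorted(secs, anchor_s)
            for w in DEFAULT_WINDOWS:
                for row_i in range(0, len(sub), 3):
                    ref = naive_window_features(
                        secs, stream.glucose, int(idx[row_i]),
                        w.duration_minutes * 60.0, stream.cadence_minutes,
                    )
                    for kind in kinds:
                        got = sub.loc[row_i, f"{kind}_{w.label}"]
                        exp = ref[kind]
                        assert (np.isnan(got) and np.isnan(exp)) or got == exp, (
                            stream.user_id, w.label, kind, row_i, got, exp,
                        )
                        checked += 1
        assert checked >= 1000


class TestBuildFeatures:
    def test_full_usage_user_all_post_week_anchors_eligible(self):
        minutes = np.arange(0, 14 * 1440, 5)
        s = make_stream(minutes, np.full(len(minutes), 150.0))
        feats = build_features(make_cohort([s]))
        # anchors with a full prior week: days 8-14 = 2016 readings
        assert len(feats) == 2016
        assert (feats["usage_fraction_one_week"] == 1.0).all()

    def test_heavy_dropout_user_filtered_out(self):
        rng = np.random.default_rng(0)
        minutes = np.arange(0, 14 * 1440, 5)
        keep = rng.uniform(size=len(minutes)) > 0.5
        s = make_stream(minutes[keep], np.full(keep.sum(), 150.0))
        feats = build_features(make_cohort([s]))
        assert len(feats) == 0

    def test_eighty_percent_usage_boundary_eligible(self):
        # exactly 80% of scheduled readings, uniformly: every 5th removed
        minutes = np.arange(0, 14 * 1440, 5)
        keep = np.arange(len(minutes)) % 5 != 0
        s = make_stream(minutes[keep], np.full(keep.sum(), 150.0))
        feats = build_features(make_cohort([s]))
        assert len(feats) > 0
        assert (feats["usage_fraction_one_week"] >= 0.8).all()

    def test_anti_leakage_truncation_invariance(self, sim_cohort):
        """No feature changes when all readings after the anchor are deleted."""
        cohort, _ = sim_cohort
        uid = cohort.user_ids[0]
        stream = cohort.streams[uid]
        feats = build_features(Cohort(streams={uid: stream}, profiles={uid: cohort.profiles[uid]}))
        row = feats.iloc[len(feats) // 2]
        cut = np.datetime64(row["anchor_time"], "s")
        sel = stream.times <= cut
        truncated = CGMStream(uid, stream.times[sel], stream.glucose[sel], stream.cadence_minutes)
        feats_t = build_features(
            Cohort(streams={uid: truncated}, profiles={uid: cohort.profiles[uid]})
        )
        row_t = feats_t[feats_t["anchor_time"] == row["anchor_time"]].iloc[-1]
        for col in feature_columns():
            a, b = row[col], row_t[col]
            assert (pd.isna(a) and pd.isna(b)) or a == b, col

    def test_permutation_safety(self, tmp_path, sim_cohort):
        """Shuffling raw CSV row order before ingest changes no feature row."""
        from cgmrisk.data_io import read_cohort, write_cohort

        cohort, _ = sim_cohort
        uid = cohort.user_ids[1]
        small = Cohort(streams={uid: cohort.streams[uid]}, profiles={uid: cohort.profiles[uid]})
        sp, pp = tmp_path / "s.csv", tmp_path / "p.csv"
        write_cohort(small, sp, pp)
        df = pd.read_csv(sp).sample(frac=1.0, random_state=7)
        df.to_csv(sp, index=False)
        shuffled = read_cohort(sp, pp)
        f1 = build_features(small, anchor_stride=8)
        f2 = build_features(shuffled, anchor_stride=8)
        pd.testing.assert_frame_equal(f1, f2)

    def test_fraction_partition_bound(self, labeled_table):
        for w in ("one_hour", "one_day", "one_week"):
            tot = labeled_table[f"frac_time_low_{w}"] + labeled_table[f"frac_time_high_{w}"]
            assert (tot <= 1.0 + 1e-12).all()

    def test_sparse_window_yields_explicit_missing(self):
        # a week of history, then a 3-hour gap: the first post-gap anchor has
        # a single-reading one-hour window -> delta stats missing, never zero
        minutes = np.concatenate([np.arange(0, 8 * 1440, 5), [8 * 1440 + 180]])
        s = make_stream(minutes, np.full(len(minutes), 150.0))
        feats = build_features(make_cohort([s]), usage_threshold=0.7)
        last = feats.iloc[-1]
        assert last["usage_fraction_one_hour"] == pytest.approx(1 / 12)
        assert pd.isna(last["sd_glucose_one_hour"])
        assert pd.isna(last["largest_increase_one_hour"])
        assert last["mean_glucose_one_hour"] == 150.0

    def test_empty_cohort_gives_empty_table(self):
        feats = build_features(Cohort())
        assert feats.empty
        assert "current_reading" in feats.columns
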