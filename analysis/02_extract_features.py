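#!/usr/bin/env python
"""Compute multi-timescale features at every third eligible reading.

Applies the >=80% prior-week usage filter and reports how many anchors
survive it. Output: results/features.csv.
"""

from pathlib import Path

from cgmrisk.data_io import read_cohort
from cgmrisk.features import build_features

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(BASE / "data" / "streams.csv", BASE / "data" / "profiles.csv")
    feats = build_features(cohort, anchor_stride=3)
    feats.to_csv(BASE / "features.csv", index=False)
    n_sparse = int(feats["sd_glucose_one_hour"].isna().sum())
    print(f"{len(feats)} feature rows across {feats['user_id'].nunique()} users")
    print(f"{n_sparse} rows have a sparse one-hour window (missing trend stats)")
    print(f"wrote {BASE / 'features.csv'}")


if __name__ == "__main__":
    main()
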