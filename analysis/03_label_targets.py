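#!/usr/bin/env python
"""Attach 60-minute ahead-of-time hypo/hyper targets to the feature table.

Removes in-event anchors (reading already <70 or >270 mg/dL) and anchors
with an empty lookahead, then reports the positive-label prevalences.
Output: results/labeled.csv.
"""

from pathlib import Path

import pandas as pd

from cgmrisk.data_io import read_cohort
from cgmrisk.labels import label_examples

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(BASE / "data" / "streams.csv", BASE / "data" / "profiles.csv")
    feats = pd.read_csv(BASE / "features.csv", parse_dates=["anchor_time"])
    labeled = label_examples(feats, cohort, horizon_minutes=60.0)
    labeled.to_csv(BASE / "labeled.csv", index=False)
    print(f"{len(labeled)} labeled rows ({len(feats) - len(labeled)} dropped by exclusion rules)")
    print(f"prevalence: hypo {labeled['y_hypo'].mean():.3%}, hyper {labeled['y_hyper'].mean():.3%}")
    print(f"wrote {BASE / 'labeled.csv'}")


if __name__ == "__main__":
    main()
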