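#!/usr/bin/env python
"""Monthly dashboard for one held-out user: hourly glucose profile with
quartiles, control metrics, and templated recommendations from that
user's top SHAP drivers.

Outputs: results/report_<user>.md and its JSON sidecar.
"""

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from cgmrisk import explain, report
from cgmrisk.data_io import read_cohort

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(BASE / "data" / "streams.csv", BASE / "data" / "profiles.csv")
    labeled = pd.read_csv(BASE / "labeled.csv", parse_dates=["anchor_time"])
    split = json.loads((BASE / "models" / "split.json").read_text())
    uid = split["test_users"][0]
    stream = cohort.streams[uid]
    period = (stream.times[-1] - np.timedelta64(30 * 86400, "s"), stream.times[-1])

    prof = report.hourly_profile(stream, period)
    ctrl = report.control_summary(stream, period)
    rows = labeled[labeled.user_id == uid].reset_index(drop=True)
    summaries = {}
    for target in ("hypo", "hyper"):
        bundle = joblib.load(BASE / "models" / f"{target}_boosted_trees.joblib")
        contribs, _, _ = explain.attribute(bundle, rows)
        summaries[target] = explain.summarize(
            contribs, rows, target=target, scope="user", user_id=uid
        )
    recs = report.build_recommendations(summaries, prof, ctrl, k=2)
    doc, sidecar = report.render_report(uid, period, prof, ctrl, recs)
    report.write_report(BASE / f"report_{uid}.md", BASE / f"report_{uid}.json", doc, sidecar)
    print(f"user {uid}: time-in-range {ctrl.time_in_range:.1%}, "
          f"high peak hour {prof.peak_hour('high')}")
    for r in recs:
        print(f"  [{r.target}] {r.text}")
    print(f"wrote {BASE / f'report_{uid}.md'}")


if __name__ == "__main__":
    main()
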