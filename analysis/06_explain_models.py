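#!/usr/bin/env python
"""Per-prediction TreeSHAP attributions for the boosted-tree models,
aggregated to cohort-level mean-|SHAP| rankings with five-category
roll-ups (device information, demographics, short/medium/long term).

Outputs: results/shap_ranking_<target>.csv, results/explanation_<target>.json.
"""

import json
from pathlib import Path

import joblib
import pandas as pd

from cgmrisk import explain

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    labeled = pd.read_csv(BASE / "labeled.csv", parse_dates=["anchor_time"])
    split = json.loads((BASE / "models" / "split.json").read_text())
    test = labeled[labeled.user_id.isin(split["test_users"])].reset_index(drop=True)
    for target in ("hypo", "hyper"):
        bundle = joblib.load(BASE / "models" / f"{target}_boosted_trees.joblib")
        contribs, _, _ = explain.attribute(bundle, test)
        summary = explain.summarize(contribs, test, target=target)
        explain.ranking_frame(summary).to_csv(BASE / f"shap_ranking_{target}.csv", index=False)
        (BASE / f"explanation_{target}.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True)
        )
        top3 = ", ".join(f"{f} ({v:.3f})" for f, v in summary.ranking[:3])
        cats = ", ".join(f"{c}={v:.2f}" for c, v in sorted(summary.category_fraction.items()))
        print(f"{target}: top features {top3}")
        print(f"{target}: category shares {cats}")


if __name__ == "__main__":
    main()
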