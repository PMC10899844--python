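#!/usr/bin/env python
"""Train the three-model suite per target on a per-person 75/25 split.

Users (never rows) are assigned to train or test; boosted trees are tuned
by seeded random search over user-disjoint 5-fold CV of the training set.
Outputs: results/models/*.joblib with JSON tuning sidecars and the split.
"""

import json
from pathlib import Path

import joblib
import pandas as pd

from cgmrisk import models, tuning
from cgmrisk.data_io import read_cohort

BASE = Path(__file__).resolve().parent.parent / "results"
SPLIT_SEED, MODEL_SEED, BUDGET = 2, 3, 6


def main() -> None:
    cohort = read_cohort(BASE / "data" / "streams.csv", BASE / "data" / "profiles.csv")
    labeled = pd.read_csv(BASE / "labeled.csv", parse_dates=["anchor_time"])
    plan = models.split_by_person(cohort, test_fraction=0.25, seed=SPLIT_SEED)
    train = labeled[labeled.user_id.isin(plan.train_users)].reset_index(drop=True)

    out = BASE / "models"
    out.mkdir(parents=True, exist_ok=True)
    (out / "split.json").write_text(
        json.dumps({"train_users": plan.train_users, "test_users": plan.test_users}, indent=2)
    )
    bundles = models.fit_all(
        train, tuning_budget=BUDGET, seed=MODEL_SEED, search_space=tuning.FAST_SEARCH_SPACE
    )
    for (target, kind), bundle in bundles.items():
        joblib.dump(bundle, out / f"{target}_{kind}.joblib")
        if bundle.tuning_record:
            (out / f"{target}_{kind}_tuning.json").write_text(
                json.dumps(bundle.tuning_record, indent=2)
            )
            print(f"{target}/{kind}: chose {bundle.tuning_record['chosen']}")
    print(f"trained on {len(train)} rows from {len(plan.train_users)} users; wrote {out}")


if __name__ == "__main__":
    main()
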