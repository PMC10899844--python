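"""The three ahead-of-time risk predictors and per-person train/test handling.

Three models of increasing capacity are compared for each target
(hypoglycemia, hyperglycemia):

* a **threshold heuristic** emulating a device alert — hypoglycemia fires
  iff the current reading is below 110 mg/dL, hyperglycemia iff above
  240 mg/dL;
* **L2 logistic regression** (≤300 iterations, class weights inversely
  proportional to class frequencies, continuous features standardized on
  training statistics, categorical features one-hot);
* **gradient-boosted trees** (XGBoost), hyperparameters chosen by seeded
  random search scored with mean average precision over user-disjoint
  5-fold cross-validation of the training set, then refit on the full
  training data. Missing feature values are consumed natively by the trees;
  the logistic model drops incomplete rows.

Users — never rows — are assigned to the train or test side, so no
individual's data leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from xgboost import XGBClassifier

from . import tuning
from .data_io import Cohort
from .evaluation import UndefinedMetricError, average_precision

HEURISTIC_HYPO_THRESHOLD = 110.0
HEURISTIC_HYPER_THRESHOLD = 240.0

#: Columns a feature table may carry beyond the model schema.
METADATA_COLUMNS = {"user_id", "anchor_time", "y_hypo", "y_hyper", "horizon_readings"}

CATEGORICAL_FEATURES = ["gender", "day_of_week"]


class SchemaMismatchError(ValueError):
    pass


class SingleClassError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    train_users: tuple[str, ...]
    test_users: tuple[str, ...]
    seed: int
    test_fraction: float = 0.25


def split_by_person(cohort_or_users, test_fraction: float = 0.25, seed: int = 0) -> SplitPlan:
    """Random user-level partition into train and test sides.

    Every labeled row later inherits its user's side, so an individual's
    complete stream lands on exactly one side of the split.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    users = sorted(
        cohort_or_users.user_ids if isinstance(cohort_or_users, Cohort) else cohort_or_users
    )
    if len(users) < 2:
        raise ValueError("need at least 2 users to split by person")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(users))
    n_test = min(len(users) - 1, max(1, int(round(test_fraction * len(users)))))
    test = tuple(sorted(users[i] for i in order[:n_test]))
    train = tuple(sorted(users[i] for i in order[n_test:]))
    return SplitPlan(train_users=train, test_users=test, seed=seed, test_fraction=test_fraction)


@dataclass
class ModelBundle:
    target: str  # "hypo" | "hyper"
    model_kind: str  # "heuristic" | "logistic" | "boosted_trees"
    feature_names: list[str]
    model: Any = None
    tuning_record: dict = field(default_factory=dict)
    seed: int = 0

    def _check_schema(self, rows: pd.DataFrame) -> None:
        from .features import feature_columns

        cols = set(rows.columns)
        missing = [c for c in self.feature_names if c not in cols]
        # standard feature columns a wider table may carry are fine;
        # anything unrecognized signals a schema mixup
        allowed = set(self.feature_names) | METADATA_COLUMNS | set(feature_columns(extended=True))
        extra = sorted(cols - allowed)
        if missing or extra:
            raise SchemaMismatchError(
                f"feature schema mismatch: missing columns {missing}, extra columns {extra}"
            )


def predict_heuristic(reading, target: str):
    """Device-alert baseline: fires iff the current reading crosses the
    alert threshold (strictly below 110 for hypo, strictly above 240 for
    hyper).

    Also returns a pseudo-probability — a strictly monotone transform of
    the distance past the threshold, calibrated so p >= 0.5 exactly when
    the alert fires. Any monotone transform yields the same ROC; this one
    additionally makes dichotomization at P=.5 agree with the alert rule.
    """
    g = np.asarray(reading, dtype=float)
    if target == "hypo":
        fires = g < HEURISTIC_HYPO_THRESHOLD
        p_fire = 0.5 + 0.5 * np.minimum(1.0, (HEURISTIC_HYPO_THRESHOLD - g) / 70.0)
        p_quiet = 0.5 * np.clip((400.0 - g) / (400.0 - HEURISTIC_HYPO_THRESHOLD), 0.0, 1.0)
    elif target == "hyper":
        fires = g > HEURISTIC_HYPER_THRESHOLD
        p_fire = 0.5 + 0.5 * np.minimum(1.0, (g - HEURISTIC_HYPER_THRESHOLD) / 80.0)
        p_quiet = 0.5 * np.clip((g - 40.0) / (HEURISTIC_HYPER_THRESHOLD - 40.0), 0.0, 1.0)
    else:
        raise ValueError(f"unknown target {target!r}")
    # keep the non-firing branch strictly below 0.5 so thresholding at 0.5
    # reproduces the strict alert rule even at the boundary reading
    prob = np.where(fires, p_fire, p_quiet * (1.0 - 1e-9))
    return fires, prob


def make_heuristic_bundle(target: str) -> ModelBundle:
    return ModelBundle(target=target, model_kind="heuristic", feature_names=["current_reading"])


def _design_columns(feature_names: list[str]):
    cat = [c for c in CATEGORICAL_FEATURES if c in feature_names]
    num = [c for c in feature_names if c not in cat]
    return num, cat


def encode_for_trees(rows: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    """Numeric design matrix for tree models; gender ordinal, NaN preserved."""
    X = rows[feature_names].copy()
    if "gender" in X.columns:
        X["gender"] = X["gender"].map({"F": 0.0, "M": 1.0}).astype(float)
    return X.astype(float)


def _class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights: w_c = n_total / (2 * n_c)."""
    n = len(y)
    return {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}


def fit_logistic(train: pd.DataFrame, target: str, seed: int = 0) -> ModelBundle:
    """L2-penalized logistic regression on complete rows.

    Continuous features are standardized on training statistics; gender and
    day-of-week are one-hot encoded. Optimization is capped at 300
    iterations with class weights inversely proportional to class
    frequencies.
    """
    from .features import feature_columns

    names = [c for c in feature_columns(extended=True) if c in train.columns]
    y_col = f"y_{target}"
    rows = train.dropna(subset=names)
    # canonical row order -> fitting is exactly invariant to input order
    sort_keys = [c for c in ("user_id", "anchor_time") if c in rows.columns]
    rows = rows.sort_values(sort_keys, kind="mergesort") if sort_keys else rows.sort_index()
    y = rows[y_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(f"training data for target {target!r} has a single class")
    num, cat = _design_columns(names)
    pre = ColumnTransformer(
        [
            ("num", StandardScaler(), num),
            ("cat", OneHotEncoder(handle_unknown="ignore"), cat),
        ]
    )
    clf = LogisticRegression(  # default penalty is L2
        max_iter=300,
        class_weight=_class_weights(y),
        solver="lbfgs",
        tol=1e-8,
        random_state=seed,
    )
    pipe = Pipeline([("pre", pre), ("clf", clf)])
    pipe.fit(rows[names], y)
    return ModelBundle(target=target, model_kind="logistic", feature_names=names, model=pipe, seed=seed)


def _make_xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        **params,
    )


def fit_boosted_trees(
    train: pd.DataFrame,
    target: str,
    tuning_budget: int = 20,
    seed: int = 0,
    search_space: dict | None = None,
    n_folds: int = 5,
) -> ModelBundle:
    """CV-tuned gradient-boosted trees.

    Hyperparameters maximize mean average precision over ``n_folds``
    user-disjoint folds of the training set (seeded random search); the
    final model is refit on the full training data with the chosen values.
    Missing feature values are handled natively by the trees.
    """
    from .features import feature_columns

    if tuning_budget < 1:
        raise ValueError("tuning budget must be >= 1")
    space = tuning.DEFAULT_SEARCH_SPACE if search_space is None else search_space
    names = [c for c in feature_columns(extended=True) if c in train.columns]
    y_col = f"y_{target}"
    y = train[y_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(f"training data for target {target!r} has a single class")
    X = encode_for_trees(train, names)
    groups = train["user_id"].to_numpy()
    n_folds = min(n_folds, len(np.unique(groups)))
    splitter = GroupKFold(n_splits=n_folds)
    folds = []
    for tr, va in splitter.split(X, y, groups):
        assert not set(groups[tr]) & set(groups[va]), "CV folds must be user-disjoint"
        if len(np.unique(y[tr])) == 2 and y[va].sum() > 0:
            folds.append((tr, va))
    if not folds:
        raise SingleClassError(f"no usable CV folds for target {target!r}")

    def objective(params: dict) -> float:
        scores = []
        for tr, va in folds:
            m = _make_xgb(params, seed)
            m.fit(X.iloc[tr], y[tr])
            p = m.predict_proba(X.iloc[va])[:, 1]
            scores.append(average_precision(p, y[va]))
        return float(np.mean(scores))

    best, record = tuning.random_search(objective, space, tuning_budget, seed)
    final = _make_xgb(best, seed)
    final.fit(X, y)
    bundle = ModelBundle(
        target=target,
        model_kind="boosted_trees",
        feature_names=names,
        model=final,
        tuning_record={
            "space": {k: list(v) for k, v in space.items()},
            "objective": "mean CV average precision",
            "n_folds": len(folds),
            "trials": record,
            "chosen": best,
        },
        seed=seed,
    )
    return bundle


def predict(bundle: ModelBundle, rows: pd.DataFrame) -> np.ndarray:
    """Per-row event probability under the bundle; deterministic."""
    bundle._check_schema(rows)
    if bundle.model_kind == "heuristic":
        _, prob = predict_heuristic(rows["current_reading"].to_numpy(), bundle.target)
        return prob
    if bundle.model_kind == "logistic":
        return bundle.model.predict_proba(rows[bundle.feature_names])[:, 1]
    if bundle.model_kind == "boosted_trees":
        X = encode_for_trees(rows, bundle.feature_names)
        return bundle.model.predict_proba(X)[:, 1]
    raise ValueError(f"unknown model kind {bundle.model_kind!r}")


def fit_all(
    train: pd.DataFrame,
    targets=("hypo", "hyper"),
    tuning_budget: int = 20,
    seed: int = 0,
    search_space: dict | None = None,
) -> dict[tuple[str, str], ModelBundle]:
    """Fit the full three-model suite for each target."""
    bundles: dict[tuple[str, str], ModelBundle] = {}
    for target in targets:
        bundles[(target, "heuristic")] = make_heuristic_bundle(target)
        bundles[(target, "logistic")] = fit_logistic(train, target, seed=seed)
        bundles[(target, "boosted_trees")] = fit_boosted_trees(
            train, target, tuning_budget=tuning_budget, seed=seed, search_space=search_space
        )
    return bundles
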