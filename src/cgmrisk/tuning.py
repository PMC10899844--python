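"""Seeded random-search hyperparameter tuner with user-disjoint CV folds.

The search space is a dict of ``name -> ("int"|"float"|"logfloat", low,
high)``; each trial draws one configuration, scores it by mean average
precision over user-disjoint cross-validation folds of the training set,
and the full trial record (space, draws, fold scores) is retained in the
model bundle so the search is auditable.
"""

from __future__ import annotations

import numpy as np

# Broad default space for gradient-boosted trees.
DEFAULT_SEARCH_SPACE = {
    "max_depth": ("int", 2, 10),
    "learning_rate": ("logfloat", 1e-3, 0.3),
    "n_estimators": ("int", 50, 1000),
    "min_child_weight": ("float", 1.0, 10.0),
    "subsample": ("float", 0.5, 1.0),
    "colsample_bytree": ("float", 0.5, 1.0),
    "reg_alpha": ("logfloat", 1e-8, 1.0),
    "reg_lambda": ("logfloat", 1e-8, 10.0),
}

# Reduced space for desk-scale cohorts: shallower trees, fewer rounds.
FAST_SEARCH_SPACE = {
    "max_depth": ("int", 2, 6),
    "learning_rate": ("logfloat", 0.03, 0.3),
    "n_estimators": ("int", 60, 200),
    "min_child_weight": ("float", 1.0, 10.0),
    "subsample": ("float", 0.6, 1.0),
    "colsample_bytree": ("float", 0.6, 1.0),
    "reg_lambda": ("logfloat", 1e-3, 10.0),
}


def sample_params(space: dict, rng: np.random.Generator) -> dict:
    """Draw one configuration; parameters are sampled in sorted-name order."""
    params = {}
    for name in sorted(space):
        kind, lo, hi = space[name]
        if kind == "int":
            params[name] = int(rng.integers(lo, hi + 1))
        elif kind == "float":
            params[name] = float(rng.uniform(lo, hi))
        elif kind == "logfloat":
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            raise ValueError(f"unknown parameter kind {kind!r} for {name!r}")
    return params


def random_search(
    objective, space: dict, n_trials: int, seed: int
) -> tuple[dict, list[dict]]:
    """Maximize ``objective(params) -> score`` over ``n_trials`` seeded draws.

    Returns (best params, trial record). Ties keep the earliest trial.
    """
    if n_trials < 1:
        raise ValueError("tuning budget must be at least 1 trial")
    rng = np.random.default_rng(seed)
    record = []
    best, best_score = None, -np.inf
    for t in range(n_trials):
        params = sample_params(space, rng)
        score = float(objective(params))
        record.append({"trial": t, "params": params, "score": score})
        if score > best_score:
            best, best_score = params, score
    return dict(best), record
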