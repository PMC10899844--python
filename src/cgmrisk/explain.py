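"""Per-prediction Shapley attributions for the tree model and their
aggregation into per-user / cohort importance rankings.

Attributions come from exact TreeSHAP (the tree-path-dependent algorithm,
computed natively by XGBoost) on the margin (log-odds) scale, where local
accuracy is exact: the base value plus all per-feature attributions equals
the model's margin output for that row. Ranking a feature by the mean of
|attribution| over rows gives its importance; features roll up into five
categories — device information, demographics, and the short/medium/long
window groups — whose fractional contributions sum to one.

The category mapping is a config file (``config/categories.yaml``) so it
can be edited without touching logic. Only the boosted-tree model is
attributed; logistic coefficients are available on their bundle directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import xgboost
import yaml

from .models import ModelBundle, encode_for_trees

CATEGORIES = ["device_information", "demographics", "short_term", "medium_term", "long_term"]


class UnsupportedModelError(TypeError):
    pass


def load_category_config() -> dict:
    with resources.files("cgmrisk.config").joinpath("categories.yaml").open() as fh:
        return yaml.safe_load(fh)


def categorize(feature_names: list[str], config: dict | None = None) -> dict[str, str]:
    """Map every schema feature to exactly one category (partition asserted)."""
    config = load_category_config() if config is None else config
    static = {f: cat for cat, feats in config["static"].items() for f in feats}
    suffixes = config["window_suffixes"]
    mapping: dict[str, str] = {}
    for name in feature_names:
        if name in static:
            mapping[name] = static[name]
            continue
        for suffix, cat in suffixes.items():
            if name.endswith("_" + suffix):
                mapping[name] = cat
                break
        else:
            raise ValueError(f"feature {name!r} not covered by the category config")
    return mapping


def attribute(bundle: ModelBundle, rows: pd.DataFrame):
    """Exact per-row TreeSHAP attributions on the margin scale.

    Returns ``(contribs, base_values, margins)`` where ``contribs`` is a
    DataFrame with one column per schema feature. For every row,
    ``base + contribs.sum(axis=1)`` equals the model margin.
    """
    if bundle.model_kind != "boosted_trees":
        raise UnsupportedModelError(
            f"attributions are only computed for boosted trees, got {bundle.model_kind!r}"
        )
    X = encode_for_trees(rows, bundle.feature_names)
    booster = bundle.model.get_booster()
    dm = xgboost.DMatrix(X, feature_names=bundle.feature_names)
    raw = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    contribs = pd.DataFrame(
        raw[:, :-1].astype(np.float64), columns=bundle.feature_names, index=rows.index
    )
    base = raw[:, -1].astype(float)
    return contribs, base, np.asarray(margins, dtype=float)


@dataclass
class ExplanationSummary:
    scope: str  # "cohort" | "user"
    target: str
    user_id: str | None
    period: tuple
    mean_abs_shap: dict[str, float]
    category_fraction: dict[str, float]
    ranking: list[tuple[str, float]] = field(default_factory=list)
    n_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "target": self.target,
            "user_id": self.user_id,
            "period": [str(p) for p in self.period],
            "mean_abs_shap": self.mean_abs_shap,
            "category_fraction": self.category_fraction,
            "ranking": [[f, v] for f, v in self.ranking],
            "n_rows": self.n_rows,
        }


def summarize(
    contribs: pd.DataFrame,
    meta: pd.DataFrame,
    target: str,
    scope: str = "cohort",
    user_id: str | None = None,
    period: tuple | None = None,
    categories: dict[str, str] | None = None,
) -> ExplanationSummary:
    """Mean-|SHAP| feature ranking with category roll-ups.

    ``meta`` aligns with ``contribs`` and provides ``user_id`` and
    ``anchor_time`` for scoping. Category fraction = (sum of member
    feature means) / (sum of all feature means). Ranking is by descending
    mean |SHAP|, ties broken lexicographically.
    """
    sel = pd.Series(True, index=contribs.index)
    if scope == "user":
        if user_id is None:
            raise ValueError("user scope requires a user_id")
        sel &= meta["user_id"] == user_id
    if period is not None:
        t = meta["anchor_time"]
        sel &= (t >= np.datetime64(period[0], "s")) & (t <= np.datetime64(period[1], "s"))
    if not sel.any():
        raise ValueError(f"no attribution rows for scope={scope!r} user={user_id!r} period={period!r}")
    sub = contribs.loc[sel]
    mean_abs = sub.abs().mean(axis=0)
    categories = categorize(list(contribs.columns)) if categories is None else categories
    total = float(mean_abs.sum())
    frac = {c: 0.0 for c in CATEGORIES}
    for f, v in mean_abs.items():
        frac[categories[f]] += float(v)
    if total > 0:
        frac = {c: v / total for c, v in frac.items()}
    ranking = sorted(mean_abs.items(), key=lambda kv: (-kv[1], kv[0]))
    if period is None:
        t = meta.loc[sel, "anchor_time"]
        period = (t.min(), t.max())
    return ExplanationSummary(
        scope=scope,
        target=target,
        user_id=user_id,
        period=tuple(period),
        mean_abs_shap={f: float(v) for f, v in mean_abs.items()},
        category_fraction=frac,
        ranking=[(f, float(v)) for f, v in ranking],
        n_rows=int(sel.sum()),
    )


def top_features(summary: ExplanationSummary, k: int) -> list[tuple[str, float]]:
    """First ``k`` of the ranked list (full list if k exceeds the schema)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return summary.ranking[: min(k, len(summary.ranking))]


def ranking_frame(summary: ExplanationSummary, categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Bar-ranking table: feature, category, mean |SHAP|."""
    categories = categorize([f for f, _ in summary.ranking]) if categories is None else categories
    return pd.DataFrame(
        [
            {"feature": f, "category": categories[f], "mean_abs_shap": v}
            for f, v in summary.ranking
        ]
    )
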