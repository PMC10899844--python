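"""Held-out evaluation: AUROC, average precision, sensitivity/specificity
at a fixed probability threshold, and percentile bootstrap confidence
intervals (default 500 resamples).

All models are scored on the *same* complete-case test rows so comparisons
are fair; the bootstrap resamples rows with replacement (a user-level
cluster bootstrap is available since rows within a user are autocorrelated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


class UndefinedMetricError(ValueError):
    """Metric has no value on this sample (e.g. a single class present)."""


def roc_auc(scores, labels) -> float:
    """Rank-based AUROC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def average_precision(scores, labels) -> float:
    """Step-wise integral of precision over recall."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("average precision undefined: no positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def sens_spec_at(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """(sensitivity, specificity) after calling score >= threshold positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = np.sum(pred & labels)
    fn = np.sum(~pred & labels)
    tn = np.sum(~pred & ~labels)
    fp = np.sum(pred & ~labels)
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return float(sens), float(spec)


def bootstrap_ci(
    scores,
    labels,
    metric,
    n_resamples: int = 500,
    seed: int = 0,
    clusters=None,
) -> tuple[float, float]:
    """Percentile 95% CI of ``metric(scores, labels)`` over resamples.

    Rows are resampled with replacement; with ``clusters`` given, whole
    clusters (users) are resampled instead. Resamples on which the metric is
    undefined are redrawn (count capped at 20x the requested resamples).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    metric(scores, labels)  # must be defined on the full sample
    rng = np.random.default_rng(seed)
    if clusters is not None:
        clusters = np.asarray(clusters)
        uniq = np.unique(clusters)
        members = {c: np.nonzero(clusters == c)[0] for c in uniq}
    stats = []
    attempts = 0
    max_attempts = 20 * n_resamples
    while len(stats) < n_resamples and attempts < max_attempts:
        attempts += 1
        if clusters is None:
            idx = rng.integers(0, len(scores), len(scores))
        else:
            picked = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([members[c] for c in picked])
        try:
            stats.append(metric(scores[idx], labels[idx]))
        except UndefinedMetricError:
            continue
    if len(stats) < n_resamples:
        raise UndefinedMetricError("bootstrap: metric undefined on too many resamples")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class EvaluationReport:
    target: str
    model_kind: str
    auroc: float
    average_precision: float
    sensitivity: float
    specificity: float
    threshold: float
    ci_auroc: tuple[float, float]
    ci_ap: tuple[float, float]
    n_rows: int
    n_positives: int
    n_resamples: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        d = json.loads(s)
        d["ci_auroc"] = tuple(d["ci_auroc"])
        d["ci_ap"] = tuple(d["ci_ap"])
        return cls(**d)


def complete_case_test_set(test: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    """Shared evaluation rows: test rows with no missing feature values."""
    return test.dropna(subset=[c for c in feature_names if c in test.columns]).reset_index(
        drop=True
    )


def evaluate_all(
    bundles: dict,
    test: pd.DataFrame,
    threshold: float = 0.5,
    n_resamples: int = 500,
    seed: int = 0,
) -> list[EvaluationReport]:
    """One report per (target, model) on the identical complete-case row set."""
    from .models import predict

    if test.empty:
        raise ValueError("empty test set")
    schemas = {tuple(b.feature_names) for b in bundles.values() if b.model_kind != "heuristic"}
    names = sorted(set().union(*schemas)) if schemas else ["current_reading"]
    shared = complete_case_test_set(test, names)
    if shared.empty:
        raise ValueError("no complete-case rows in the test set")
    reports = []
    for (target, kind), bundle in sorted(bundles.items()):
        y = shared[f"y_{target}"].to_numpy(dtype=int)
        p = predict(bundle, shared)
        sens, spec = sens_spec_at(p, y, threshold)
        reports.append(
            EvaluationReport(
                target=target,
                model_kind=kind,
                auroc=roc_auc(p, y),
                average_precision=average_precision(p, y),
                sensitivity=sens,
                specificity=spec,
                threshold=threshold,
                ci_auroc=bootstrap_ci(p, y, roc_auc, n_resamples, seed),
                ci_ap=bootstrap_ci(p, y, average_precision, n_resamples, seed),
                n_rows=int(len(y)),
                n_positives=int(y.sum()),
                n_resamples=n_resamples,
            )
        )
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Performance table shaped like the standard model-comparison summary."""
    rows = []
    for r in reports:
        d = asdict(r)
        d["ci_auroc_lo"], d["ci_auroc_hi"] = d.pop("ci_auroc")
        d["ci_ap_lo"], d["ci_ap_hi"] = d.pop("ci_ap")
        rows.append(d)
    return pd.DataFrame(rows)
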