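"""End-to-end orchestration: simulate → featurize → label → split → train →
evaluate → explain → report, as one reproducible, file-backed run.

A run is fully determined by its :class:`RunConfig` (which embeds the
simulator seed and all stage settings); the manifest records the config
hash, per-stage row counts, every evaluation report, horizon summaries and
top explanation features, so two runs from one config produce identical
manifests. Every data-shaping exclusion (usage filter, in-event removal,
empty lookahead, missing values) is visible in the row-count accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, explain, labels, models, report, synthetic, tuning
from .data_io import write_cohort
from .features import build_features

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: synthetic.SimConfig = field(default_factory=synthetic.emulate_city_defaults)
    usage_threshold: float = 0.8
    extended_features: bool = False
    anchor_stride: int = 1
    horizon_minutes: float = 60.0
    tuning_budget: int = 8
    search_space: str = "fast"  # "fast" | "full"
    model_seed: int = 7
    eval_threshold: float = 0.5
    n_resamples: int = 500
    test_fraction: float = 0.25
    split_seed: int = 11
    top_k: int = 2
    write_intermediates: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["hba1c_range"] = list(d["sim"]["hba1c_range"])
        d["sim"]["age_range"] = list(d["sim"]["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if not isinstance(sim, synthetic.SimConfig):
            sim = dict(sim)
            for k in ("hba1c_range", "age_range"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            sim = synthetic.SimConfig(**sim)
        return cls(sim=sim, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _horizon_summaries(bundles, labeled_test, cohort, plan, cfg):
    out = {}
    for target in ("hypo", "hyper"):
        preds = labeled_test[["user_id", "anchor_time"]].copy()
        preds["probability"] = models.predict(bundles[(target, "boosted_trees")], labeled_test)
        events = [
            ev
            for uid in plan.test_users
            for ev in labels.extract_events(cohort.streams[uid])
            if ev.event_type == target
        ]
        table, summary = labels.prediction_horizons(
            events, preds, threshold=cfg.eval_threshold, lookback_minutes=cfg.horizon_minutes
        )
        out[target] = {"summary": summary, "table": table}
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage, write artifacts under ``out_dir``, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "config_hash": config.config_hash(), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # partial outputs are retained for debugging
                manifest["stages"][name] = {"status": "failed", "error": str(e)}
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
                raise StageError(name, e) from e

        return deco

    @stage("simulate")
    def _sim():
        cohort, truth = synthetic.simulate_cohort(config.sim)
        write_cohort(cohort, out / "streams.csv", out / "profiles.csv")
        truth.to_frame().to_csv(out / "truth_events.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_users": len(cohort),
            "n_readings": int(sum(len(s) for s in cohort.streams.values())),
            "n_truth_hypo": truth.count("hypo"),
            "n_truth_hyper": truth.count("hyper"),
        }
        return cohort, truth

    cohort, truth = _sim

    @stage("featurize")
    def _feat():
        feats = build_features(
            cohort,
            usage_threshold=config.usage_threshold,
            extended=config.extended_features,
            anchor_stride=config.anchor_stride,
        )
        manifest["stages"]["featurize"] = {"n_rows": int(len(feats))}
        return feats

    feats = _feat

    @stage("label")
    def _label():
        labeled = labels.label_examples(feats, cohort, horizon_minutes=config.horizon_minutes)
        if config.write_intermediates:
            labeled.to_csv(out / "labeled.csv", index=False)
        manifest["stages"]["label"] = {
            "horizon_minutes": config.horizon_minutes,
            "n_rows": int(len(labeled)),
            "n_dropped": int(len(feats) - len(labeled)),
            "prevalence_hypo": float(labeled["y_hypo"].mean()),
            "prevalence_hyper": float(labeled["y_hyper"].mean()),
        }
        return labeled

    labeled = _label

    @stage("split")
    def _split():
        plan = models.split_by_person(cohort, config.test_fraction, config.split_seed)
        manifest["stages"]["split"] = {
            "train_users": list(plan.train_users),
            "test_users": list(plan.test_users),
        }
        return plan

    plan = _split
    train = labeled[labeled["user_id"].isin(plan.train_users)].reset_index(drop=True)
    test = labeled[labeled["user_id"].isin(plan.test_users)].reset_index(drop=True)

    @stage("train")
    def _train():
        space = tuning.FAST_SEARCH_SPACE if config.search_space == "fast" else tuning.DEFAULT_SEARCH_SPACE
        bundles = models.fit_all(
            train, tuning_budget=config.tuning_budget, seed=config.model_seed, search_space=space
        )
        manifest["stages"]["train"] = {
            "n_train_rows": int(len(train)),
            "tuning": {
                f"{t}_{k}": b.tuning_record.get("chosen")
                for (t, k), b in bundles.items()
                if b.tuning_record
            },
        }
        return bundles

    bundles = _train

    @stage("evaluate")
    def _eval():
        reports = evaluation.evaluate_all(
            bundles, test, threshold=config.eval_threshold,
            n_resamples=config.n_resamples, seed=config.model_seed,
        )
        frame = evaluation.reports_to_frame(reports)
        frame.to_csv(out / "model_performance.csv", index=False)
        manifest["stages"]["evaluate"] = {
            "n_test_rows_shared": int(reports[0].n_rows),
            "reports": [json.loads(r.to_json()) for r in reports],
        }
        return reports

    _ = _eval

    @stage("horizons")
    def _hor():
        hz = _horizon_summaries(bundles, test, cohort, plan, config)
        for target, d in hz.items():
            d["table"].to_csv(out / f"horizons_{target}.csv", index=False)
        manifest["stages"]["horizons"] = {t: d["summary"] for t, d in hz.items()}
        return hz

    _ = _hor

    @stage("explain")
    def _explain():
        summaries = {}
        for target in ("hypo", "hyper"):
            contribs, base, _m = explain.attribute(bundles[(target, "boosted_trees")], test)
            summary = explain.summarize(contribs, test, target=target, scope="cohort")
            summaries[target] = summary
            explain.ranking_frame(summary).to_csv(out / f"shap_ranking_{target}.csv", index=False)
            with open(out / f"explanation_{target}.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        manifest["stages"]["explain"] = {
            t: {
                "top_feature": s.ranking[0][0],
                "category_fraction": s.category_fraction,
            }
            for t, s in summaries.items()
        }
        return summaries

    cohort_summaries = _explain

    @stage("report")
    def _report():
        uid = plan.test_users[0]
        stream = cohort.streams[uid]
        end = stream.times[-1]
        start = end - np.timedelta64(30 * 86400, "s")
        period = (start, end)
        prof = report.hourly_profile(stream, period)
        ctrl = report.control_summary(stream, period)
        user_rows = test["user_id"] == uid
        user_summaries = {}
        for target in ("hypo", "hyper"):
            contribs, _b, _m = explain.attribute(
                bundles[(target, "boosted_trees")], test.loc[user_rows]
            )
            user_summaries[target] = explain.summarize(
                contribs, test.loc[user_rows], target=target, scope="user", user_id=uid
            )
        recs = report.build_recommendations(user_summaries, prof, ctrl, k=config.top_k)
        doc, sidecar = report.render_report(uid, period, prof, ctrl, recs)
        report.write_report(out / f"report_{uid}.md", out / f"report_{uid}.json", doc, sidecar)
        manifest["stages"]["report"] = {"user_id": uid, "n_recommendations": len(recs)}
        return sidecar

    _ = _report

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
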