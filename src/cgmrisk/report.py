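"""Per-user monthly dashboard artifacts: hourly glucose profile with
quartiles, hourly high/low fractions, summary control metrics, and
templated control recommendations derived from the user's top explanation
features.

All "time" metrics here are fractions of observed readings (consistent
with the feature engine), quartiles use the linear-interpolation percentile
definition, and every number rendered in the document is read from the
machine-readable sidecar — the renderer computes nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .data_io import CGMStream
from .explain import ExplanationSummary, top_features
from .features import HIGH_THRESHOLD, LOW_THRESHOLD

logger = logging.getLogger(__name__)


def _period_slice(stream: CGMStream, period) -> tuple[np.ndarray, np.ndarray]:
    lo = np.datetime64(period[0], "s")
    hi = np.datetime64(period[1], "s")
    sel = (stream.times >= lo) & (stream.times <= hi)
    return stream.times[sel], stream.glucose[sel]


@dataclass
class HourlyProfile:
    """Per hour-of-day aggregates over a period; empty hours are NaN."""

    mean: np.ndarray  # shape (24,)
    q25: np.ndarray
    q75: np.ndarray
    frac_high: np.ndarray
    frac_low: np.ndarray
    n_readings: np.ndarray

    def peak_hour(self, which: str) -> int | None:
        arr = self.frac_high if which == "high" else self.frac_low
        if np.all(np.isnan(arr)) or np.nanmax(arr) == 0:
            return None
        return int(np.nanargmax(arr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hour": np.arange(24),
                "mean_glucose": self.mean,
                "q25": self.q25,
                "q75": self.q75,
                "frac_high": self.frac_high,
                "frac_low": self.frac_low,
                "n_readings": self.n_readings,
            }
        )


def hourly_profile(stream: CGMStream, period) -> HourlyProfile:
    times, glucose = _period_slice(stream, period)
    if times.size == 0:
        raise ValueError("no readings in the requested period")
    hours = (times.astype(np.int64) % 86400) // 3600
    shape = (24,)
    mean = np.full(shape, np.nan)
    q25 = np.full(shape, np.nan)
    q75 = np.full(shape, np.nan)
    fh = np.full(shape, np.nan)
    fl = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=np.int64)
    for h in range(24):
        g = glucose[hours == h]
        n[h] = g.size
        if g.size == 0:
            continue
        mean[h] = g.mean()
        q25[h], q75[h] = np.percentile(g, [25, 75])  # linear interpolation
        fh[h] = float((g > HIGH_THRESHOLD).sum()) / g.size
        fl[h] = float((g < LOW_THRESHOLD).sum()) / g.size
    return HourlyProfile(mean=mean, q25=q25, q75=q75, frac_high=fh, frac_low=fl, n_readings=n)


@dataclass
class ControlSummary:
    period: tuple
    time_in_range: float
    time_high: float
    time_low: float
    usage_fraction: float
    mean_glucose: float
    sd_glucose: float
    n_readings: int


def control_summary(stream: CGMStream, period, cadence_minutes: float | None = None) -> ControlSummary:
    """Reading-count control metrics; in-range is 70 <= G <= 270 mg/dL,
    so time_in_range + time_high + time_low = 1 exactly."""
    times, glucose = _period_slice(stream, period)
    cadence = stream.cadence_minutes if cadence_minutes is None else cadence_minutes
    span_min = (np.datetime64(period[1], "s") - np.datetime64(period[0], "s")) / np.timedelta64(
        60, "s"
    )
    expected = max(1.0, float(span_min) / cadence)
    if glucose.size == 0:
        return ControlSummary(tuple(period), np.nan, np.nan, np.nan, 0.0, np.nan, np.nan, 0)
    high = float((glucose > HIGH_THRESHOLD).sum()) / glucose.size
    low = float((glucose < LOW_THRESHOLD).sum()) / glucose.size
    return ControlSummary(
        period=tuple(period),
        time_in_range=1.0 - high - low,
        time_high=high,
        time_low=low,
        usage_fraction=min(1.0, glucose.size / expected),
        mean_glucose=float(glucose.mean()),
        sd_glucose=float(glucose.std(ddof=0)),
        n_readings=int(glucose.size),
    )


@dataclass
class Recommendation:
    target: str
    driver_feature: str
    mean_abs_shap: float
    text: str


def load_templates() -> dict:
    with resources.files("cgmrisk.config").joinpath("templates.yaml").open() as fh:
        return yaml.safe_load(fh)


def _base_name(feature: str) -> tuple[str, str]:
    for suffix in ("one_hour", "one_day", "one_week"):
        if feature.endswith("_" + suffix):
            return feature[: -len(suffix) - 1], suffix.replace("_", "-")
    return feature, ""


def build_recommendations(
    summaries: dict[str, ExplanationSummary],
    profile: HourlyProfile,
    control: ControlSummary,
    k: int = 2,
    templates: dict | None = None,
) -> list[Recommendation]:
    """Top-k explanation drivers per target, rendered through the template table."""
    if k == 0:
        return []
    templates = load_templates() if templates is None else templates
    peak_high = profile.peak_hour("high")
    peak_low = profile.peak_hour("low")
    ctx_base = {
        "time_low": control.time_low,
        "time_high": control.time_high,
        "time_in_range": control.time_in_range,
        "mean_glucose": control.mean_glucose,
        "peak_high_hour": "unclear" if peak_high is None else peak_high,
        "peak_low_hour": "unclear" if peak_low is None else peak_low,
    }
    recs: list[Recommendation] = []
    for target in sorted(summaries):
        summary = summaries[target]
        for feature, value in top_features(summary, k):
            base, window = _base_name(feature)
            table = templates.get(target, {})
            template = table.get(base)
            if template is None:
                logger.info("no template for feature %r (target %s); using fallback", feature, target)
                template = table.get("generic", "Most associated driver: {feature}.")
            text = template.format(feature=feature, window=window, **ctx_base).strip()
            recs.append(
                Recommendation(
                    target=target, driver_feature=feature, mean_abs_shap=value, text=text
                )
            )
    return recs


def render_report(
    user_id: str,
    period,
    profile: HourlyProfile,
    control: ControlSummary,
    recommendations: list[Recommendation],
) -> tuple[str, dict]:
    """Markdown dashboard document plus a JSON-serializable sidecar.

    The sidecar is the single source of truth: every number in the document
    is formatted from sidecar fields.
    """
    sidecar = {
        "user_id": user_id,
        "period": [str(period[0]), str(period[1])],
        "control": {
            "time_in_range": control.time_in_range,
            "time_high": control.time_high,
            "time_low": control.time_low,
            "usage_fraction": control.usage_fraction,
            "mean_glucose": control.mean_glucose,
            "sd_glucose": control.sd_glucose,
            "n_readings": control.n_readings,
        },
        "hourly_profile": {
            k: [None if (isinstance(v, float) and np.isnan(v)) else v for v in arr]
            for k, arr in profile.to_frame().to_dict(orient="list").items()
        },
        "recommendations": [
            {
                "target": r.target,
                "driver_feature": r.driver_feature,
                "mean_abs_shap": r.mean_abs_shap,
                "text": r.text,
            }
            for r in recommendations
        ],
    }
    c = sidecar["control"]
    lines = [
        f"# CGM summary for {user_id}",
        f"Period: {sidecar['period'][0]} to {sidecar['period'][1]}",
        "",
        "## Glucose control",
        f"- Time in range (70-270 mg/dL): {c['time_in_range']:.1%}",
        f"- Time above 270 mg/dL: {c['time_high']:.1%}",
        f"- Time below 70 mg/dL: {c['time_low']:.1%}",
        f"- Device usage: {c['usage_fraction']:.1%}",
        f"- Mean glucose: {c['mean_glucose']:.1f} mg/dL (SD {c['sd_glucose']:.1f})",
        "",
        "## Hourly profile (mean [q25-q75], % high, % low)",
    ]
    hp = sidecar["hourly_profile"]
    for h in range(24):
        if hp["n_readings"][h] == 0:
            lines.append(f"- {h:02d}:00 — no readings")
            continue
        lines.append(
            f"- {h:02d}:00 — {hp['mean_glucose'][h]:.0f} "
            f"[{hp['q25'][h]:.0f}-{hp['q75'][h]:.0f}] mg/dL, "
            f"high {hp['frac_high'][h]:.1%}, low {hp['frac_low'][h]:.1%}"
        )
    lines += ["", "## Control recommendations"]
    if sidecar["recommendations"]:
        for r in sidecar["recommendations"]:
            lines.append(f"- **{r['target']}** (driver: `{r['driver_feature']}`): {r['text']}")
    else:
        lines.append("- No risk drivers identified for this period.")
    lines += [
        "",
        "_All time metrics are fractions of observed readings; quartiles use "
        "linear-interpolation percentiles. Recommendations are derived from "
        "model explanations and are not medical advice._",
    ]
    return "\n".join(lines) + "\n", sidecar


def write_report(path_md, path_json, document: str, sidecar: dict) -> None:
    with open(path_md, "w") as fh:
        fh.write(document)
    with open(path_json, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
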