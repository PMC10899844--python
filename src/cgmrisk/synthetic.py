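"""Seeded synthetic CGM cohort generator.

Emulates the statistical structure of a young-adult type-1-diabetes CGM
cohort (ages 14-<25, HbA1c 7.5-<11%, 5-minute cadence, months of wear):
per-user mean glucose tied to HbA1c through the standard eAG linear map,
a circadian sinusoid, gamma-shaped meal excursions at breakfast/lunch/dinner
anchors with jitter, post-meal insulin-correction dips whose depth is
amplified by ``hypo_propensity`` (occasionally undershooting 70 mg/dL),
meal-amplitude tail boosts governed by ``hyper_propensity`` (excursions
above 270 mg/dL), AR(1) observation noise, Bernoulli dropout, and periodic
sensor-swap gaps.

The generator is phenomenological, not physiological — no insulin-glucose
ODE kinetics and no sensor-error (MARD) model. Ground-truth hypo/hyper
event intervals are logged from the *noiseless latent* trace evaluated on
the full scheduled reading grid, so downstream labeling can be checked
against truth without noise artifacts.

All randomness is drawn in a fixed order independent of the propensity
values, so two runs at the same seed differing only in a propensity share
common random numbers; propensities act monotonically on excursion depth
and height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CGMStream, Cohort, UserProfile

#: ADAG estimated-average-glucose map: mean glucose (mg/dL) from HbA1c (%).
EAG_SLOPE = 28.7
EAG_INTERCEPT = -46.7

#: CGM reporting limits (mg/dL); observed readings are clipped here.
CLIP_LOW = 40.0
CLIP_HIGH = 400.0

HYPO_THRESHOLD = 70.0
HYPER_THRESHOLD = 270.0

_MEAL_ANCHORS_HOURS = (8.0, 13.0, 20.0)
_MEAL_JITTER_MINUTES = 90.0
_MEAL_TAU_MINUTES = 55.0  # gamma-pulse peak delay
_DIP_WIDTH_MINUTES = 35.0  # gaussian dip sigma


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort draw; the seed fully determines output."""

    n_users: int = 20
    days_per_user: int = 60
    seed: int = 0
    cadence_minutes: float = 5.0
    dropout_fraction: float = 0.08
    sensor_swap_interval_days: float = 10.0
    sensor_swap_gap_hours: float = 3.0
    meal_rate: float = 3.0  # meals/day, at most one per anchor
    meal_amplitude_mean: float = 75.0  # mg/dL, gamma-distributed per meal
    meal_amplitude_shape: float = 9.0
    hypo_propensity: float = 0.15
    hyper_propensity: float = 0.25
    noise_sd: float = 6.0
    ar_coefficient: float = 0.7
    hba1c_range: tuple[float, float] = (7.5, 11.0)
    age_range: tuple[float, float] = (14.0, 25.0)
    start: str = "2022-03-01T00:00:00"

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.days_per_user < 1:
            raise SimConfigError("n_users and days_per_user must be >= 1")
        for name in ("dropout_fraction", "hypo_propensity", "hyper_propensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise SimConfigError("ar_coefficient must lie in [0, 1)")
        if self.cadence_minutes <= 0 or self.meal_rate < 0 or self.noise_sd < 0:
            raise SimConfigError("cadence, meal_rate and noise_sd must be non-negative")


@dataclass
class TruthLog:
    """Ground-truth hypo/hyper intervals of the latent trace, per user."""

    events: dict[str, list[tuple[str, np.datetime64, np.datetime64]]] = field(
        default_factory=dict
    )

    def count(self, event_type: str | None = None) -> int:
        return sum(
            1
            for evs in self.events.values()
            for (kind, _, _) in evs
            if event_type is None or kind == event_type
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"user_id": uid, "event_type": kind, "start": s, "end": e}
            for uid, evs in sorted(self.events.items())
            for (kind, s, e) in evs
        ]
        return pd.DataFrame(rows, columns=["user_id", "event_type", "start", "end"])


def emulate_city_defaults(full_scale: bool = False, seed: int = 0) -> SimConfig:
    """Shipped default configuration emulating the study cohort's structure.

    ``full_scale=True`` uses 153 users; the default is a desk-scale cohort of
    20 users x 60 days. HbA1c uniform on [7.5, 11.0) and enrollment ages
    uniform on [14, 25), mixed gender and prior-CGM use.
    """
    return SimConfig(n_users=153 if full_scale else 20, days_per_user=60, seed=seed)


def _gamma_pulse(minutes_since: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak gamma-shaped meal excursion, peaking ``tau`` minutes after onset."""
    x = np.clip(minutes_since / tau, 0.0, None)
    return np.where(minutes_since >= 0.0, x * x * np.exp(2.0 - 2.0 * x), 0.0)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j] (inclusive) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return list(zip(starts, ends))


def _simulate_user(uid: str, cfg: SimConfig, rng: np.random.Generator):
    step_s = cfg.cadence_minutes * 60.0
    n = int(round(cfg.days_per_user * 24 * 60 / cfg.cadence_minutes))
    start = np.datetime64(cfg.start, "s")
    grid = start + (np.arange(n) * step_s).astype("timedelta64[s]")
    t_min = np.arange(n) * cfg.cadence_minutes  # minutes since start
    hour = (t_min / 60.0) % 24.0

    # --- profile ---------------------------------------------------------
    age = rng.uniform(*cfg.age_range)
    age_diag = rng.uniform(2.0, max(2.5, age - 1.0))
    gender = "F" if rng.uniform() < 0.5 else "M"
    prior = bool(rng.uniform() < 0.5)
    hba1c = rng.uniform(*cfg.hba1c_range)
    # floor to 0.1 so values stay inside their half-open sampling intervals
    profile = UserProfile(
        user_id=uid,
        gender=gender,
        age_enrollment=np.floor(age * 10) / 10,
        age_diagnosis=np.floor(age_diag * 10) / 10,
        prior_cgm_use=prior,
        hba1c_latest=np.floor(hba1c * 10) / 10,
    )

    # --- latent trace ----------------------------------------------------
    # Offset the baseline by the expected meal-pulse mean (a function of the
    # meal settings only, never the propensities) so user mean ~ eAG(HbA1c).
    pulse_area = _MEAL_TAU_MINUTES * np.e**2 / 4.0  # integral of unit-peak pulse
    meal_offset = cfg.meal_rate * cfg.meal_amplitude_mean * pulse_area / 1440.0
    baseline = EAG_SLOPE * hba1c + EAG_INTERCEPT - meal_offset
    circ_amp = rng.uniform(8.0, 18.0)
    # circadian phase: daily high in the evening, low in the early morning
    latent = baseline + circ_amp * np.sin(2.0 * np.pi * (hour - 13.5) / 24.0)

    p_meal = min(1.0, cfg.meal_rate / len(_MEAL_ANCHORS_HOURS))
    amp_scale = cfg.meal_amplitude_mean / cfg.meal_amplitude_shape
    for day in range(cfg.days_per_user):
        for anchor in _MEAL_ANCHORS_HOURS:
            # Fixed draw order; propensities only scale the drawn quantities.
            u_occ = rng.uniform()
            jitter = rng.uniform(-_MEAL_JITTER_MINUTES, _MEAL_JITTER_MINUTES)
            base_amp = rng.gamma(cfg.meal_amplitude_shape, amp_scale)
            boost = 160.0 * min(rng.exponential(), 2.5)
            dip_base = rng.uniform(10.0, 30.0)
            dip_heavy = 1600.0 * rng.uniform() ** 3
            dip_delay = rng.uniform(100.0, 160.0)
            if u_occ >= p_meal:
                continue
            meal_t = day * 1440.0 + anchor * 60.0 + jitter
            # dinner is the largest meal: evening excursions dominate
            anchor_factor = 1.25 if anchor == _MEAL_ANCHORS_HOURS[-1] else 0.9
            amp = anchor_factor * (base_amp + cfg.hyper_propensity * boost)
            lo = np.searchsorted(t_min, meal_t)
            hi = np.searchsorted(t_min, meal_t + 300.0)
            latent[lo:hi] += amp * _gamma_pulse(t_min[lo:hi] - meal_t, _MEAL_TAU_MINUTES)
            # insulin-correction decline after the meal; overshoot is worse
            # late in the evening (no snack follows), a sharp time-of-day
            # dependence deliberately beyond a linear clock-time effect
            depth = dip_base + cfg.hypo_propensity * dip_heavy
            dip_c = meal_t + dip_delay
            dip_hour = (dip_c / 60.0) % 24.0
            depth *= 1.35 if (dip_hour >= 20.0 or dip_hour < 2.0) else 0.85
            dlo = np.searchsorted(t_min, dip_c - 90.0)
            dhi = np.searchsorted(t_min, dip_c + 90.0)
            latent[dlo:dhi] -= depth * np.exp(
                -0.5 * ((t_min[dlo:dhi] - dip_c) / _DIP_WIDTH_MINUTES) ** 2
            )

    # --- truth log from the latent trace on the scheduled grid -----------
    latent = np.clip(latent, CLIP_LOW, CLIP_HIGH)  # CGM reporting limits
    events: list[tuple[str, np.datetime64, np.datetime64]] = []
    for i, j in _runs_above(latent < HYPO_THRESHOLD):
        events.append(("hypo", grid[i], grid[j]))
    for i, j in _runs_above(latent > HYPER_THRESHOLD):
        events.append(("hyper", grid[i], grid[j]))
    events.sort(key=lambda e: (e[1], e[0]))

    # --- observation noise, clipping, thinning ---------------------------
    innov = rng.normal(0.0, 1.0, n)
    noise = np.empty(n)
    a = cfg.ar_coefficient
    scale = cfg.noise_sd * np.sqrt(1.0 - a * a)
    noise[0] = innov[0] * cfg.noise_sd
    for k in range(1, n):
        noise[k] = a * noise[k - 1] + scale * innov[k]
    observed = np.clip(latent + noise, CLIP_LOW, CLIP_HIGH)

    keep = rng.uniform(size=n) >= cfg.dropout_fraction
    if cfg.sensor_swap_interval_days > 0:
        swap_t = cfg.sensor_swap_interval_days * 1440.0
        while swap_t < cfg.days_per_user * 1440.0:
            gap_start = swap_t + rng.uniform(0.0, 720.0)
            gap_len = cfg.sensor_swap_gap_hours * 60.0
            keep[(t_min >= gap_start) & (t_min < gap_start + gap_len)] = False
            swap_t += cfg.sensor_swap_interval_days * 1440.0
    if not keep.any():
        keep[0] = True  # degenerate configs still yield a non-empty stream

    stream = CGMStream(
        user_id=uid,
        times=grid[keep],
        glucose=np.round(observed[keep], 1),
        cadence_minutes=cfg.cadence_minutes,
    )
    return stream, profile, events


def simulate_cohort(config: SimConfig) -> tuple[Cohort, TruthLog]:
    """Generate a seeded cohort and its ground-truth event log.

    Each user gets an independent child RNG spawned from the config seed, so
    output is bit-reproducible and per-user traces do not depend on
    ``n_users`` ordering.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_users)
    streams: dict[str, CGMStream] = {}
    profiles: dict[str, UserProfile] = {}
    truth = TruthLog()
    for i, ss in enumerate(seeds):
        uid = f"u{i:03d}"
        stream, profile, events = _simulate_user(uid, config, np.random.default_rng(ss))
        streams[uid] = stream
        profiles[uid] = profile
        truth.events[uid] = events
    return Cohort(streams=streams, profiles=profiles), truth
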