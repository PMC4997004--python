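"""Synthetic per-user phone-usage streams with a planted usage→emotion link.

No raw data from any real cohort is shipped; instead this module emulates
the streams the monitoring app would record, with a *known* dependence of
the three VAS emotions on usage, so every downstream stage (event
inference, feature extraction, selection, classification, prospective
evaluation) can be tested for parameter recovery and null behaviour.

Generative model, per user:

* **Calls** are a marked Poisson process over the waking day
  (08:00–23:00) with a per-user daily rate; each arrival is call-out,
  call-in or missed, with log-normal ring and talk durations.
* **Screen bouts** are a second Poisson process; each bout is 1–3
  back-to-back app sessions drawn from a per-user Dirichlet preference
  over the app catalog, with log-normal session lengths.  The union of a
  bout's sessions is the screen session.
* **Emotion tags**: during training days, ``tags_per_day`` reports at
  jittered times in fixed daily slots respecting the minimum gap; during
  evaluation days, reports at the seven 2-hourly prediction times
  (11:00–23:00), each present with probability ``response_rate``.
* **VAS values**: a small set of *planted* features (screen-time total
  and count, plus one app's total duration) is computed over the 2-hour
  window preceding each tag from the true events, z-scored within the
  user, linearly combined with per-scale unit-norm weights, scaled by
  ``effect_size``, offset to mid-scale, perturbed with Gaussian noise of
  sd ``noise_sd``, then rounded and clipped to the integer VAS range
  0–100.  ``effect_size = 0`` yields tags independent of usage.

Raw call-state and foreground-app samples are emitted every
``sample_period`` seconds during activity (durations are rounded to whole
periods so the sampled stream determines the true events exactly), and
each call is terminated by an explicit ``idle`` sample.  One master seed
drives everything; per-user substreams are derived from the user id, so
users are independent and order-insensitive.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .emotion_tags import SCALES, EmotionTag, read_tags, write_tags
from .evaluation import EVAL_HOURS
from .feature_extraction import Timeslot, extract_batch
from .usage_log import RawLogRecord, UsageEvent, read_raw_log, write_raw_log

__all__ = [
    "DEFAULT_APP_CATALOG",
    "SimConfig",
    "SimConfigError",
    "GroundTruth",
    "simulate_user",
    "simulate_cohort",
    "split_tags",
    "write_fixture",
    "read_fixture",
    "user_ids",
]

DEFAULT_APP_CATALOG: tuple[tuple[str, str], ...] = (
    ("com.chat.blue", "communication"),
    ("com.social.stream", "social"),
    ("com.video.loop", "entertainment"),
    ("com.mail.swift", "productivity"),
    ("com.game.puzzler", "games"),
    ("com.news.daily", "news"),
)

#: Width (hours) of the window the planted dependence acts over.
PLANTED_WINDOW_HOURS = 2.0
VAS_MID = 50.0

_WAKE_START_H = 8.0
_WAKE_END_H = 23.0
_TAG_JITTER_S = 1500  # +/- 25 min around each daily tag slot


class SimConfigError(ValueError):
    """A simulation configuration field violates its invariant."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the data-collection protocol being emulated: 14
    training days with 4 tags/day at least 3 h apart, at least 5
    evaluation days, and 3-second polling of the call state.
    """

    n_users: int = 10
    n_days_train: int = 14
    n_days_eval: int = 5
    tags_per_day: int = 4
    min_tag_gap: float = 3.0  # hours
    sample_period: float = 3.0  # seconds
    effect_size: float = 25.0
    noise_sd: float = 8.0
    seed: int = 0
    app_catalog: tuple[tuple[str, str], ...] = DEFAULT_APP_CATALOG
    start_date: date = date(2024, 1, 1)
    response_rate: float = 0.98

    def validate(self) -> None:
        if self.n_users < 1:
            raise SimConfigError("n_users must be >= 1")
        if self.n_days_train < 1:
            raise SimConfigError("n_days_train must be >= 1")
        if self.n_days_eval < 0:
            raise SimConfigError("n_days_eval must be >= 0")
        if self.tags_per_day < 1:
            raise SimConfigError("tags_per_day must be >= 1")
        if self.tags_per_day * self.min_tag_gap > 24:
            raise SimConfigError(
                "tags_per_day * min_tag_gap must fit within 24 h"
            )
        if self.sample_period <= 0:
            raise SimConfigError("sample_period must be > 0")
        if self.effect_size < 0:
            raise SimConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be > 0")
        if not 0 <= self.response_rate <= 1:
            raise SimConfigError("response_rate must be in [0, 1]")
        if not self.app_catalog:
            raise SimConfigError("app_catalog must not be empty")

    @property
    def category_map(self) -> dict[str, str]:
        return dict(self.app_catalog)

    @property
    def train_cutoff(self) -> datetime:
        return _day_start(self.start_date, self.n_days_train)


@dataclass
class GroundTruth:
    """Planted generative parameters and latent values for one user."""

    user_id: str
    planted_window_hours: float
    baseline: float
    weights: dict[str, dict[str, float]]  # scale -> feature key -> weight
    latent: dict[str, list[float]]  # scale -> latent VAS per tag (pre-noise)
    tag_times: list[str]  # ISO timestamps, aligned with latent lists

    @property
    def planted_features(self) -> list[str]:
        keys: list[str] = []
        for per_scale in self.weights.values():
            for k in per_scale:
                if k not in keys:
                    keys.append(k)
        return keys

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def user_ids(config: SimConfig) -> list[str]:
    return [f"user{i:02d}" for i in range(config.n_users)]


def _day_start(start: date, day_index: int) -> datetime:
    return datetime(start.year, start.month, start.day) + timedelta(
        days=day_index
    )


def _user_rng(config: SimConfig, user_id: str) -> np.random.Generator:
    # per-user substream: independent of other users and of call order
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(user_id.encode())]
    )


def _round_to_period(seconds: float, period: float) -> float:
    return max(period, round(seconds / period) * period)


def _lognormal(rng, median: float, sigma: float) -> float:
    return float(rng.lognormal(np.log(median), sigma))


def _tag_slot_hours(config: SimConfig) -> tuple[list[float], int]:
    """Daily tag slot centres (hours) and allowed jitter (seconds)."""
    n = config.tags_per_day
    if n == 1:
        return [14.0], _TAG_JITTER_S
    jitter = _TAG_JITTER_S
    spacing = max(config.min_tag_gap + 2 * jitter / 3600 + 0.1, 3.5)
    span = (n - 1) * spacing
    start = 9.0
    if start + span + jitter / 3600 >= 24.0:
        jitter = 0
        spacing = config.min_tag_gap + 0.05
        span = (n - 1) * spacing
        start = max(0.25, (24.0 - span) / 2)
        if start + span >= 24.0:
            raise SimConfigError(
                "tags_per_day and min_tag_gap leave no feasible daily schedule"
            )
    return [start + i * spacing for i in range(n)], jitter


def _simulate_calls(
    config: SimConfig, rng: np.random.Generator, n_days: int
) -> list[dict]:
    """Non-overlapping call arrivals with type, ring and talk durations."""
    p = config.sample_period
    rate = rng.uniform(2.0, 5.0)  # calls per day
    raw: list[dict] = []
    for day in range(n_days):
        day0 = _day_start(config.start_date, day)
        for _ in range(rng.poisson(rate)):
            # whole seconds: the on-disk schema is second-resolution
            at = day0 + timedelta(
                seconds=int(
                    rng.uniform(_WAKE_START_H * 3600, _WAKE_END_H * 3600)
                )
            )
            kind = rng.choice(
                ["call_out", "call_in", "call_missed"], p=[0.45, 0.40, 0.15]
            )
            ring = _round_to_period(_lognormal(rng, 9.0, 0.5), p)
            talk = _round_to_period(_lognormal(rng, 90.0, 0.8), p)
            raw.append({"type": str(kind), "at": at, "ring": ring, "talk": talk})
    raw.sort(key=lambda c: c["at"])
    calls: list[dict] = []
    for c in raw:
        if c["type"] == "call_missed":
            start, end = c["at"], c["at"] + timedelta(seconds=c["ring"])
        elif c["type"] == "call_in":
            start = c["at"] + timedelta(seconds=c["ring"])
            end = start + timedelta(seconds=c["talk"])
            c["ring_start"] = c["at"]
        else:
            start, end = c["at"], c["at"] + timedelta(seconds=c["talk"])
        span_start = c.get("ring_start", start)
        if calls and span_start <= calls[-1]["end"] + timedelta(
            seconds=2 * config.sample_period
        ):
            continue  # drop overlapping/abutting arrivals
        c["start"], c["end"] = start, end
        calls.append(c)
    return calls


def _simulate_screen(
    config: SimConfig, rng: np.random.Generator, n_days: int
) -> list[dict]:
    """Non-overlapping screen bouts, each a run of app sessions."""
    p = config.sample_period
    packages = [pkg for pkg, _ in config.app_catalog]
    prefs = rng.dirichlet(np.full(len(packages), 0.8))
    bout_rate = rng.uniform(12.0, 20.0)  # bouts per day
    raw_starts: list[datetime] = []
    for day in range(n_days):
        day0 = _day_start(config.start_date, day)
        for _ in range(rng.poisson(bout_rate)):
            raw_starts.append(
                day0
                + timedelta(
                    seconds=int(
                        rng.uniform(_WAKE_START_H * 3600, _WAKE_END_H * 3600)
                    )
                )
            )
    raw_starts.sort()
    bouts: list[dict] = []
    for at in raw_starts:
        n_sessions = int(rng.integers(1, 4))
        sessions = []
        t = at
        for _ in range(n_sessions):
            pkg = packages[int(rng.choice(len(packages), p=prefs))]
            dur = _round_to_period(
                min(_lognormal(rng, 70.0, 0.9), 1800.0), p
            )
            end = t + timedelta(seconds=dur)
            if sessions and sessions[-1]["package"] == pkg:
                # back-to-back same-package sessions are indistinguishable
                # in the sampled stream; merge them at generation time
                sessions[-1]["end"] = end
            else:
                sessions.append({"package": pkg, "start": t, "end": end})
            t = end
        if bouts and at <= bouts[-1]["end"] + timedelta(seconds=2 * p):
            continue
        bouts.append({"start": at, "end": t, "sessions": sessions})
    return bouts


def _true_events(
    config: SimConfig, calls: list[dict], bouts: list[dict]
) -> list[UsageEvent]:
    events: list[UsageEvent] = []
    cat = config.category_map
    for c in calls:
        events.append(UsageEvent(c["type"], c["start"], c["end"]))
    for b in bouts:
        events.append(UsageEvent("screen_session", b["start"], b["end"]))
        for s in b["sessions"]:
            events.append(
                UsageEvent(
                    "app_session", s["start"], s["end"],
                    package=s["package"],
                    category=cat.get(s["package"], "other"),
                )
            )
    return sorted(events, key=lambda e: (e.start, e.event_type, e.package or ""))


def _emit_samples(
    config: SimConfig, calls: list[dict], bouts: list[dict]
) -> list[RawLogRecord]:
    p = config.sample_period
    records: list[RawLogRecord] = []

    def sample_times(start: datetime, end: datetime) -> list[datetime]:
        n = int(round((end - start).total_seconds() / p))
        return [start + timedelta(seconds=i * p) for i in range(n)]

    for c in calls:
        if c["type"] == "call_missed":
            for t in sample_times(c["start"], c["end"]):
                records.append(RawLogRecord(t, "call_state", "ringing"))
        elif c["type"] == "call_in":
            for t in sample_times(c["ring_start"], c["start"]):
                records.append(RawLogRecord(t, "call_state", "ringing"))
            for t in sample_times(c["start"], c["end"]):
                records.append(RawLogRecord(t, "call_state", "offhook"))
        else:
            for t in sample_times(c["start"], c["end"]):
                records.append(RawLogRecord(t, "call_state", "offhook"))
        records.append(RawLogRecord(c["end"], "call_state", "idle"))
    for b in bouts:
        for s in b["sessions"]:
            for t in sample_times(s["start"], s["end"]):
                records.append(RawLogRecord(t, "app", s["package"]))
    records.sort(key=lambda r: (r.timestamp, r.record_type, r.value))
    return records


def _tag_times(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[datetime], list[datetime]]:
    """(training tag times, evaluation report times)."""
    slots, jitter = _tag_slot_hours(config)
    train: list[datetime] = []
    for day in range(config.n_days_train):
        day0 = _day_start(config.start_date, day)
        for h in slots:
            off = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            train.append(day0 + timedelta(seconds=int(round(h * 3600)) + off))
    evals: list[datetime] = []
    for day in range(config.n_days_train,
                     config.n_days_train + config.n_days_eval):
        day0 = _day_start(config.start_date, day)
        for h in EVAL_HOURS:
            if rng.random() < config.response_rate:
                evals.append(day0 + timedelta(hours=h))
    return train, evals


def _planted_keys(config: SimConfig) -> list[str]:
    first_pkg = config.app_catalog[0][0]
    return [
        "screen_session|total_duration",
        "screen_session|count",
        f"app:{first_pkg}|total_duration",
    ]


def simulate_user(
    config: SimConfig, user_id: str
) -> tuple[list[RawLogRecord], list[EmotionTag], GroundTruth]:
    """Generate one user's raw samples, emotion tags and ground truth."""
    config.validate()
    rng = _user_rng(config, user_id)
    n_days = config.n_days_train + config.n_days_eval

    calls = _simulate_calls(config, rng, n_days)
    bouts = _simulate_screen(config, rng, n_days)
    events = _true_events(config, calls, bouts)
    records = _emit_samples(config, calls, bouts)
    train_times, eval_times = _tag_times(config, rng)
    all_times = train_times + eval_times

    planted = _planted_keys(config)
    usage_types = sorted({k.split("|")[0] for k in planted})
    fx = extract_batch(
        events, all_times, Timeslot(PLANTED_WINDOW_HOURS), usage_types
    )[planted].to_numpy()
    mu = fx.mean(axis=0)
    sd = fx.std(axis=0)
    sd[sd == 0] = 1.0
    z = (fx - mu) / sd

    weights: dict[str, dict[str, float]] = {}
    latent: dict[str, list[float]] = {}
    tags: list[EmotionTag] = []
    vas: dict[str, np.ndarray] = {}
    for scale in SCALES:
        # one direction per scale: heavier usage raises or lowers the
        # emotion consistently across the planted set.  The planted
        # features are positively correlated (they all track screen
        # activity), so mixed signs would let marginal effects cancel.
        sign = float(rng.choice([-1.0, 1.0]))
        w = sign * rng.uniform(0.5, 1.0, size=len(planted))
        w /= np.linalg.norm(w)
        score = z @ w
        # normalize so effect_size is the latent signal sd in VAS units
        # regardless of the correlation structure of the planted features
        ssd = float(score.std())
        if ssd > 0:
            score = score / ssd
            w = w / ssd
        weights[scale] = {k: float(wi) for k, wi in zip(planted, w)}
        lat = VAS_MID + config.effect_size * score
        latent[scale] = [float(v) for v in lat]
        noise = rng.normal(0.0, config.noise_sd, size=len(all_times))
        vas[scale] = np.clip(np.rint(lat + noise), 0, 100).astype(int)
    for i, t in enumerate(all_times):
        tags.append(
            EmotionTag(
                t,
                int(vas["depression"][i]),
                int(vas["anxiety"][i]),
                int(vas["stress"][i]),
            )
        )
    truth = GroundTruth(
        user_id=user_id,
        planted_window_hours=PLANTED_WINDOW_HOURS,
        baseline=VAS_MID,
        weights=weights,
        latent=latent,
        tag_times=[t.isoformat() for t in all_times],
    )
    return records, tags, truth


def simulate_cohort(
    config: SimConfig,
) -> dict[str, tuple[list[RawLogRecord], list[EmotionTag], GroundTruth]]:
    config.validate()
    return {uid: simulate_user(config, uid) for uid in user_ids(config)}


def split_tags(
    config: SimConfig, tags: Sequence[EmotionTag]
) -> tuple[list[EmotionTag], list[EmotionTag]]:
    """Partition a user's tags into (training, evaluation) phases."""
    cutoff = config.train_cutoff
    train = [t for t in tags if t.timestamp < cutoff]
    evals = [t for t in tags if t.timestamp >= cutoff]
    return train, evals


# ---------------------------------------------------------------------------
# Fixture I/O: raw_logs/<user>.csv, tags/<user>.csv, truth/<user>.json

def write_fixture(
    user_id: str,
    records: Sequence[RawLogRecord],
    tags: Sequence[EmotionTag],
    truth: GroundTruth | None,
    outdir,
) -> dict[str, Path]:
    out = Path(outdir)
    paths = {
        "raw": out / "raw_logs" / f"{user_id}.csv",
        "tags": out / "tags" / f"{user_id}.csv",
    }
    for p in paths.values():
        p.parent.mkdir(parents=True, exist_ok=True)
    write_raw_log(records, paths["raw"])
    write_tags(tags, paths["tags"])
    if truth is not None:
        tp = out / "truth" / f"{user_id}.json"
        tp.parent.mkdir(parents=True, exist_ok=True)
        tp.write_text(truth.to_json())
        paths["truth"] = tp
    return paths


def read_fixture(
    user_id: str, outdir
) -> tuple[list[RawLogRecord], list[EmotionTag]]:
    out = Path(outdir)
    return (
        read_raw_log(out / "raw_logs" / f"{user_id}.csv"),
        read_tags(out / "tags" / f"{user_id}.csv"),
    )
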