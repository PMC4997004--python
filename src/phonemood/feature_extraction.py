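"""Windowed usage statistics computed for each emotion tag.

For every tag a *timeslot* — the fixed-width window ``[t - width, t)``
immediately preceding the tag, with width 0.5, 1, 1.5 or 2 hours — is
scanned and four statistics are computed per usage type:

* ``count``            — number of events overlapping the window,
* ``total_duration``   — summed in-window (clipped) duration, seconds,
* ``average_duration`` — total_duration / count (0 for an empty window),
* ``average_interval`` — mean of ``start_i - end_{i-1}`` over consecutive
  contributing event pairs of the same type (0 if fewer than two events).

Usage types are the three call outcomes, the screen session, each of the
user's top-k apps, and each app category.  Events straddling the window
boundary contribute their clipped duration rather than being excluded.

Events of a single usage type are non-overlapping, so both their start
and end times are sorted; window membership is then two binary searches,
which keeps the full (tags x timeslots x types) sweep cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .emotion_tags import SCALES, EmotionTag, categorize
from .usage_log import UsageEvent, categorize_apps, top_apps

__all__ = [
    "STATISTICS",
    "DEFAULT_TIMESLOT_HOURS",
    "Timeslot",
    "feature_key",
    "usage_types_for_user",
    "events_for_type",
    "extract",
    "extract_batch",
    "build_design_matrix",
]

STATISTICS = ("count", "total_duration", "average_duration", "average_interval")
DEFAULT_TIMESLOT_HOURS = (0.5, 1.0, 1.5, 2.0)

_EPOCH = datetime(1970, 1, 1)


@dataclass(frozen=True)
class Timeslot:
    """Window width in hours; the window is [tag_time - width, tag_time)."""

    width_hours: float

    def __post_init__(self) -> None:
        if self.width_hours <= 0:
            raise ValueError("timeslot width must be positive")

    @property
    def width(self) -> timedelta:
        return timedelta(hours=self.width_hours)


def feature_key(usage_type: str, statistic: str) -> str:
    return f"{usage_type}|{statistic}"


def usage_types_for_user(
    events: Sequence[UsageEvent],
    app_category_map: dict[str, str],
    k_top_apps: int = 10,
) -> list[str]:
    """Fix a user's feature vocabulary from their training-period events.

    Call outcomes and the screen session are always present; the user's
    top-k apps (by total duration) and every category observed in their
    sessions are appended.  The ordering is deterministic.
    """
    types = ["call_in", "call_out", "call_missed", "screen_session"]
    types += [f"app:{pkg}" for pkg in top_apps(events, k_top_apps)]
    cats = sorted(
        {
            e.category or "other"
            for e in categorize_apps(events, app_category_map)
            if e.event_type == "app_session"
        }
    )
    types += [f"category:{c}" for c in cats]
    return types


def _matches(e: UsageEvent, usage_type: str) -> bool:
    if usage_type.startswith("app:"):
        return e.event_type == "app_session" and e.package == usage_type[4:]
    if usage_type.startswith("category:"):
        return (
            e.event_type == "app_session"
            and (e.category or "other") == usage_type[9:]
        )
    if usage_type in {"call_in", "call_out", "call_missed",
                      "screen_session", "app_session"}:
        return e.event_type == usage_type
    raise KeyError(f"unknown usage type {usage_type!r}")


def events_for_type(
    events: Sequence[UsageEvent], usage_type: str
) -> list[UsageEvent]:
    """Events of one usage type, sorted by start."""
    if not (
        usage_type.startswith(("app:", "category:"))
        or usage_type in {"call_in", "call_out", "call_missed",
                          "screen_session", "app_session"}
    ):
        raise KeyError(f"unknown usage type {usage_type!r}")
    return sorted(
        (e for e in events if _matches(e, usage_type)), key=lambda e: e.start
    )


class _TypeIndex:
    """Sorted start/end arrays (epoch seconds) for one usage type."""

    def __init__(self, events: Sequence[UsageEvent]):
        self.starts = np.array(
            [(e.start - _EPOCH).total_seconds() for e in events]
        )
        self.ends = np.array(
            [(e.end - _EPOCH).total_seconds() for e in events]
        )

    def stats(self, t: float, width_s: float) -> tuple[float, float, float, float]:
        lo_t = t - width_s
        # contributing events: start < t and end > window start
        hi = int(np.searchsorted(self.starts, t, side="left"))
        lo = int(np.searchsorted(self.ends, lo_t, side="right"))
        n = hi - lo
        if n <= 0:
            return 0.0, 0.0, 0.0, 0.0
        starts = self.starts[lo:hi]
        ends = self.ends[lo:hi]
        total = float(
            np.sum(np.minimum(ends, t) - np.maximum(starts, lo_t))
        )
        interval = float(np.mean(starts[1:] - ends[:-1])) if n > 1 else 0.0
        return float(n), total, total / n, interval


def _build_indexes(
    events: Sequence[UsageEvent], usage_types: Sequence[str]
) -> dict[str, _TypeIndex]:
    return {u: _TypeIndex(events_for_type(events, u)) for u in usage_types}


def extract_batch(
    events: Sequence[UsageEvent],
    tag_times: Sequence[datetime],
    slot: Timeslot,
    usage_types: Sequence[str],
) -> pd.DataFrame:
    """Feature matrix for many tags at once; one row per tag time."""
    idx = _build_indexes(events, usage_types)
    width_s = slot.width_hours * 3600.0
    columns = [feature_key(u, s) for u in usage_types for s in STATISTICS]
    rows = np.empty((len(tag_times), len(columns)))
    for r, tt in enumerate(tag_times):
        t = (tt - _EPOCH).total_seconds()
        col = 0
        for u in usage_types:
            rows[r, col:col + 4] = idx[u].stats(t, width_s)
            col += 4
    return pd.DataFrame(rows, columns=columns)


def extract(
    events: Sequence[UsageEvent],
    tag_time: datetime,
    slot: Timeslot,
    usage_types: Sequence[str],
) -> dict[str, float]:
    """Feature vector for one tag: all four statistics per usage type.

    An event contributes if it overlaps ``[tag_time - width, tag_time)``;
    its duration is clipped to the window.  Inter-event intervals use the
    events' own (unclipped) endpoints, which for contributing pairs lie
    inside the window.
    """
    df = extract_batch(events, [tag_time], slot, usage_types)
    return {k: float(v) for k, v in df.iloc[0].items()}


def build_design_matrix(
    events: Sequence[UsageEvent],
    tags: Sequence[EmotionTag],
    slot: Timeslot,
    usage_types: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One feature row per tag plus the three categorical label vectors.

    Returns ``(X, y, meta)`` where ``X`` has one column per
    (usage type, statistic) key in deterministic order, ``y`` has one
    categorical column per scale, and ``meta`` records the column keys,
    the timeslot and any zero-variance columns (retained but flagged).
    """
    ordered = sorted(tags, key=lambda t: t.timestamp)
    X = extract_batch(events, [t.timestamp for t in ordered], slot, usage_types)
    y = pd.DataFrame(
        [[categorize(t.value(s)) for s in SCALES] for t in ordered],
        columns=list(SCALES),
    )
    zero_var = [c for c in X.columns if len(X) and X[c].nunique() <= 1]
    meta = {
        "columns": list(X.columns),
        "timeslot_hours": slot.width_hours,
        "zero_variance_columns": zero_var,
    }
    return X, y, meta
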