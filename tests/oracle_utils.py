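"""Independent brute-force oracles used to cross-check event inference
and feature extraction.

These reconstruct events by explicit per-second state expansion: each
sample marks ``sample_period`` seconds of occupancy, maximal constant
runs become intervals, and intervals of the same value separated by a
hole of at most one period (one dropped poll) are merged.  The code path
is deliberately different from the streaming state machine it checks.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np

from phonemood.usage_log import RawLogRecord, UsageEvent

_EPOCH = datetime(1970, 1, 1)


def _sec(dt: datetime) -> int:
    return int((dt - _EPOCH).total_seconds())


def _dt(sec: float) -> datetime:
    return _EPOCH + timedelta(seconds=sec)


def _coverage_intervals(samples, period: int):
    """Maximal (start_s, end_s, value) runs of per-second coverage."""
    cov: dict[int, str] = {}
    for rec in samples:
        t0 = _sec(rec.timestamp)
        for s in range(t0, t0 + period):
            cov[s] = rec.value
    intervals: list[list] = []
    for s in sorted(cov):
        v = cov[s]
        if intervals and intervals[-1][1] == s and intervals[-1][2] == v:
            intervals[-1][1] = s + 1
        else:
            intervals.append([s, s + 1, v])
    return intervals


def _merge_holes(intervals, max_hole: int):
    """Merge same-value intervals separated by a hole <= max_hole seconds
    with no other interval in between."""
    merged: list[list] = []
    for iv in intervals:
        if (
            merged
            and merged[-1][2] == iv[2]
            and iv[0] - merged[-1][1] <= max_hole
        ):
            merged[-1][1] = iv[1]
        else:
            merged.append(list(iv))
    return merged


def brute_force_call_events(samples, period: int) -> list[UsageEvent]:
    """Per-second reconstruction of call events from call-state samples."""
    # keep idle intervals: they separate a ring from a later unrelated call
    intervals = _merge_holes(_coverage_intervals(samples, period), period)
    # a ringing run and an answering offhook run may still be separated by
    # a <= period hole (one dropped poll); treat them as contiguous
    events = []
    i = 0
    while i < len(intervals):
        start, end, state = intervals[i]
        if state == "idle":
            i += 1
            continue
        if state == "ringing":
            nxt = intervals[i + 1] if i + 1 < len(intervals) else None
            if (
                nxt is not None
                and nxt[2] == "offhook"
                and nxt[0] - end <= period
            ):
                events.append(UsageEvent("call_in", _dt(nxt[0]), _dt(nxt[1])))
                i += 2
                continue
            events.append(UsageEvent("call_missed", _dt(start), _dt(end)))
        else:  # offhook with no answering ring
            events.append(UsageEvent("call_out", _dt(start), _dt(end)))
        i += 1
    return events


def brute_force_app_sessions(samples, period: int) -> list[UsageEvent]:
    """Per-second reconstruction of app sessions and screen sessions."""
    runs = _merge_holes(_coverage_intervals(samples, period), period)
    events = [
        UsageEvent("app_session", _dt(a), _dt(b), package=v)
        for a, b, v in runs
    ]
    # screen sessions: union of coverage, merged across holes <= 2 periods
    screen_runs = _merge_holes(
        [[a, b, "screen"] for a, b, _ in runs], 2 * period
    )
    events += [
        UsageEvent("screen_session", _dt(a), _dt(b)) for a, b, _ in screen_runs
    ]
    return sorted(events, key=lambda e: (e.start, e.event_type))


def brute_force_window_duration(
    events, tag_time: datetime, width_hours: float
) -> float:
    """Per-second accumulation of in-window occupancy for one event list."""
    a = _sec(tag_time) - int(width_hours * 3600)
    b = _sec(tag_time)
    covered = 0
    for s in range(a, b):
        if any(_sec(e.start) <= s < _sec(e.end) for e in events):
            covered += 1
    return float(covered)


def random_call_stream(seed: int, n_samples: int = 200, period: int = 3):
    """Random legal-transition call-state stream with occasional gaps."""
    rng = np.random.default_rng(seed)
    legal = {
        "idle": ["idle", "ringing", "offhook"],
        "ringing": ["ringing", "idle", "offhook"],
        "offhook": ["offhook", "idle"],
    }
    stay = {"idle": 0.6, "ringing": 0.5, "offhook": 0.7}
    t = 0
    state = "idle"
    out = []
    for _ in range(n_samples):
        out.append(RawLogRecord(_dt(t), "call_state", state))
        # occasional dropped polls and longer dropouts
        step = rng.choice([period, 2 * period, 5 * period],
                          p=[0.80, 0.12, 0.08])
        t += int(step)
        if rng.random() < stay[state]:
            continue
        nxt = [s for s in legal[state] if s != state]
        state = str(rng.choice(nxt))
    return out


def random_app_stream(seed: int, n_samples: int = 200, period: int = 3):
    """Random foreground-app stream with package switches and gaps."""
    rng = np.random.default_rng(seed)
    packages = ["app.alpha", "app.beta", "app.gamma"]
    t = 0
    pkg = packages[0]
    out = []
    for _ in range(n_samples):
        out.append(RawLogRecord(_dt(t), "app", pkg))
        t += int(rng.choice([period, 2 * period, 4 * period],
                            p=[0.75, 0.15, 0.10]))
        if rng.random() < 0.25:
            pkg = str(rng.choice(packages))
    return out
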