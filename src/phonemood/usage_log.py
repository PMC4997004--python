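"""Raw usage-log parsing and discrete event inference.

A monitoring app samples two channels on the phone: the telephony call
state (``idle`` / ``ringing`` / ``offhook``) every few seconds, and the
package name of the app currently occupying the screen.  This module
turns those sample streams into discrete usage events:

* ``call_missed`` — a run of ``ringing`` samples that returns to ``idle``,
* ``call_in``     — a run of ``ringing`` samples followed by ``offhook``,
* ``call_out``    — ``offhook`` entered directly from ``idle``,
* ``app_session`` — a maximal run of identical package-name samples,
* ``screen_session`` — the union of app sessions, merged where adjacent.

Samples are treated as left endpoints of ``sample_period``-second occupancy
intervals, so a run ends at its last sample's timestamp plus one period and
a single-sample run has duration ``sample_period``.  A gap between
consecutive samples longer than ``2 * sample_period`` (one dropped poll)
closes any open run.  All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "CALL_STATES",
    "RawLogRecord",
    "UsageEvent",
    "ValidationError",
    "infer_call_events",
    "infer_app_sessions",
    "infer_events",
    "top_apps",
    "categorize_apps",
    "read_raw_log",
    "write_raw_log",
    "write_events_csv",
]

CALL_STATES = frozenset({"idle", "ringing", "offhook"})
RECORD_TYPES = frozenset({"call_state", "app"})

#: Timestamp format used by all on-disk files (UTC, second resolution).
TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


class ValidationError(ValueError):
    """A raw stream violates its ordering or value-domain contract."""


class RawLogRecord(NamedTuple):
    """One timestamped sample: a call state or a foreground app package."""

    timestamp: datetime
    record_type: str  # "call_state" | "app"
    value: str

    def validate(self) -> None:
        if self.record_type not in RECORD_TYPES:
            raise ValidationError(f"unknown record_type {self.record_type!r}")
        if self.record_type == "call_state" and self.value not in CALL_STATES:
            raise ValidationError(f"unknown call state token {self.value!r}")


@dataclass(frozen=True)
class UsageEvent:
    """An inferred usage event over the half-open interval [start, end)."""

    event_type: str
    start: datetime
    end: datetime
    package: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"event end {self.end} precedes start {self.start}"
            )

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def _check_sorted(samples: Sequence[RawLogRecord], expect_type: str) -> None:
    prev: datetime | None = None
    for rec in samples:
        rec.validate()
        if rec.record_type != expect_type:
            raise ValidationError(
                f"expected only {expect_type!r} records, got {rec.record_type!r}"
            )
        if prev is not None and rec.timestamp < prev:
            raise ValidationError(
                f"out-of-order timestamp {rec.timestamp} after {prev}"
            )
        prev = rec.timestamp


def infer_call_events(
    samples: Sequence[RawLogRecord], sample_period: float
) -> list[UsageEvent]:
    """Infer call-in / call-out / missed-call events from call-state samples.

    Transition rules: a ``ringing`` run ending in ``idle`` is a missed
    call spanning the ringing run; a ``ringing`` run ending in ``offhook``
    starts a ``call_in`` at the first offhook sample (ringing time is not
    counted in the call); ``offhook`` entered from ``idle`` is a
    ``call_out``.  An open run is closed by a sampling gap exceeding
    ``2 * sample_period`` or by the end of the stream.
    """
    _check_sorted(samples, "call_state")
    period = timedelta(seconds=sample_period)
    max_gap = timedelta(seconds=2 * sample_period)

    events: list[UsageEvent] = []
    state = "idle"  # current run state
    run_start: datetime | None = None
    call_type: str | None = None  # "call_in" | "call_out" while offhook
    last_ts: datetime | None = None

    def close_run() -> None:
        nonlocal state, run_start, call_type
        if run_start is None or last_ts is None:
            return
        end = last_ts + period
        if state == "ringing":
            events.append(UsageEvent("call_missed", run_start, end))
        elif state == "offhook":
            events.append(UsageEvent(call_type or "call_out", run_start, end))
        state, run_start, call_type = "idle", None, None

    for rec in samples:
        if last_ts is not None and rec.timestamp - last_ts > max_gap:
            close_run()
        tok = rec.value
        if tok != state:
            if tok == "ringing":
                # idle -> ringing is the legal entry; offhook -> ringing
                # (call waiting) is handled leniently by closing the call.
                close_run()
                state, run_start = "ringing", rec.timestamp
            elif tok == "offhook":
                if state == "ringing":
                    # answered: the call starts at the first offhook sample
                    state, run_start = "offhook", rec.timestamp
                    call_type = "call_in"
                else:
                    close_run()
                    state, run_start = "offhook", rec.timestamp
                    call_type = "call_out"
            else:  # idle
                close_run()
        last_ts = rec.timestamp
    close_run()
    return events


def infer_app_sessions(
    samples: Sequence[RawLogRecord], sample_period: float
) -> list[UsageEvent]:
    """Infer app sessions and screen sessions from foreground-app samples.

    A maximal run of identical package names becomes one ``app_session``;
    a package change or a gap longer than ``2 * sample_period`` closes the
    session.  The union of app sessions, merged where adjacent within
    ``2 * sample_period``, is additionally emitted as ``screen_session``
    events.  Returned events are sorted by (start, event_type).
    """
    _check_sorted(samples, "app")
    period = timedelta(seconds=sample_period)
    max_gap = timedelta(seconds=2 * sample_period)

    sessions: list[UsageEvent] = []
    cur_pkg: str | None = None
    run_start: datetime | None = None
    last_ts: datetime | None = None

    def close_session(end: datetime) -> None:
        nonlocal cur_pkg, run_start
        if cur_pkg is not None and run_start is not None:
            sessions.append(
                UsageEvent("app_session", run_start, end, package=cur_pkg)
            )
        cur_pkg, run_start = None, None

    for rec in samples:
        if last_ts is not None and rec.timestamp - last_ts > max_gap:
            close_session(last_ts + period)
        if rec.value != cur_pkg:
            if cur_pkg is not None and last_ts is not None:
                # package switch: previous session ends one period after
                # its last sample (== this sample's time in a dense stream)
                close_session(last_ts + period)
            cur_pkg, run_start = rec.value, rec.timestamp
        last_ts = rec.timestamp
    if last_ts is not None:
        close_session(last_ts + period)

    screen = merge_screen_sessions(sessions, sample_period)
    return sorted(sessions + screen, key=lambda e: (e.start, e.event_type))


def merge_screen_sessions(
    app_sessions: Iterable[UsageEvent], sample_period: float
) -> list[UsageEvent]:
    """Union of app sessions, merged where adjacent within 2 * period."""
    max_gap = timedelta(seconds=2 * sample_period)
    spans = sorted(
        (e for e in app_sessions if e.event_type == "app_session"),
        key=lambda e: e.start,
    )
    merged: list[UsageEvent] = []
    for e in spans:
        if merged and e.start - merged[-1].end <= max_gap:
            if e.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=e.end)
        else:
            merged.append(UsageEvent("screen_session", e.start, e.end))
    return merged


def infer_events(
    records: Sequence[RawLogRecord], sample_period: float
) -> list[UsageEvent]:
    """Split a mixed record stream by channel and infer all event types."""
    calls = [r for r in records if r.record_type == "call_state"]
    apps = [r for r in records if r.record_type == "app"]
    events = infer_call_events(calls, sample_period) + infer_app_sessions(
        apps, sample_period
    )
    return sorted(events, key=lambda e: (e.start, e.event_type, e.package or ""))


def top_apps(events: Iterable[UsageEvent], k: int = 10) -> list[str]:
    """Packages ranked by total app-session duration, descending.

    Ties are broken lexicographically by package name.  ``k`` larger than
    the number of distinct packages returns all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals: dict[str, float] = {}
    for e in events:
        if e.event_type == "app_session" and e.package is not None:
            totals[e.package] = totals.get(e.package, 0.0) + e.duration_s
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pkg for pkg, _ in ranked[:k]]


def categorize_apps(
    events: Iterable[UsageEvent], mapping: dict[str, str]
) -> list[UsageEvent]:
    """Annotate app sessions with their catalog category (default "other")."""
    out: list[UsageEvent] = []
    for e in events:
        if e.event_type == "app_session" and e.package is not None:
            out.append(replace(e, category=mapping.get(e.package, "other")))
        else:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# I/O — raw log schema: header ``timestamp,record_type,value``

def write_raw_log(records: Iterable[RawLogRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "record_type", "value"])
        for rec in records:
            w.writerow([rec.timestamp.strftime(TS_FORMAT), rec.record_type, rec.value])


def read_raw_log(path) -> list[RawLogRecord]:
    records: list[RawLogRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            rec = RawLogRecord(
                datetime.strptime(row["timestamp"], TS_FORMAT),
                row["record_type"],
                row["value"],
            )
            rec.validate()
            records.append(rec)
    return records


def write_events_csv(events: Iterable[UsageEvent], user_id: str, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["user_id", "event_type", "package_or_empty", "category",
             "start_iso", "end_iso", "duration_s"]
        )
        for e in events:
            w.writerow(
                [user_id, e.event_type, e.package or "", e.category or "",
                 e.start.strftime(TS_FORMAT), e.end.strftime(TS_FORMAT),
                 f"{e.duration_s:.0f}"]
            )
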