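"""Event inference from raw call-state and foreground-app samples."""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import (
    brute_force_app_sessions,
    brute_force_call_events,
    random_app_stream,
    random_call_stream,
)
from phonemood.usage_log import (
    RawLogRecord,
    UsageEvent,
    ValidationError,
    categorize_apps,
    infer_app_sessions,
    infer_call_events,
    infer_events,
    top_apps,
)

T0 = datetime(2024, 1, 1, 12, 0, 0)


def _calls(*pairs):
    return [
        RawLogRecord(T0 + timedelta(seconds=s), "call_state", v)
        for s, v in pairs
    ]


def _apps(*pairs):
    return [RawLogRecord(T0 + timedelta(seconds=s), "app", v) for s, v in pairs]


class TestCallInference:
    @pytest.mark.parametrize(
        "stream,expected",
        [
            # ringing run returning to idle -> missed call over the ring span
            (
                [(0, "idle"), (3, "ringing"), (6, "ringing"), (9, "idle")],
                [("call_missed", 3, 9)],
            ),
            # offhook entered from idle -> outgoing call, 6 s duration
            (
                [(0, "idle"), (3, "offhook"), (6, "offhook"), (9, "idle")],
                [("call_out", 3, 9)],
            ),
            # answered ring -> call_in starting at the first offhook sample
            (
                [(0, "idle"), (3, "ringing"), (6, "offhook"), (9, "offhook"),
                 (12, "idle")],
                [("call_in", 6, 12)],
            ),
            # single offhook sample stream -> one-period outgoing call
            ([(0, "offhook")], [("call_out", 0, 3)]),
            # sampling dropout (> 2 periods) closes the open call
            (
                [(0, "offhook"), (3, "offhook"), (60, "offhook"), (63, "idle")],
                [("call_out", 0, 6), ("call_out", 60, 63)],
            ),
        ],
    )
    def test_transition_rules(self, stream, expected):
        events = infer_call_events(_calls(*stream), 3)
        got = [
            (
                e.event_type,
                (e.start - T0).total_seconds(),
                (e.end - T0).total_seconds(),
            )
            for e in events
        ]
        assert got == expected

    def test_empty_stream(self):
        assert infer_call_events([], 3) == []

    def test_out_of_order_rejected(self):
        stream = _calls((3, "idle"), (0, "idle"))
        with pytest.raises(ValidationError):
            infer_call_events(stream, 3)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValidationError):
            infer_call_events(_calls((0, "busy")), 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_second_oracle(self, seed):
        stream = random_call_stream(seed)
        assert infer_call_events(stream, 3) == brute_force_call_events(
            stream, 3
        )


class TestAppSessions:
    def test_package_switch_closes_session(self):
        events = infer_app_sessions(
            _apps((0, "A"), (3, "A"), (6, "B"), (9, "B")), 3
        )
        apps = [e for e in events if e.event_type == "app_session"]
        assert [(e.package, (e.start - T0).total_seconds(),
                 (e.end - T0).total_seconds()) for e in apps] == [
            ("A", 0, 6), ("B", 6, 12)
        ]
        screens = [e for e in events if e.event_type == "screen_session"]
        assert len(screens) == 1
        assert (screens[0].end - screens[0].start).total_seconds() == 12

    def test_single_sample_has_one_period_duration(self):
        events = infer_app_sessions(_apps((0, "A")), 3)
        apps = [e for e in events if e.event_type == "app_session"]
        assert len(apps) == 1 and apps[0].duration_s == 3

    def test_gap_splits_sessions(self):
        events = infer_app_sessions(_apps((0, "A"), (300, "A")), 3)
        apps = [e for e in events if e.event_type == "app_session"]
        assert len(apps) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_second_oracle(self, seed):
        stream = random_app_stream(seed)
        assert infer_app_sessions(stream, 3) == brute_force_app_sessions(
            stream, 3
        )

    def test_screen_duration_bounds(self):
        # total screen time >= any single app session, <= sum of sessions
        stream = random_app_stream(99)
        events = infer_app_sessions(stream, 3)
        apps = [e.duration_s for e in events if e.event_type == "app_session"]
        screen = sum(
            e.duration_s for e in events if e.event_type == "screen_session"
        )
        assert screen >= max(apps)
        assert screen <= sum(apps) + 2 * 3 * len(apps)  # merge slack only


def test_channel_interleaving_is_irrelevant():
    calls = _calls((0, "idle"), (3, "offhook"), (9, "idle"))
    apps = _apps((2, "A"), (5, "A"))
    mixed = sorted(calls + apps, key=lambda r: r.timestamp)
    assert infer_events(mixed, 3) == infer_events(calls + apps, 3)


class TestTopApps:
    def _sessions(self, spec):
        out = []
        t = T0
        for pkg, dur in spec:
            out.append(
                UsageEvent("app_session", t, t + timedelta(seconds=dur),
                           package=pkg)
            )
            t += timedelta(seconds=dur + 60)
        return out

    def test_ranked_by_total_duration(self):
        events = self._sessions([("A", 100), ("B", 200)])
        assert top_apps(events, 2) == ["B", "A"]

    def test_ties_break_lexicographically(self):
        events = self._sessions([("b", 100), ("a", 50), ("a", 50)])
        assert top_apps(events, 2) == ["a", "b"]

    def test_k_larger_than_catalog(self):
        events = self._sessions([("A", 10), ("B", 20)])
        assert set(top_apps(events, 10)) == {"A", "B"}
        assert top_apps([], 3) == []


@given(st.sampled_from(["mapped.app", "unknown.app"]))
@settings(deadline=None)
def test_categorize_apps_fallback(pkg):
    e = UsageEvent("app_session", T0, T0 + timedelta(seconds=10), package=pkg)
    (annotated,) = categorize_apps([e], {"mapped.app": "social"})
    assert annotated.category == ("social" if pkg == "mapped.app" else "other")
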