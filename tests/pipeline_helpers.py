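"""Shared in-memory cohort preparation for pipeline-level tests."""

from __future__ import annotations

import numpy as np

from phonemood.feature_extraction import (
    Timeslot,
    build_design_matrix,
    usage_types_for_user,
)
from phonemood.synthetic_data import SimConfig, simulate_cohort, split_tags
from phonemood.usage_log import categorize_apps, infer_events


def prepare_cohort(cfg: SimConfig, timeslots=(0.5, 1.0, 1.5, 2.0)):
    """Simulate, infer events and build per-slot training matrices.

    Returns ``{user: {"matrices", "events", "train_tags", "eval_tags",
    "usage_types", "truth"}}``.
    """
    out = {}
    for uid, (records, tags, truth) in simulate_cohort(cfg).items():
        events = categorize_apps(
            infer_events(records, cfg.sample_period), cfg.category_map
        )
        train_tags, eval_tags = split_tags(cfg, tags)
        train_events = [e for e in events if e.start < cfg.train_cutoff]
        utypes = usage_types_for_user(train_events, cfg.category_map)
        out[uid] = {
            "matrices": {
                s: build_design_matrix(
                    train_events, train_tags, Timeslot(s), utypes
                )
                for s in timeslots
            },
            "events": events,
            "train_tags": train_tags,
            "eval_tags": eval_tags,
            "usage_types": utypes,
            "truth": truth,
        }
    return out


def holdout_matrix(user_data, slot_hours: float):
    """Design matrix and labels for the user's evaluation-phase tags."""
    return build_design_matrix(
        user_data["events"],
        user_data["eval_tags"],
        Timeslot(slot_hours),
        user_data["usage_types"],
    )
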