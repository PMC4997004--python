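"""Visual-analog-scale (VAS) emotion reports and their 3-category mapping.

Subjects report momentary depression, anxiety and stress on 0–100 sliders.
For prediction-success accounting each scale is divided into three equal
thirds — low ``[0, 100/3)``, medium ``[100/3, 200/3)``, high
``[200/3, 100]`` — with the upper category winning at a cut point.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, NamedTuple, Sequence

from .usage_log import TS_FORMAT

__all__ = [
    "SCALES",
    "CATEGORIES",
    "EmotionTag",
    "categorize",
    "categorize_tag",
    "validate_training_set",
    "check_min_gap",
    "read_tags",
    "write_tags",
]

SCALES = ("depression", "anxiety", "stress")
#: Total order low < medium < high.
CATEGORIES = ("low", "medium", "high")

_LOW_CUT = 100.0 / 3.0
_HIGH_CUT = 200.0 / 3.0


class EmotionTag(NamedTuple):
    timestamp: datetime
    depression: int
    anxiety: int
    stress: int

    def value(self, scale: str) -> int:
        return getattr(self, scale)


def categorize(value: float) -> str:
    """Map a VAS value to its third of the scale range.

    Raises ``ValueError`` outside [0, 100].
    """
    if not 0 <= value <= 100:
        raise ValueError(f"VAS value {value} outside [0, 100]")
    if value < _LOW_CUT:
        return "low"
    if value < _HIGH_CUT:
        return "medium"
    return "high"


def categorize_tag(tag: EmotionTag) -> dict[str, str]:
    return {scale: categorize(tag.value(scale)) for scale in SCALES}


@dataclass(frozen=True)
class TrainingSetStatus:
    accepted: bool
    n_tags: int
    minimum: int


def validate_training_set(
    tags: Sequence[EmotionTag], minimum: int = 40
) -> TrainingSetStatus:
    """Accept a user's training tags only if at least ``minimum`` exist."""
    return TrainingSetStatus(len(tags) >= minimum, len(tags), minimum)


def check_min_gap(tags: Sequence[EmotionTag], min_gap_hours: float) -> int:
    """Warn (never reject) on consecutive tags closer than the minimum gap.

    Returns the number of violations.
    """
    ordered = sorted(tags, key=lambda t: t.timestamp)
    violations = 0
    for a, b in zip(ordered, ordered[1:]):
        if (b.timestamp - a.timestamp).total_seconds() < min_gap_hours * 3600:
            violations += 1
    if violations:
        warnings.warn(
            f"{violations} consecutive tag pairs closer than "
            f"{min_gap_hours} h minimum gap",
            stacklevel=2,
        )
    return violations


def write_tags(tags: Iterable[EmotionTag], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "depression", "anxiety", "stress"])
        for t in tags:
            w.writerow(
                [t.timestamp.strftime(TS_FORMAT), t.depression, t.anxiety, t.stress]
            )


def read_tags(path) -> list[EmotionTag]:
    tags: list[EmotionTag] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            tag = EmotionTag(
                datetime.strptime(row["timestamp"], TS_FORMAT),
                int(row["depression"]),
                int(row["anxiety"]),
                int(row["stress"]),
            )
            for scale in SCALES:
                if not 0 <= tag.value(scale) <= 100:
                    raise ValueError(
                        f"{scale} value {tag.value(scale)} outside [0, 100]"
                    )
            tags.append(tag)
    return tags
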