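"""Prospective evaluation: 2-hourly predictions, success accounting, benchmarks.

During the evaluation phase the deployed personalized model issues seven
predictions per day, every 2 hours from 11:00 to 23:00.  The subject may
correct a prediction by re-reporting the three VAS values; a prediction
*succeeds* only if all three corrected values fall in the predicted
categories.  Accuracy accounting follows the study-report convention:

* per-user accuracy  = 100 x successful / responded,
* cohort mean        = unweighted mean of per-user accuracies,
* pooled rate        = 100 x total successful / total responded,
* feedback rate      = 100 x responded / predictions made.

Two benchmark predictors are included: per-scale ordinary least squares
on the raw VAS values (prediction = category of the clipped fitted
value), and the "general guess" — always the user's most frequent
training category, ties resolved toward the lower category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .emotion_tags import CATEGORIES, SCALES, categorize

__all__ = [
    "EVAL_HOURS",
    "PredictionRecord",
    "EvaluationSummary",
    "schedule_predictions",
    "judge",
    "summarize",
    "summarize_counts",
    "feedback_rate",
    "benchmark_linear",
    "benchmark_guess",
    "LinearBenchmark",
    "GuessBenchmark",
    "round_half_up",
]

#: Prediction hours: every 2 h from 11:00 to 23:00 (7 per day).
EVAL_HOURS = tuple(range(11, 24, 2))


def schedule_predictions(day: date) -> list[datetime]:
    """The seven daily prediction timestamps, 11:00–23:00 every 2 h.

    Naive datetimes denote UTC, matching the on-disk timestamp schema.
    """
    return [datetime.combine(day, time(hour=h)) for h in EVAL_HOURS]


def judge(
    prediction: Mapping[str, str], corrected: Mapping[str, float]
) -> bool:
    """Success iff every corrected VAS value falls in its predicted category."""
    return all(
        categorize(corrected[scale]) == prediction[scale] for scale in SCALES
    )


@dataclass(frozen=True)
class PredictionRecord:
    user: str
    timestamp: datetime
    predicted: Mapping[str, str]
    corrected: Mapping[str, float] | None = None
    responded: bool = False

    @property
    def success(self) -> bool | None:
        if not self.responded or self.corrected is None:
            return None
        return judge(self.predicted, self.corrected)


def round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationSummary:
    per_user: pd.DataFrame  # user, days, n_responded, n_success, accuracy_pct
    total_responded: int
    total_success: int
    pooled_accuracy_pct: float
    cohort_mean_accuracy_pct: float
    n_predictions_made: int | None = None
    feedback_rate_pct: float | None = None
    excluded_users: list[str] = field(default_factory=list)


def summarize_counts(
    rows: Sequence[tuple[str, int, int, int]],
    n_predictions_made: int | None = None,
) -> EvaluationSummary:
    """Accuracy accounting from per-user (user, days, responded, successful).

    Users with zero responses are excluded from the cohort mean with a
    warning.  Percentages are rounded half-up to two decimals.
    """
    records = []
    excluded = []
    for user, days, responded, success in rows:
        if success > responded:
            raise ValueError(f"user {user}: successes exceed responses")
        if responded == 0:
            excluded.append(user)
            warnings.warn(f"user {user} has no responses; excluded from mean")
            acc = np.nan
        else:
            acc = round_half_up(100.0 * success / responded)
        records.append(
            {"user": user, "days": days, "n_responded": responded,
             "n_success": success, "accuracy_pct": acc}
        )
    per_user = pd.DataFrame(
        records,
        columns=["user", "days", "n_responded", "n_success", "accuracy_pct"],
    )
    total_resp = int(per_user["n_responded"].sum())
    total_succ = int(per_user["n_success"].sum())
    pooled = 100.0 * total_succ / total_resp if total_resp else float("nan")
    valid = per_user["accuracy_pct"].dropna()
    cohort_mean = (
        round_half_up(float(valid.mean())) if len(valid) else float("nan")
    )
    fb = (
        feedback_rate(n_predictions_made, total_resp)
        if n_predictions_made
        else None
    )
    return EvaluationSummary(
        per_user, total_resp, total_succ, pooled, cohort_mean,
        n_predictions_made, fb, excluded,
    )


def summarize(records: Sequence[PredictionRecord]) -> EvaluationSummary:
    """Accuracy accounting from raw prediction records."""
    users = sorted({r.user for r in records})
    rows = []
    for user in users:
        mine = [r for r in records if r.user == user]
        days = len({r.timestamp.date() for r in mine})
        responded = [r for r in mine if r.responded]
        success = sum(1 for r in responded if r.success)
        rows.append((user, days, len(responded), success))
    return summarize_counts(rows, n_predictions_made=len(records))


def feedback_rate(n_made: int, n_responded: int) -> float:
    """Percentage of issued predictions that received feedback."""
    if n_made <= 0:
        raise ValueError("no predictions made")
    return round_half_up(100.0 * n_responded / n_made)


# ---------------------------------------------------------------------------
# Benchmarks

@dataclass
class LinearBenchmark:
    """Per-scale OLS on raw VAS values; predicts the fitted value's category."""

    coef: dict[str, np.ndarray]  # scale -> (d + 1,) with intercept last
    feature_keys: list[str]

    def predict_values(self, X) -> pd.DataFrame:
        Xa = _design(_as_array(X))
        return pd.DataFrame(
            {s: np.clip(Xa @ self.coef[s], 0.0, 100.0) for s in SCALES}
        )

    def predict(self, X) -> pd.DataFrame:
        vals = self.predict_values(X)
        return vals.apply(lambda col: col.map(categorize))


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(
        X, dtype=float
    )


def _design(Xa: np.ndarray) -> np.ndarray:
    return np.hstack([Xa, np.ones((len(Xa), 1))])


def benchmark_linear(X, vas_labels: pd.DataFrame) -> LinearBenchmark:
    """Fit per-scale multiple linear regression on the raw VAS values.

    Rank-deficient designs fall back to the minimum-norm least-squares
    solution with a warning.
    """
    Xa = _design(_as_array(X))
    keys = list(X.columns) if hasattr(X, "columns") else [
        f"f{i}" for i in range(Xa.shape[1] - 1)
    ]
    coef = {}
    for scale in SCALES:
        yv = np.asarray(vas_labels[scale], dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(Xa, yv, rcond=None)
        if rank < Xa.shape[1]:
            warnings.warn(
                f"rank-deficient design for {scale}; minimum-norm fit used"
            )
        coef[scale] = beta
    return LinearBenchmark(coef, keys)


@dataclass
class GuessBenchmark:
    """Always predicts the user's most frequent training category."""

    majority: dict[str, str]

    def predict(self, n: int) -> pd.DataFrame:
        return pd.DataFrame({s: [self.majority[s]] * n for s in SCALES})


def benchmark_guess(category_labels: pd.DataFrame) -> GuessBenchmark:
    """Per-scale majority category; ties resolve to the lower category."""
    if len(category_labels) == 0:
        raise ValueError("at least one training label required")
    majority = {}
    for scale in SCALES:
        counts = category_labels[scale].value_counts()
        best = max(
            CATEGORIES,
            key=lambda c: (counts.get(c, 0), -CATEGORIES.index(c)),
        )
        majority[scale] = best
    return GuessBenchmark(majority)


def summary_to_frame(summary: EvaluationSummary) -> pd.DataFrame:
    """Per-user table mirroring the evaluation report layout."""
    df = summary.per_user.copy()
    total = pd.DataFrame(
        [{
            "user": "Total",
            "days": round_half_up(float(df["days"].mean())) if len(df) else 0,
            "n_responded": summary.total_responded,
            "n_success": summary.total_success,
            "accuracy_pct": summary.cohort_mean_accuracy_pct,
        }]
    )
    return pd.concat([df, total], ignore_index=True)
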