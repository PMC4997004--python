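"""Per-user feature selection: two-level t-test filters and greedy wrappers.

The three-category labels (low / medium / high) are reduced to two binary
contrasts before testing each feature:

* level 1 — ``{low}`` vs ``{medium, high}``,
* level 2 — ``{low, medium}`` vs ``{high}``.

Five methods are provided:

``ttest``
    Welch (unequal-variance) two-sample t test per feature at each level;
    a feature is kept if P < .05 at either level.  If fewer than five
    features are kept the set is filled to five with the smallest
    remaining (min-over-levels) P values.
``ttest_homoscedastic``
    Pooled-variance t test; starting from the full feature set, every
    feature with P < .05 at either level is deleted (a small P marks a
    feature whose groups differ, i.e. low between-group similarity).  If
    deletion empties the set, the five largest-P features are retained.
``greedy_forward`` / ``greedy_backward`` / ``greedy_bidirectional``
    Best-first wrapper searches scored by seeded stratified
    cross-validated classifier accuracy; they stop when no single
    addition / removal strictly improves the score, and never re-evaluate
    a feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .classifiers import (
    ClassifierSpec,
    cross_validated_accuracy,
    majority_cv_accuracy,
)

__all__ = [
    "METHODS",
    "P_THRESHOLD",
    "MIN_FEATURES",
    "TwoLevelSplit",
    "DEFAULT_SPLIT",
    "SelectionResult",
    "SelectionError",
    "level_pvalues",
    "ttest_select",
    "ttest_homoscedastic_select",
    "greedy_select",
    "make_cv_scorer",
    "select",
]

METHODS = (
    "ttest",
    "ttest_homoscedastic",
    "greedy_forward",
    "greedy_backward",
    "greedy_bidirectional",
)
P_THRESHOLD = 0.05
MIN_FEATURES = 5
_IMPROVEMENT_EPS = 1e-12


class SelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class TwoLevelSplit:
    """Two binary partitions of the three emotion categories."""

    level1: tuple[frozenset, frozenset] = (
        frozenset({"low"}),
        frozenset({"medium", "high"}),
    )
    level2: tuple[frozenset, frozenset] = (
        frozenset({"low", "medium"}),
        frozenset({"high"}),
    )

    @property
    def levels(self) -> tuple[tuple[frozenset, frozenset], ...]:
        return (self.level1, self.level2)


DEFAULT_SPLIT = TwoLevelSplit()


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    pvalues: dict[str, float] | None = None
    trajectory: list[tuple] = field(default_factory=list)
    final_score: float | None = None


def _columns(X) -> list[str]:
    return list(X.columns) if hasattr(X, "columns") else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(
        X, dtype=float
    )


def level_pvalues(
    X, labels, split: TwoLevelSplit = DEFAULT_SPLIT, equal_var: bool = False
) -> np.ndarray:
    """Per-feature P values for each usable level, shape (n_levels, n_feat).

    A level whose either side has fewer than two samples is skipped with a
    warning (its row is all-NaN); if no level is usable a
    ``SelectionError`` is raised.  Features with undefined t statistics
    (zero variability in both groups) get NaN.
    """
    Xa = _as_array(X)
    y = np.asarray(labels)
    out = np.full((len(split.levels), Xa.shape[1]), np.nan)
    usable = 0
    for i, (side_a, side_b) in enumerate(split.levels):
        mask_a = np.isin(y, list(side_a))
        mask_b = np.isin(y, list(side_b))
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            warnings.warn(
                f"level {i + 1} skipped: a group has fewer than 2 samples"
            )
            continue
        usable += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                Xa[mask_a], Xa[mask_b], axis=0, equal_var=equal_var
            )
        out[i] = res.pvalue
    if usable == 0:
        raise SelectionError("no level of the two-level split is testable")
    return out


def ttest_select(
    X, labels, split: TwoLevelSplit = DEFAULT_SPLIT,
    p_threshold: float = P_THRESHOLD, minimum: int = MIN_FEATURES,
) -> SelectionResult:
    """Welch two-level filter: keep P < threshold at either level.

    Fills to ``minimum`` features by smallest min-over-levels P when the
    threshold keeps fewer; features with undefined t statistics are never
    auto-selected (they can only enter through nothing else existing).
    """
    cols = _columns(X)
    pv = level_pvalues(X, labels, split, equal_var=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_min = np.nanmin(pv, axis=0)
    hit = np.nan_to_num(pv, nan=np.inf) < p_threshold
    selected_idx = [i for i in range(len(cols)) if hit[:, i].any()]
    if len(selected_idx) < minimum:
        rest = [
            i for i in np.argsort(p_min, kind="stable")
            if i not in set(selected_idx) and np.isfinite(p_min[i])
        ]
        selected_idx += rest[: minimum - len(selected_idx)]
    order = sorted(
        selected_idx,
        key=lambda i: (p_min[i] if np.isfinite(p_min[i]) else np.inf, i),
    )
    return SelectionResult(
        "ttest",
        [cols[i] for i in order],
        pvalues={cols[i]: float(p_min[i]) for i in range(len(cols))},
    )


def ttest_homoscedastic_select(
    X, labels, split: TwoLevelSplit = DEFAULT_SPLIT,
    p_threshold: float = P_THRESHOLD, minimum: int = MIN_FEATURES,
) -> SelectionResult:
    """Pooled-variance deletion filter: start full, delete P < threshold."""
    cols = _columns(X)
    pv = level_pvalues(X, labels, split, equal_var=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_min = np.nanmin(pv, axis=0)
    delete = np.nan_to_num(pv, nan=np.inf) < p_threshold
    kept = [i for i in range(len(cols)) if not delete[:, i].any()]
    if not kept:
        finite = np.where(np.isfinite(p_min), p_min, -np.inf)
        kept = sorted(
            np.argsort(-finite, kind="stable")[:minimum].tolist()
        )
    return SelectionResult(
        "ttest_homoscedastic",
        [cols[i] for i in kept],
        pvalues={cols[i]: float(p_min[i]) for i in range(len(cols))},
    )


def make_cv_scorer(
    spec: ClassifierSpec, X, labels, folds: int = 5, seed: int = 0
) -> Callable[[tuple[int, ...]], float]:
    """Scorer over feature-index subsets: seeded stratified CV accuracy.

    The empty subset scores as the cross-validated accuracy of predicting
    the training-fold majority category.
    """
    Xa = _as_array(X)
    y = np.asarray(labels)

    def scorer(subset: tuple[int, ...]) -> float:
        if not subset:
            return majority_cv_accuracy(y, folds=folds, seed=seed)
        return cross_validated_accuracy(
            spec, Xa[:, list(subset)], y, folds=folds, seed=seed
        )

    return scorer


def greedy_select(
    X, labels, direction: str,
    scorer: Callable[[tuple[int, ...]], float],
) -> SelectionResult:
    """Best-first wrapper search over feature subsets.

    ``forward`` starts empty and adds; ``backward`` starts full and
    drops; ``bidirectional`` starts empty and at each step takes the
    better of the best single addition and the best single removal.
    A step is taken only on strict score improvement; ties among
    candidate features are broken by column order; no subset is ever
    scored twice.
    """
    cols = _columns(X)
    if not cols:
        raise SelectionError("empty feature pool")
    if direction not in {"forward", "backward", "bidirectional"}:
        raise ValueError(f"unknown direction {direction!r}")
    all_idx = tuple(range(len(cols)))
    cache: dict[tuple[int, ...], float] = {}

    def score(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = scorer(subset)
        return cache[subset]

    current: tuple[int, ...] = all_idx if direction == "backward" else ()
    cur_score = score(current)
    trajectory: list[tuple] = [("start", None, cur_score)]

    while True:
        candidates: list[tuple[float, int, str, tuple[int, ...]]] = []
        if direction in {"forward", "bidirectional"}:
            for i in all_idx:
                if i not in current:
                    nxt = tuple(sorted(current + (i,)))
                    if nxt not in cache or cache[nxt] > cur_score:
                        candidates.append((score(nxt), i, "add", nxt))
        if direction in {"backward", "bidirectional"}:
            for i in current:
                nxt = tuple(j for j in current if j != i)
                if nxt not in cache or cache[nxt] > cur_score:
                    candidates.append((score(nxt), i, "drop", nxt))
        if not candidates:
            break
        # best score; ties by action order then column order (stable sort)
        best = max(candidates, key=lambda c: c[0])
        if best[0] <= cur_score + _IMPROVEMENT_EPS:
            break
        # among equal best scores prefer the earliest candidate
        best = next(c for c in candidates if c[0] == best[0])
        cur_score, current = best[0], best[3]
        trajectory.append((best[2], cols[best[1]], cur_score))

    return SelectionResult(
        f"greedy_{direction}",
        [cols[i] for i in current],
        trajectory=trajectory,
        final_score=cur_score,
    )


def select(
    method: str, X, labels,
    spec: ClassifierSpec | None = None,
    split: TwoLevelSplit = DEFAULT_SPLIT,
    folds: int = 5, seed: int = 0,
) -> SelectionResult:
    """Dispatch one of the five selection methods by name."""
    if method == "ttest":
        return ttest_select(X, labels, split)
    if method == "ttest_homoscedastic":
        return ttest_homoscedastic_select(X, labels, split)
    if method in {"greedy_forward", "greedy_backward", "greedy_bidirectional"}:
        if spec is None:
            raise ValueError("greedy selection requires a classifier spec")
        scorer = make_cv_scorer(spec, X, labels, folds=folds, seed=seed)
        return greedy_select(X, labels, method.removeprefix("greedy_"), scorer)
    raise ValueError(f"unknown selection method {method!r}")
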