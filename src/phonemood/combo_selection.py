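"""Detection-classifier selection by rank-product scoring.

Every (timeslot, feature-selection method, classifier family) triple is a
candidate *combination*.  Each combination is cross-validated per
(user, scale) context; within a context the combinations are ranked by
accuracy (rank 1 best, ties get the average rank) and a combination's
score is the geometric mean of its ranks across contexts, so a single
outlying accuracy cannot dominate the choice.

The final choice is two-staged: for each selection method the
rank-product-best (timeslot, family) pair is fixed, then among the five
method winners the one with the highest mean accuracy over the three VAS
scales (averaged over users) is deployed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifiers import ClassifierSpec, cross_validated_accuracy, majority_cv_accuracy
from .emotion_tags import SCALES
from .feature_selection import (
    METHODS,
    SelectionError,
    make_cv_scorer,
    greedy_select,
    ttest_homoscedastic_select,
    ttest_select,
)
from .feature_extraction import DEFAULT_TIMESLOT_HOURS

__all__ = [
    "ComboResult",
    "RankProductScore",
    "FinalChoice",
    "evaluate_all_combos",
    "rank_product",
    "select_final",
    "results_to_frame",
]

FAMILIES = ("naive_bayes", "c45_tree", "nb_tree", "svm")


@dataclass(frozen=True)
class ComboResult:
    user: str
    scale: str
    timeslot_hours: float
    method: str
    family: str
    accuracy: float | None  # None = selection failed for this combo
    n_features: int = 0
    error: str | None = None

    @property
    def combo(self) -> tuple[float, str, str]:
        return (self.timeslot_hours, self.method, self.family)


@dataclass(frozen=True)
class RankProductScore:
    combo: tuple[float, str, str]
    ranks: tuple[float, ...]
    score: float  # geometric mean of per-context ranks


@dataclass(frozen=True)
class FinalChoice:
    timeslot_hours: float
    method: str
    family: str
    mean_accuracy: float
    method_winners: tuple = ()


def _fold_seed(master_seed: int, *parts) -> int:
    """Stable per-combination fold seed below 2**31."""
    token = "|".join(str(p) for p in parts).encode()
    return (master_seed * 1_000_003 + zlib.crc32(token)) % (2**31 - 1)


def evaluate_all_combos(
    user_matrices: Mapping[str, Mapping[float, tuple]],
    timeslots: Sequence[float] = DEFAULT_TIMESLOT_HOURS,
    methods: Sequence[str] = METHODS,
    families: Sequence[str] = FAMILIES,
    folds: int = 5,
    seed: int = 0,
) -> list[ComboResult]:
    """Cross-validate the full combination grid for every (user, scale).

    ``user_matrices[user][slot_hours]`` is the ``(X, y)`` pair returned by
    :func:`phonemood.feature_extraction.build_design_matrix` (the metadata
    element may be included and is ignored here).  Filter selections are
    computed once per (user, scale, slot, method) and reused across
    families; a greedy wrapper is scored with the same family it selects
    for, so its final search score is the combination's accuracy.
    """
    results: list[ComboResult] = []
    for user in sorted(user_matrices):
        for slot in timeslots:
            X, y = user_matrices[user][slot][:2]
            for scale in SCALES:
                labels = np.asarray(y[scale])
                for method in methods:
                    results.extend(
                        _eval_method(
                            user, scale, slot, method, X, labels,
                            families, folds, seed,
                        )
                    )
    return results


def _eval_method(
    user, scale, slot, method, X, labels, families, folds, master_seed
) -> list[ComboResult]:
    out: list[ComboResult] = []
    if method in {"ttest", "ttest_homoscedastic"}:
        fn = ttest_select if method == "ttest" else ttest_homoscedastic_select
        try:
            sel = fn(X, labels)
        except SelectionError as exc:
            return [
                ComboResult(user, scale, slot, method, fam, None, 0, str(exc))
                for fam in families
            ]
        cols = sel.selected
        Xs = X[cols]
        for fam in families:
            fseed = _fold_seed(master_seed, user, scale, slot, method, fam)
            spec = ClassifierSpec(fam, seed=fseed)
            if cols:
                acc = cross_validated_accuracy(
                    spec, Xs, labels, folds=folds, seed=fseed
                )
            else:
                acc = majority_cv_accuracy(labels, folds=folds, seed=fseed)
            out.append(
                ComboResult(user, scale, slot, method, fam, acc, len(cols))
            )
        return out
    # greedy wrappers: selection is family-specific
    for fam in families:
        fseed = _fold_seed(master_seed, user, scale, slot, method, fam)
        spec = ClassifierSpec(fam, seed=fseed)
        try:
            scorer = make_cv_scorer(spec, X, labels, folds=folds, seed=fseed)
            sel = greedy_select(X, labels, method.removeprefix("greedy_"), scorer)
        except (SelectionError, ValueError) as exc:
            out.append(
                ComboResult(user, scale, slot, method, fam, None, 0, str(exc))
            )
            continue
        out.append(
            ComboResult(
                user, scale, slot, method, fam,
                sel.final_score, len(sel.selected),
            )
        )
    return out


def rank_product(results: Sequence[ComboResult]) -> list[RankProductScore]:
    """Geometric-mean rank of each combination across (user, scale) contexts.

    Within each context combinations are ranked by accuracy descending
    (rank 1 best, average ranks on ties); a combination missing from a
    context, or whose selection failed there, gets that context's worst
    rank.  Output is sorted ascending by score (best first), ties broken
    by the combination key.
    """
    if not results:
        raise ValueError("no combination results to rank")
    combos = sorted({r.combo for r in results})
    contexts = sorted({(r.user, r.scale) for r in results})
    acc = {(r.user, r.scale, r.combo): r.accuracy for r in results}
    n_combos = len(combos)
    ranks = np.empty((len(contexts), n_combos))
    for ci, ctx in enumerate(contexts):
        values = np.array(
            [
                -np.inf
                if (a := acc.get((ctx[0], ctx[1], c))) is None
                else a
                for c in combos
            ]
        )
        ranks[ci] = rankdata(-values, method="average")
    scores = np.exp(np.mean(np.log(ranks), axis=0))
    out = [
        RankProductScore(combos[i], tuple(ranks[:, i]), float(scores[i]))
        for i in range(n_combos)
    ]
    return sorted(out, key=lambda s: (s.score, s.combo))


def select_final(results: Sequence[ComboResult]) -> FinalChoice:
    """Two-stage choice: per-method rank-product winner, then best mean
    accuracy over the three scales (averaged over users and scales).

    Ties are broken toward the smaller timeslot, then method name order.
    """
    methods = sorted({r.method for r in results})
    winners = []
    for method in methods:
        sub = [r for r in results if r.method == method]
        best = rank_product(sub)[0]
        slot, _, family = best.combo
        accs = [
            r.accuracy
            for r in sub
            if r.combo == best.combo and r.accuracy is not None
        ]
        mean_acc = float(np.mean(accs)) if accs else float("-inf")
        winners.append((method, slot, family, mean_acc, best.score))
    # highest mean accuracy; ties -> smaller timeslot, then method order
    chosen = max(winners, key=lambda w: (w[3], -w[1], _neg_name(w[0])))
    method, slot, family, mean_acc, _ = chosen
    return FinalChoice(slot, method, family, mean_acc, tuple(winners))


class _neg_name(str):
    """Reverse lexicographic comparison so max() prefers earlier names."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def results_to_frame(results: Sequence[ComboResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "user": r.user,
                "scale": r.scale,
                "timeslot_hours": r.timeslot_hours,
                "method": r.method,
                "family": r.family,
                "accuracy": r.accuracy,
                "n_features": r.n_features,
                "error": r.error or "",
            }
            for r in results
        ]
    )
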