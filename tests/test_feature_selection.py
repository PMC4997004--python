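"""Two-level t-test filters and greedy wrapper searches."""

import numpy as np
import pandas as pd
import pytest

from phonemood.classifiers import ClassifierSpec
from phonemood.feature_selection import (
    SelectionError,
    greedy_select,
    level_pvalues,
    make_cv_scorer,
    select,
    ttest_homoscedastic_select,
    ttest_select,
)
from phonemood.synthetic_data import SimConfig, simulate_user, split_tags
from phonemood.usage_log import categorize_apps, infer_events
from phonemood.feature_extraction import (
    Timeslot,
    build_design_matrix,
    usage_types_for_user,
)


def _labels(n_low=20, n_med=10, n_high=10):
    return np.array(["low"] * n_low + ["medium"] * n_med + ["high"] * n_high)


def _noise_matrix(rng, n, d, prefix="f"):
    return pd.DataFrame(
        rng.normal(size=(n, d)), columns=[f"{prefix}{i}" for i in range(d)]
    )


class TestWelchFilter:
    def test_planted_feature_has_tiny_p(self):
        # 10-sd separation of low vs {medium, high} at 20 per side
        rng = np.random.default_rng(0)
        y = _labels(20, 10, 10)
        X = _noise_matrix(rng, 40, 6)
        X["planted"] = np.where(y == "low", 0.0, 10.0) + rng.normal(
            scale=1.0, size=40
        )
        res = ttest_select(X, y)
        assert "planted" in res.selected
        assert res.pvalues["planted"] < 1e-6

    def test_fills_to_five_on_pure_noise(self):
        rng = np.random.default_rng(1)
        y = _labels()
        X = _noise_matrix(rng, 40, 30)
        pv = level_pvalues(X, y)
        n_hits = int((np.nan_to_num(pv, nan=1.0) < 0.05).any(axis=0).sum())
        res = ttest_select(X, y)
        assert len(res.selected) == max(5, n_hits)

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(2)
        y = _labels()
        X = _noise_matrix(rng, 40, 10)
        X["flat"] = 1.0
        res = ttest_select(X, y)
        assert "flat" not in res.selected

    def test_empty_group_level_is_skipped(self):
        rng = np.random.default_rng(3)
        y = np.array(["low"] * 20 + ["medium"] * 20)  # no "high": level 2 dead
        X = _noise_matrix(rng, 40, 8)
        with pytest.warns(UserWarning, match="level 2 skipped"):
            res = ttest_select(X, y)
        assert len(res.selected) >= 5

    def test_single_category_errors(self):
        X = _noise_matrix(np.random.default_rng(4), 10, 3)
        with pytest.raises(SelectionError):
            ttest_select(X, np.array(["low"] * 10))


class TestHomoscedasticFilter:
    def test_significant_feature_deleted(self):
        rng = np.random.default_rng(5)
        y = _labels()
        X = _noise_matrix(rng, 40, 10)
        X["separating"] = np.where(y == "low", 0.0, 5.0) + rng.normal(size=40)
        res = ttest_homoscedastic_select(X, y)
        assert "separating" not in res.selected
        assert res.pvalues["separating"] < 0.05

    def test_all_insignificant_returns_full_set(self):
        rng = np.random.default_rng(1)  # no P < .05 among these columns
        y = _labels()
        X = _noise_matrix(rng, 40, 5)
        pv = level_pvalues(X, y, equal_var=True)
        assert not (np.nan_to_num(pv, nan=1.0) < 0.05).any()
        assert ttest_homoscedastic_select(X, y).selected == list(X.columns)

    def test_emptied_set_keeps_five_largest_p(self):
        rng = np.random.default_rng(7)
        y = _labels()
        shift = np.where(y == "low", 0.0, 8.0)
        X = pd.DataFrame(
            {f"s{i}": shift + rng.normal(size=40) for i in range(8)}
        )
        res = ttest_homoscedastic_select(X, y)
        assert len(res.selected) == 5


class TestGreedySearch:
    def _separable(self, seed=0, d=6, n=60):
        rng = np.random.default_rng(seed)
        X = _noise_matrix(rng, n, d)
        y = np.where(X["f0"] > 0, "high", "low")
        return X, y

    def test_forward_picks_the_separating_feature_first(self):
        X, y = self._separable()
        scorer = make_cv_scorer(ClassifierSpec("naive_bayes"), X, y, seed=0)
        res = greedy_select(X, y, "forward", scorer)
        assert res.trajectory[1][1] == "f0"
        assert res.final_score > 0.9

    def test_constant_scorer_edge_cases(self):
        X, y = self._separable()
        res_f = greedy_select(X, y, "forward", lambda s: 0.5)
        res_b = greedy_select(X, y, "backward", lambda s: 0.5)
        assert res_f.selected == []
        assert res_b.selected == list(X.columns)

    def test_forward_matches_exhaustive_best_subset(self):
        X, y = self._separable(seed=1)
        scorer = make_cv_scorer(ClassifierSpec("naive_bayes"), X, y, seed=3)
        res = greedy_select(X, y, "forward", scorer)
        d = X.shape[1]
        best = max(
            scorer(tuple(i for i in range(d) if mask >> i & 1))
            for mask in range(1, 2**d)
        )
        assert res.final_score == best == 1.0

    def test_no_subset_evaluated_twice_and_trajectory_improves(self):
        X, y = self._separable(seed=2)
        seen = []
        base = make_cv_scorer(ClassifierSpec("naive_bayes"), X, y, seed=1)

        def counting(subset):
            seen.append(subset)
            return base(subset)

        res = greedy_select(X, y, "bidirectional", counting)
        assert len(seen) == len(set(seen))
        scores = [step[2] for step in res.trajectory]
        assert scores == sorted(scores)
        assert res.final_score >= max(scores)

    def test_backward_drops_useless_features(self):
        X, y = self._separable(seed=4, d=4, n=80)
        scorer = make_cv_scorer(ClassifierSpec("naive_bayes"), X, y, seed=2)
        res = greedy_select(X, y, "backward", scorer)
        assert "f0" in res.selected

    def test_empty_pool_errors(self):
        with pytest.raises(SelectionError):
            greedy_select(pd.DataFrame(), np.array([]), "forward", lambda s: 0)


def test_all_methods_deterministic():
    rng = np.random.default_rng(8)
    y = _labels()
    X = _noise_matrix(rng, 40, 8)
    X["sig"] = np.where(y == "high", 3.0, 0.0) + rng.normal(size=40)
    spec = ClassifierSpec("naive_bayes")
    for method in ("ttest", "ttest_homoscedastic", "greedy_forward",
                   "greedy_backward", "greedy_bidirectional"):
        a = select(method, X, y, spec=spec, seed=11)
        b = select(method, X, y, spec=spec, seed=11)
        assert a.selected == b.selected


def test_planted_features_recovered_across_replicates():
    """Strong-coupling regime: the t-test filter finds >= 80% of the
    planted features, aggregated over 20 seeded single-user replicates."""
    recovered = total = 0
    for seed in range(100, 120):
        cfg = SimConfig(n_users=1, seed=seed, effect_size=40, noise_sd=3)
        records, tags, truth = simulate_user(cfg, "user00")
        events = categorize_apps(infer_events(records, 3), cfg.category_map)
        train_tags, _ = split_tags(cfg, tags)
        train_events = [e for e in events if e.start < cfg.train_cutoff]
        utypes = usage_types_for_user(train_events, cfg.category_map)
        X, y, _ = build_design_matrix(
            train_events, train_tags, Timeslot(2.0), utypes
        )
        for scale in ("depression", "anxiety", "stress"):
            sel = ttest_select(X, np.asarray(y[scale]))
            recovered += sum(k in sel.selected for k in truth.planted_features)
            total += len(truth.planted_features)
    assert recovered >= 0.8 * total
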