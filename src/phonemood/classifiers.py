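"""The four classifier families behind one training/prediction contract.

Every family maps a per-tag feature vector to a low/medium/high category:

* ``naive_bayes`` — per-class Gaussian per feature with variance
  smoothing (implemented in plain numpy: it sits in the inner loop of the
  wrapper feature searches, where estimator overhead dominates runtime);
* ``c45_tree``    — entropy (information-gain) decision tree with
  cost-complexity pruning, standing in for a C4.5-style pruned tree;
* ``nb_tree``     — a decision tree whose leaves hold naive-Bayes models;
  a split is accepted only if the cross-validated accuracy of the child
  leaf models beats that of the parent's single model;
* ``svm``         — RBF-kernel support vector machine, regularization 1.0,
  kernel scale set by the median heuristic on the training pairwise
  distances.

Models train per (user, scale): one three-category model per VAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "TrainedModel",
    "make_estimator",
    "train",
    "predict",
    "cross_validated_accuracy",
    "stratified_folds",
    "majority_cv_accuracy",
    "save_model",
    "load_model",
]

FAMILIES = ("naive_bayes", "c45_tree", "nb_tree", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    params: tuple = ()  # (name, value) pairs; keeps the spec hashable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)


class GaussianNBLite:
    """Gaussian naive Bayes with variance smoothing, minimal overhead."""

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNBLite":
        X = np.asarray(X, dtype=float)
        self.classes_, counts = np.unique(y, return_counts=True)
        n, d = X.shape
        k = len(self.classes_)
        self.theta_ = np.empty((k, d))
        self.var_ = np.empty((k, d))
        for i, c in enumerate(self.classes_):
            Xc = X[y == c]
            self.theta_[i] = Xc.mean(axis=0)
            self.var_[i] = Xc.var(axis=0)
        eps = self.var_smoothing * max(float(X.var(axis=0).max()), 1e-12)
        self.var_ += eps
        self.log_prior_ = np.log(counts / n)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        # (n, k) log joint: sum over features of the Gaussian log density
        diff = X[:, None, :] - self.theta_[None, :, :]
        ll = -0.5 * np.sum(
            np.log(2.0 * np.pi * self.var_) + diff**2 / self.var_, axis=2
        )
        return ll + self.log_prior_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)


class MedianGammaSVC:
    """RBF SVC whose gamma is 1 / (2 * median squared pairwise distance)."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MedianGammaSVC":
        X = np.asarray(X, dtype=float)
        n = len(X)
        sq = np.sum(X**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
        iu = np.triu_indices(n, k=1)
        med = float(np.median(d2[iu])) if n > 1 else 0.0
        gamma = 1.0 / (2.0 * med) if med > 0 else 1.0
        self._svc = SVC(C=self.C, kernel="rbf", gamma=gamma,
                        random_state=self.seed)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float))


class NBTreeClassifier:
    """Decision tree with naive-Bayes leaf models.

    At each node the single best entropy split (a depth-1 tree stump) is
    evaluated: it is accepted only if the weighted cross-validated
    accuracy of naive-Bayes models fitted in the children exceeds the
    cross-validated accuracy of a naive-Bayes model at the node itself.
    """

    def __init__(self, max_depth: int = 2, min_leaf: int = 8,
                 cv_folds: int = 3, seed: int = 0):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.cv_folds = cv_folds
        self.seed = seed

    @staticmethod
    def _nb_codes_fit(X: np.ndarray, onehot: np.ndarray):
        """Closed-form Gaussian NB on one-hot class codes (fast path)."""
        counts = onehot.sum(axis=0)
        present = counts > 0
        cnt = np.where(present, counts, 1.0)[:, None]
        theta = (onehot.T @ X) / cnt
        var = (onehot.T @ X**2) / cnt - theta**2
        var += 1e-9 * max(float(X.var(axis=0).max()), 1e-12)
        log_prior = np.where(
            present, np.log(np.maximum(counts, 1e-300) / len(X)), -np.inf
        )
        return log_prior, theta, var

    @staticmethod
    def _nb_codes_predict(model, X: np.ndarray) -> np.ndarray:
        log_prior, theta, var = model
        diff = X[:, None, :] - theta[None]
        ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + diff**2 / var, axis=2)
        return np.argmax(ll + log_prior, axis=1)

    def _node_cv(self, X: np.ndarray, codes: np.ndarray, k: int) -> float:
        """Cross-validated leaf-model accuracy at one node.

        Folds are a deterministic within-class round robin; degenerate
        nodes score as their majority-class rate.
        """
        n = len(codes)
        counts = np.bincount(codes, minlength=k)
        if (counts > 0).sum() < 2 or n < self.cv_folds:
            return float(counts.max() / n)
        fold = np.empty(n, dtype=int)
        for c in range(k):
            idx = np.flatnonzero(codes == c)
            fold[idx] = np.arange(len(idx)) % self.cv_folds
        onehot = np.eye(k)[codes]
        hits = 0
        for f in range(self.cv_folds):
            test = fold == f
            cts = np.bincount(codes[~test], minlength=k)
            if (cts > 0).sum() < 2:
                pred = np.full(int(test.sum()), int(np.argmax(cts)))
            else:
                model = self._nb_codes_fit(X[~test], onehot[~test])
                pred = self._nb_codes_predict(model, X[test])
            hits += int(np.sum(pred == codes[test]))
        return hits / n

    @staticmethod
    def _best_entropy_split(
        X: np.ndarray, codes: np.ndarray, k: int, min_leaf: int
    ) -> tuple[int, float] | None:
        """Single best (feature, threshold) by information gain."""
        n, d = X.shape
        onehot = np.eye(k)[codes]
        order = np.argsort(X, axis=0, kind="stable")  # (n, d)
        xs = np.take_along_axis(X, order, axis=0)
        counts = np.cumsum(onehot[order], axis=0)  # (n, d, k) left-side
        sizes = np.arange(1, n)[:, None]
        valid = (
            (sizes >= min_leaf)
            & (n - sizes >= min_leaf)
            & (xs[1:] > xs[:-1])  # threshold must separate values
        )
        if not valid.any():
            return None
        left = counts[:-1]  # (n-1, d, k)
        right = counts[-1][None] - left
        nl = left.sum(axis=2, keepdims=True)
        nr = right.sum(axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            pl = left / nl
            pr = right / nr
        # weighted child entropy per candidate split (lower is better)
        ent = (
            -np.sum(np.where(pl > 0, pl * np.log2(pl), 0.0), axis=2)
            * nl[..., 0]
            - np.sum(np.where(pr > 0, pr * np.log2(pr), 0.0), axis=2)
            * nr[..., 0]
        ) / n
        ent[~valid] = np.inf
        pos, j = np.unravel_index(int(np.argmin(ent)), ent.shape)
        thr = float((xs[pos, j] + xs[pos + 1, j]) / 2.0)
        return int(j), thr

    def _build(self, X: np.ndarray, codes: np.ndarray, k: int,
               depth: int) -> dict:
        counts = np.bincount(codes, minlength=k)
        if (counts > 0).sum() > 1:
            leaf_model = self._nb_codes_fit(X, np.eye(k)[codes])
        else:
            leaf_model = int(np.argmax(counts))  # constant-code leaf
        node = {"leaf": True, "model": leaf_model}
        if (
            depth >= self.max_depth
            or len(codes) < 2 * self.min_leaf
            or (counts > 0).sum() < 2
        ):
            return node
        split = self._best_entropy_split(X, codes, k, self.min_leaf)
        if split is None:
            return node
        feat, thr = split
        left = X[:, feat] <= thr
        if left.sum() < self.min_leaf or (~left).sum() < self.min_leaf:
            return node
        node_score = self._node_cv(X, codes, k)
        child_score = (
            left.sum() * self._node_cv(X[left], codes[left], k)
            + (~left).sum() * self._node_cv(X[~left], codes[~left], k)
        ) / len(codes)
        if child_score <= node_score + 1e-9:
            return node
        return {
            "leaf": False, "feature": feat, "threshold": thr,
            "left": self._build(X[left], codes[left], k, depth + 1),
            "right": self._build(X[~left], codes[~left], k, depth + 1),
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NBTreeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        self._root = self._build(X, codes, len(self.classes_), 0)
        return self

    def _predict_one(self, x: np.ndarray) -> int:
        node = self._root
        while not node["leaf"]:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        model = node["model"]
        if isinstance(model, int):
            return model
        return int(self._nb_codes_predict(model, x[None, :])[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.classes_[[self._predict_one(x) for x in X]]


class _ConstantModel:
    """Always predicts one category (single-class training data)."""

    def __init__(self, label: Any):
        self.label = label
        self.classes_ = np.array([label])

    def fit(self, X, y):  # pragma: no cover - interface symmetry
        return self

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.label)


def _majority(y: np.ndarray) -> Any:
    """Most frequent label; ties broken by label sort order (low first)."""
    vals, counts = np.unique(y, return_counts=True)
    return vals[np.argmax(counts)]


def make_estimator(spec: ClassifierSpec):
    p = spec.param_dict()
    if spec.family == "naive_bayes":
        return GaussianNBLite(var_smoothing=p.get("var_smoothing", 1e-9))
    if spec.family == "c45_tree":
        return DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=p.get("min_samples_leaf", 2),
            ccp_alpha=p.get("ccp_alpha", 0.01),
            random_state=spec.seed,
        )
    if spec.family == "nb_tree":
        return NBTreeClassifier(
            max_depth=p.get("max_depth", 2),
            min_leaf=p.get("min_leaf", 8),
            seed=spec.seed,
        )
    if spec.family == "svm":
        return MedianGammaSVC(C=p.get("C", 1.0), seed=spec.seed)
    raise ValueError(spec.family)  # pragma: no cover


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: Any
    feature_keys: list[str]
    classes: list[str]
    metadata: dict = field(default_factory=dict)


def train(
    spec: ClassifierSpec,
    X,
    labels: Sequence[str],
    feature_keys: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> TrainedModel:
    """Fit one model; single-class data degrades to a constant predictor."""
    Xa = _as_array(X)
    if Xa.size == 0 or len(labels) == 0:
        raise ValueError("empty training matrix")
    y = np.asarray(labels)
    if feature_keys is None:
        feature_keys = list(X.columns) if hasattr(X, "columns") else [
            f"f{i}" for i in range(Xa.shape[1])
        ]
    classes = sorted(set(y))
    if len(classes) < 2:
        warnings.warn("single-class training data; constant model returned")
        est: Any = _ConstantModel(classes[0])
    else:
        est = make_estimator(spec).fit(Xa, y)
    return TrainedModel(spec, est, list(feature_keys), classes, metadata or {})


def train_majority(
    labels: Sequence[str], metadata: dict | None = None
) -> TrainedModel:
    """Constant majority-category model (empty feature selections)."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty training labels")
    spec = ClassifierSpec("naive_bayes")
    return TrainedModel(
        spec, _ConstantModel(_majority(y)), [], sorted(set(y)),
        metadata or {},
    )


def predict(model: TrainedModel, features: dict[str, float]) -> np.ndarray:
    """Predict the category for one feature vector (dict keyed by feature)."""
    try:
        row = np.array([[features[k] for k in model.feature_keys]], dtype=float)
    except KeyError as exc:
        raise KeyError(f"feature vector missing key {exc.args[0]!r}") from exc
    return model.estimator.predict(row)[0]


def predict_matrix(model: TrainedModel, X) -> np.ndarray:
    return model.estimator.predict(_as_array(X))


def stratified_folds(
    y: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold test-index sets.

    Indices are shuffled by the seeded RNG, then dealt round-robin within
    each class, which stratifies whenever every class has >= folds members
    and degrades gracefully (with a warning) otherwise.
    """
    y = np.asarray(y)
    n = len(y)
    if n < folds:
        raise ValueError(f"{n} samples cannot be split into {folds} folds")
    rng = np.random.default_rng(seed)
    vals, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        warnings.warn(
            "class too small for stratification; plain shuffled folds used"
        )
        perm = rng.permutation(n)
        return [perm[i::folds] for i in range(folds)]
    assignment = np.empty(n, dtype=int)
    for c in vals:
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == i) for i in range(folds)]


def cross_validated_accuracy(
    spec: ClassifierSpec, X, labels, folds: int = 5, seed: int = 0
) -> float:
    """Mean held-out accuracy over seeded stratified folds."""
    Xa = _as_array(X)
    y = np.asarray(labels)
    fold_idx = stratified_folds(y, folds, seed)
    hits = 0
    for test_idx in fold_idx:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        ytr = y[mask]
        if len(set(ytr)) < 2:
            pred = np.full(len(test_idx), _majority(ytr))
        else:
            est = make_estimator(spec).fit(Xa[mask], ytr)
            pred = est.predict(Xa[test_idx])
        hits += int(np.sum(pred == y[test_idx]))
    return hits / len(y)


def majority_cv_accuracy(labels, folds: int = 5, seed: int = 0) -> float:
    """CV accuracy of predicting the training-fold majority category.

    Serves as the score of the empty feature set in wrapper searches.
    """
    y = np.asarray(labels)
    fold_idx = stratified_folds(y, folds, seed)
    hits = 0
    for test_idx in fold_idx:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        hits += int(np.sum(y[test_idx] == _majority(y[mask])))
    return hits / len(y)


def _as_array(X) -> np.ndarray:
    if hasattr(X, "to_numpy"):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model file version")
    return payload["model"]
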