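"""Per-modality boosted classifiers and their prediction triplets.

Each modality gets an AdaBoost ensemble of depth-1 decision stumps
(iterative reweighting of the samples the previous weak classifier got
wrong), fitted on the training rows restricted to the lasso-selected
features. A fitted model is immediately converted to a *portable* stump
list — (feature, threshold, left/right vote) plus the per-stump weights —
which is what predicts from then on and what the JSON archive stores, so a
saved and reloaded model is exactly the model that was trained.

Probability mapping (fixed, documented here): with stump votes
``s_i(x) ∈ {-1, +1}`` (+1 = positive class) and weights ``a_i``, the
normalised margin is ``D(x) = 2 * sum_i a_i s_i(x) / sum_i a_i`` and the
positive-class probability is the logistic ``eta = 1 / (1 + exp(-D))`` —
identical to scikit-learn's SAMME ``predict_proba`` for the binary case
(verified by a round-trip test). Labels use the strict rule
``rho = 1 iff eta > t`` with threshold ``t = 0.5`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Stump",
    "PortableBoostEnsemble",
    "ModalModel",
    "SingleModalPrediction",
    "train_modal_learner",
    "predict_modal",
    "BASE_LEARNERS",
    "make_base_learner",
]

DEFAULT_N_ESTIMATORS = 50
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class Stump:
    """One depth-1 weak classifier: x[feature] <= threshold ? left : right.

    ``left``/``right`` are class votes in {0, 1}. ``feature < 0`` marks a
    degenerate no-split stump voting ``left`` everywhere.
    """

    feature: int
    threshold: float
    left: int
    right: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.feature < 0:
            return np.full(X.shape[0], self.left, dtype=int)
        return np.where(X[:, self.feature] <= self.threshold, self.left, self.right)


@dataclass(frozen=True)
class PortableBoostEnsemble:
    """Weighted stump ensemble with sklearn-equivalent probabilities."""

    stumps: tuple[Stump, ...]
    weights: tuple[float, ...]

    def decision_margin(self, X: np.ndarray) -> np.ndarray:
        total = float(np.sum(self.weights))
        if total <= 0:
            return np.zeros(X.shape[0])
        votes = np.zeros(X.shape[0])
        for stump, w in zip(self.stumps, self.weights):
            votes += w * (2.0 * stump.predict(X) - 1.0)  # {0,1} -> {-1,+1}
        return 2.0 * votes / total

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_margin(X)))

    def to_dict(self) -> dict:
        return {
            "stumps": [
                {"feature": s.feature, "threshold": s.threshold,
                 "left": s.left, "right": s.right}
                for s in self.stumps
            ],
            "weights": list(self.weights),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PortableBoostEnsemble":
        return cls(
            stumps=tuple(
                Stump(int(s["feature"]), float(s["threshold"]),
                      int(s["left"]), int(s["right"]))
                for s in d["stumps"]
            ),
            weights=tuple(float(w) for w in d["weights"]),
        )

    @classmethod
    def from_sklearn(cls, booster: AdaBoostClassifier) -> "PortableBoostEnsemble":
        classes = [int(c) for c in booster.classes_]
        stumps, weights = [], []
        for est, w in zip(booster.estimators_, booster.estimator_weights_):
            if w <= 0:
                continue
            tree = est.tree_
            if tree.node_count == 1:
                cls_idx = int(np.argmax(tree.value[0]))
                stumps.append(Stump(-1, 0.0, classes[cls_idx], classes[cls_idx]))
            else:
                left = classes[int(np.argmax(tree.value[1]))]
                right = classes[int(np.argmax(tree.value[2]))]
                stumps.append(
                    Stump(int(tree.feature[0]), float(tree.threshold[0]), left, right)
                )
            weights.append(float(w))
        return cls(tuple(stumps), tuple(weights))


class SklearnEnsembleWrapper:
    """Duck-typed stand-in for PortableBoostEnsemble around any fitted
    scikit-learn classifier with ``predict_proba`` — used by the
    learner-comparison harness, not by the JSON archive."""

    def __init__(self, clf):
        self._clf = clf
        self._pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(X)[:, self._pos_col]

    def to_dict(self) -> dict:
        raise NotImplementedError(
            "only the boosted-stump ensemble has a portable JSON form"
        )


def make_base_learner(name: str, seed: int = 0, n_estimators: int = 50):
    """Instantiate a registered base classifier (unfitted).

    The registry mirrors the learner-substitution comparison: adaptive
    boosting (the default) against logistic regression, Gaussian naive
    Bayes, a decision tree, a support-vector machine, k-nearest
    neighbours, random forest and extra trees.
    """
    from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    factories = {
        "adaboost": lambda: AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=n_estimators, random_state=seed,
        ),
        "logistic_regression": lambda: LogisticRegression(max_iter=1000),
        "naive_bayes": lambda: GaussianNB(),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        ),
        "extra_trees": lambda: ExtraTreesClassifier(
            n_estimators=n_estimators, random_state=seed
        ),
    }
    if name not in factories:
        raise KeyError(f"unknown base learner {name!r}; known: {sorted(factories)}")
    return factories[name]()


BASE_LEARNERS = (
    "adaboost", "logistic_regression", "naive_bayes", "decision_tree",
    "svm", "knn", "random_forest", "extra_trees",
)


@dataclass
class ModalModel:
    """A fitted single-modality classifier restricted to selected features."""

    modality: str
    feature_names: tuple[str, ...]
    ensemble: PortableBoostEnsemble
    n_estimators: int
    seed: int
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise ValueError("ModalModel needs at least one feature")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "feature_names": list(self.feature_names),
            "ensemble": self.ensemble.to_dict(),
            "n_estimators": self.n_estimators,
            "seed": self.seed,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModalModel":
        return cls(
            modality=d["modality"],
            feature_names=tuple(d["feature_names"]),
            ensemble=PortableBoostEnsemble.from_dict(d["ensemble"]),
            n_estimators=int(d["n_estimators"]),
            seed=int(d["seed"]),
            threshold=float(d["threshold"]),
        )


@dataclass(frozen=True)
class SingleModalPrediction:
    """One modality's output triplet: labels rho, probabilities eta, accuracy phi.

    ``phi`` is the model's set-level accuracy on the evaluation rows and is
    ``None`` when no evaluation labels were supplied.
    """

    modality: str
    patient_ids: tuple[str, ...]
    rho: np.ndarray
    eta: np.ndarray
    phi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=int))
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))
        if self.rho.shape != self.eta.shape or len(self.rho) != len(self.patient_ids):
            raise ValueError("rho/eta/patient_ids lengths disagree")
        if self.phi is not None and not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")


def _extract_matrix(rows, feature_names: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rows as ndarray restricted to feature_names; returns (X, patient_ids)."""
    from .cohort import ModalityTable

    if isinstance(rows, ModalityTable):
        pos = {n: i for i, n in enumerate(rows.feature_names)}
        missing = [n for n in feature_names if n not in pos]
        if missing:
            raise KeyError(f"{rows.modality}: missing feature column(s) {missing}")
        X = rows.values[:, [pos[n] for n in feature_names]]
        return X, tuple(rows.patient_ids)
    X = np.asarray(rows, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError("bare array width must equal len(feature_names)")
    return X, tuple(str(i) for i in range(X.shape[0]))


def train_modal_learner(
    train_rows,
    train_labels: np.ndarray,
    selected_features: Sequence[str],
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    modality: str | None = None,
    base_learner: str = "adaboost",
) -> ModalModel:
    """Fit the base classifier on the selected feature columns.

    The default boosted stump ensemble is converted to its portable form;
    any other registered base learner (see :func:`make_base_learner`) is
    kept as a fitted scikit-learn object behind the same interface.
    """
    from .cohort import ModalityTable

    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; cannot fit")
    names = tuple(selected_features)
    X, _ = _extract_matrix(train_rows, names)
    if modality is None:
        modality = train_rows.modality if isinstance(train_rows, ModalityTable) else "unknown"
    clf = make_base_learner(base_learner, seed=seed, n_estimators=n_estimators)
    clf.fit(X, y)
    if base_learner == "adaboost":
        ensemble = PortableBoostEnsemble.from_sklearn(clf)
    else:
        ensemble = SklearnEnsembleWrapper(clf)
    return ModalModel(
        modality=modality,
        feature_names=names,
        ensemble=ensemble,
        n_estimators=n_estimators,
        seed=seed,
        threshold=threshold,
    )


def predict_modal(
    model: ModalModel, rows, eval_labels: np.ndarray | None = None
) -> SingleModalPrediction:
    """Predict (rho, eta, phi) on ``rows``.

    ``eta`` is the ensemble's positive-class probability, ``rho`` the
    strict-threshold label ``[eta > t]`` (so ``eta == t`` maps to 0), and
    ``phi`` the accuracy against ``eval_labels`` when those are given.
    """
    X, patient_ids = _extract_matrix(rows, model.feature_names)
    eta = model.ensemble.predict_proba_pos(X)
    rho = (eta > model.threshold).astype(int)
    phi = None
    if eval_labels is not None:
        y = np.asarray(eval_labels, dtype=int)
        if len(y) != len(rho):
            raise ValueError("eval_labels length does not match rows")
        phi = float(np.mean(rho == y))
    return SingleModalPrediction(model.modality, patient_ids, rho, eta, phi)
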