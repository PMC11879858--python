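"""Random-forest mechanism classification.

Wraps :class:`sklearn.ensemble.RandomForestClassifier` behind the training
protocol used throughout the experiments: 100 trees, unlimited depth, split
criterion chosen by grid search over {gini, entropy} on a validation split
carved from the training set, class-balanced training and test samples, and
per-tree vote access for classification-certainty reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

__all__ = [
    "RFProtocol",
    "RandomForestMechanismClassifier",
    "balanced_sample",
    "train",
    "evaluate",
    "certainty",
]


@dataclass(frozen=True)
class RFProtocol:
    """Training protocol for the mechanism random forests.

    Defaults follow the per-pair setting: 6000 training and 2000 test
    instances per class (18,000 / 6,000 total over three classes), 100 trees
    of unlimited depth, criterion by grid search, results averaged over
    ``n_realisations`` repetitions.
    """

    n_trees: int = 100
    train_per_class: int = 6000
    test_per_class: int = 2000
    criteria: tuple[str, ...] = ("gini", "entropy")
    validation_frac: float = 0.2
    n_realisations: int = 10

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.train_per_class < 1 or self.test_per_class < 1:
            raise ValueError("protocol counts must be positive")


def balanced_sample(
    y: np.ndarray,
    per_class: int,
    rng: np.random.Generator,
    classes: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of a class-balanced subsample.

    If a class has fewer than ``per_class`` instances the balanced count is
    scaled down to the smallest class size (with all classes equal).
    """
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    counts = {c: int((y == c).sum()) for c in classes}
    n = min(per_class, min(counts.values()))
    if n < per_class:
        import warnings

        warnings.warn(
            f"balanced sample scaled down to {n}/class (requested {per_class}); "
            f"class counts: {counts}",
            stacklevel=2,
        )
    if n == 0:
        raise ValueError(f"a class has no instances: {counts}")
    idx = []
    for c in classes:
        rows = np.nonzero(y == c)[0]
        idx.append(rng.choice(rows, size=n, replace=False))
    idx = np.concatenate(idx)
    rng.shuffle(idx)
    return idx


class RandomForestMechanismClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with protocol-driven criterion selection.

    ``fit`` runs a small grid search over the split criterion using an
    internal validation split, then refits the winning forest on the full
    training data.  ``certainty`` exposes the fraction of trees voting for
    each instance's assigned class.
    """

    def __init__(self, protocol: RFProtocol | None = None, random_state: int = 0):
        self.protocol = protocol
        self.random_state = random_state

    def fit(self, X, y):
        proto = self.protocol or RFProtocol()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        rs = np.random.RandomState(self.random_state)
        if len(proto.criteria) > 1:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y,
                test_size=proto.validation_frac,
                random_state=rs.randint(2**31 - 1),
                stratify=y,
            )
            scores = {}
            for crit in proto.criteria:
                rf = RandomForestClassifier(
                    n_estimators=proto.n_trees,
                    criterion=crit,
                    max_depth=None,
                    random_state=rs.randint(2**31 - 1),
                    n_jobs=1,
                )
                rf.fit(X_tr, y_tr)
                scores[crit] = rf.score(X_val, y_val)
            self.criterion_ = max(scores, key=scores.get)
            self.grid_scores_ = scores
        else:
            self.criterion_ = proto.criteria[0]
            self.grid_scores_ = {}
        self.forest_ = RandomForestClassifier(
            n_estimators=proto.n_trees,
            criterion=self.criterion_,
            max_depth=None,
            random_state=rs.randint(2**31 - 1),
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict(self, X):
        return self.forest_.predict(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X):
        return self.forest_.predict_proba(np.asarray(X, dtype=np.float64))

    def certainty(self, X) -> np.ndarray:
        """Per-instance fraction of trees voting for the assigned class.

        The assigned class is the majority (plurality) vote, so with three
        classes the certainty is always above 1/3.
        """
        proba = self.predict_proba(X)
        return proba.max(axis=1)

    def manifest(self) -> dict:
        """Library-agnostic description of the fitted model for audit."""
        return {
            "n_trees": int(self.forest_.n_estimators),
            "criterion": self.criterion_,
            "classes": [str(c) for c in self.classes_],
            "random_state": int(self.random_state),
        }


def train(
    X: np.ndarray,
    y: np.ndarray,
    protocol: RFProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> RandomForestMechanismClassifier:
    """Fit one protocol forest (thin functional wrapper)."""
    rng = rng or np.random.default_rng()
    clf = RandomForestMechanismClassifier(
        protocol=protocol, random_state=int(rng.integers(2**31 - 1))
    )
    return clf.fit(X, y)


def evaluate(
    model: RandomForestMechanismClassifier, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows = true class, cols = predicted)."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    cm = confusion_matrix(y, pred, labels=model.classes_)
    return float((pred == y).mean()), cm


def certainty(model: RandomForestMechanismClassifier, X: np.ndarray) -> np.ndarray:
    return model.certainty(X)
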