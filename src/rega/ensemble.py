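"""AdaBoost-style chain of weak classifiers over rotated feature subsets.

One GA individual encodes K feature subsets. Training walks the subsets
in order: subset k is rotated (PCA/MCA), a bootstrap sample is drawn
from the current sample-weight distribution, a base learner D_k is fit
on the rotated sample, and its weighted error

    eps_k = sum_j w_j^k [D_k misclassifies sample j]

is measured on the *full* training set. Slots with eps_k = 0 or
eps_k >= 0.5 are discarded (weights reset to uniform, a few retries with
fresh bootstraps); valid slots receive confidence beta_k = eps_k/(1-eps_k)
and the weights of correctly classified samples shrink by beta_k before
renormalization. Prediction sums vote weight ln(1/beta_k) per class and
takes the argmax, ties broken toward the negative class.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .rotation import DegenerateSubsetError, SubsetRotation

logger = logging.getLogger(__name__)

#: Tolerance on the sample-weight normalization invariant.
WEIGHT_ATOL = 1e-12


# ---------------------------------------------------------------------------
# boosting arithmetic
# ---------------------------------------------------------------------------

def init_weights(n: int) -> np.ndarray:
    """Uniform initial sample weights w_j = 1/N."""
    if n < 1:
        raise ValueError("need at least one sample")
    return np.full(n, 1.0 / n)


def weighted_bootstrap(n: int, weights: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw n row indices i.i.d. with replacement, P(j) = w_j."""
    return rng.choice(len(weights), size=n, replace=True, p=weights)


def weighted_error(predictions: np.ndarray, labels: np.ndarray,
                   weights: np.ndarray) -> float:
    """Weighted misclassification rate eps = sum_j w_j [pred_j != y_j]."""
    miss = np.asarray(predictions) != np.asarray(labels)
    return float(np.sum(weights[miss]))


def compute_beta(epsilon: float) -> float:
    """Confidence ratio beta = eps/(1-eps); requires 0 < eps < 0.5."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5); got {epsilon}")
    return epsilon / (1.0 - epsilon)


def update_weights(weights: np.ndarray, beta: float,
                   miss: np.ndarray) -> np.ndarray:
    """Shrink correct samples by beta, keep misclassified, renormalize.

    ``miss`` is the 0/1 misclassification indicator l_j; the update is
    w'_j = w_j beta^(1 - l_j) / sum_i w_i beta^(1 - l_i).
    """
    miss = np.asarray(miss)
    raw = weights * beta ** (1.0 - miss)
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# the ensemble classifier
# ---------------------------------------------------------------------------

@dataclass
class WeakLearnerSlot:
    rotation: SubsetRotation
    classifier: object
    epsilon: float
    beta: float

    @property
    def vote_weight(self) -> float:
        return float(np.log(1.0 / self.beta))


class RotationBoostClassifier(ClassifierMixin, BaseEstimator):
    """Boosted chain of base learners over K rotated feature subsets.

    Parameters
    ----------
    subsets : array-like of shape (K, Sfs)
        Feature-index subsets, one per weak-learner slot. Duplicate
        indices within a subset are permitted.
    column_kinds : sequence of {"binary", "continuous"}
        Kind of every column of the input matrix.
    base_estimator : sklearn classifier, default RandomForestClassifier(50)
        Cloned per slot.
    max_retries : int, default 5
        Fresh-bootstrap retries when a slot's error leaves (0, 0.5).
    random_state : int, Generator or None
        Seeds bootstraps and base learners.

    Attributes
    ----------
    slots_ : list of WeakLearnerSlot
        The valid (voting) slots, at most K.
    fallback_label_ : int
        Training-majority class, used when no slot is valid.
    """

    def __init__(self, subsets=None, column_kinds=None, base_estimator=None,
                 max_retries: int = 5, random_state=None):
        self.subsets = subsets
        self.column_kinds = column_kinds
        self.base_estimator = base_estimator
        self.max_retries = max_retries
        self.random_state = random_state

    def _base(self):
        if self.base_estimator is None:
            return RandomForestClassifier(n_estimators=50)
        return clone(self.base_estimator)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if not set(self.classes_) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.subsets is None:
            raise ValueError("subsets must be provided")
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        n = X.shape[0]
        counts = np.bincount(y.astype(int), minlength=2)
        self.fallback_label_ = int(np.argmax(counts))  # argmax ties -> 0
        self.n_features_in_ = X.shape[1]

        weights = init_weights(n)
        self.slots_ = []
        for subset in np.asarray(self.subsets, dtype=int):
            rotation = SubsetRotation(subset, self.column_kinds).fit(X)
            X_rot = rotation.transform(X)
            for attempt in range(self.max_retries + 1):
                idx = weighted_bootstrap(n, weights, rng)
                clf = self._base()
                if "random_state" in clf.get_params():
                    clf.set_params(random_state=int(rng.integers(2**31)))
                clf.fit(X_rot[idx], y[idx])
                pred = clf.predict(X_rot)
                eps = weighted_error(pred, y, weights)
                if 0.0 < eps < 0.5:
                    beta = compute_beta(eps)
                    weights = update_weights(weights, beta, (pred != y).astype(float))
                    self.slots_.append(WeakLearnerSlot(rotation, clf, eps, beta))
                    break
                # degenerate slot: reset the distribution and retry
                weights = init_weights(n)
                if attempt == self.max_retries:
                    logger.warning("slot skipped: error %.3f outside (0, 0.5) "
                                   "after %d retries", eps, self.max_retries)
        if not self.slots_:
            logger.warning("no valid weak learner; falling back to majority "
                           "class %d", self.fallback_label_)
        return self

    def _supports(self, X) -> np.ndarray:
        """Per-row vote support (mu_0, mu_1) accumulated over valid slots."""
        supports = np.zeros((X.shape[0], 2))
        for slot in self.slots_:
            pred = np.asarray(slot.classifier.predict(slot.rotation.transform(X)),
                              dtype=int)
            supports[np.arange(X.shape[0]), pred] += slot.vote_weight
        return supports

    def decision_function(self, X) -> np.ndarray:
        """Signed support margin mu_1 - mu_0 (positive favours class 1)."""
        check_is_fitted(self, "slots_")
        X = check_array(X)
        if not self.slots_:
            return np.full(X.shape[0],
                           1e-9 if self.fallback_label_ == 1 else -1e-9)
        s = self._supports(X)
        return s[:, 1] - s[:, 0]

    def predict(self, X) -> np.ndarray:
        """Argmax-support label; exact ties resolve to class 0."""
        check_is_fitted(self, "slots_")
        X = check_array(X)
        if not self.slots_:
            return np.full(X.shape[0], self.fallback_label_, dtype=int)
        return (self.decision_function(X) > 0).astype(int)


def train_ensemble(subsets, X, y, column_kinds, base_estimator=None,
                   max_retries: int = 5, rng=None) -> RotationBoostClassifier:
    """Functional wrapper: fit a :class:`RotationBoostClassifier`."""
    return RotationBoostClassifier(
        subsets=subsets, column_kinds=column_kinds, base_estimator=base_estimator,
        max_retries=max_retries, random_state=rng,
    ).fit(X, y)


def predict_labels(ensemble: RotationBoostClassifier, X) -> np.ndarray:
    return ensemble.predict(X)


def decision_scores(ensemble: RotationBoostClassifier, X) -> np.ndarray:
    return ensemble.decision_function(X)
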