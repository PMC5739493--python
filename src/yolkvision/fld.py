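"""Two-class Fisher's linear discriminant on NFD feature vectors.

Fisher classification functions are the per-class linear scores

    f_g(x) = mu_g' Sp^-1 x - 1/2 mu_g' Sp^-1 mu_g + ln p_g

with Sp the pooled within-class covariance; a sample goes to the class
with the larger score.  Evaluation follows the leave-one-out protocol:
each sample is classified by functions fitted on all other samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

__all__ = ["FisherDiscriminant", "ConfusionMatrix", "fit_fld", "fld_classify", "loocv"]


@dataclass
class ConfusionMatrix:
    """Cross-tab of true vs predicted class with per-class accuracy in %."""

    counts: pd.DataFrame        # rows = true class, columns = predicted

    @property
    def per_class_accuracy(self) -> dict:
        acc = {}
        for cls in self.counts.index:
            row = self.counts.loc[cls]
            acc[cls] = 100.0 * row[cls] / row.sum()
        return acc

    def to_text(self) -> str:
        lines = ["Classification results", "", self.counts.to_string(), "",
                 "Per-class accuracy (%):"]
        for cls, a in self.per_class_accuracy.items():
            lines.append(f"  {cls}: {a:.1f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


class FisherDiscriminant(ClassifierMixin, BaseEstimator):
    """Two-class linear discriminant with Fisher classification functions.

    Parameters
    ----------
    priors : "equal", "proportional", or an array of two class priors in
        the order of the sorted class labels.
    ridge : regularization factor applied as ``ridge * trace(Sp)/p * I``
        when the pooled covariance is numerically singular.
    tie_break : class label favoured on exact score ties (falls back to
        the first sorted class if absent from the data).

    Attributes (after ``fit``)
    --------------------------
    classes_ : the two class labels, sorted.
    means_ : (2, p) class mean vectors.
    pooled_cov_ : (p, p) pooled within-class covariance.
    coef_, intercept_ : classification-function weights and constants,
        one row / entry per class.
    priors_ : fitted prior probabilities.
    """

    def __init__(self, priors="equal", ridge: float = 1e-6, tie_break="SY"):
        self.priors = priors
        self.ridge = ridge
        self.tie_break = tie_break

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(f"exactly two classes required, got {list(self.classes_)}")
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=2)
        if n < 3:
            raise ValueError("need at least 3 samples")

        self.means_ = np.vstack([X[y_idx == g].mean(axis=0) for g in range(2)])
        pooled = np.zeros((p, p))
        for g in range(2):
            diff = X[y_idx == g] - self.means_[g]
            pooled += diff.T @ diff
        pooled /= (n - 2)
        self.pooled_cov_ = pooled

        if isinstance(self.priors, str):
            if self.priors == "equal":
                self.priors_ = np.array([0.5, 0.5])
            elif self.priors == "proportional":
                self.priors_ = counts / n
            else:
                raise ValueError(f"unknown priors setting {self.priors!r}")
        else:
            self.priors_ = np.asarray(self.priors, dtype=np.float64)
            if self.priors_.shape != (2,) or not np.isclose(self.priors_.sum(), 1.0):
                raise ValueError("priors must be two probabilities summing to 1")

        cov = pooled
        # near-singular pooled covariance: NFDs of near-circular yolks can be
        # almost collinear
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            lam = self.ridge * np.trace(cov) / p
            log.warning("pooled covariance near-singular; ridge %.3e added", lam)
            cov = cov + lam * np.eye(p)
            self.pooled_cov_ = cov
        inv = np.linalg.inv(cov)
        self.coef_ = self.means_ @ inv                                  # (2, p)
        self.intercept_ = (-0.5 * np.einsum("gp,gp->g", self.coef_, self.means_)
                           + np.log(self.priors_))
        return self

    def decision_function(self, X) -> np.ndarray:
        """Fisher classification scores f_g(x), one column per class."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef_.shape[1]:
            raise ValueError("feature dimension mismatch")
        return X @ self.coef_.T + self.intercept_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        tie_idx = 0
        if self.tie_break in self.classes_:
            tie_idx = int(np.where(self.classes_ == self.tie_break)[0][0])
        best = np.argmax(scores, axis=1)
        ties = scores[:, 0] == scores[:, 1]
        if np.any(ties):
            log.info("%d tied samples broken toward %s",
                     int(ties.sum()), self.classes_[tie_idx])
            best[ties] = tie_idx
        return self.classes_[best]

    def to_json(self, path) -> None:
        check_is_fitted(self, "coef_")
        payload = {
            "classes": [str(c) for c in self.classes_],
            "means": self.means_.tolist(),
            "pooled_cov": self.pooled_cov_.tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "priors": self.priors_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FisherDiscriminant":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls()
        model.classes_ = np.array(payload["classes"])
        model.means_ = np.array(payload["means"])
        model.pooled_cov_ = np.array(payload["pooled_cov"])
        model.coef_ = np.array(payload["coef"])
        model.intercept_ = np.array(payload["intercept"])
        model.priors_ = np.array(payload["priors"])
        return model


def fit_fld(features, labels, **params) -> FisherDiscriminant:
    """Fit a Fisher discriminant on an (n, 14) feature matrix."""
    return FisherDiscriminant(**params).fit(features, labels)


def fld_classify(model: FisherDiscriminant, x):
    """Classify one feature vector; returns (label, {class: score})."""
    scores = model.decision_function(np.atleast_2d(x))[0]
    label = model.predict(np.atleast_2d(x))[0]
    return label, dict(zip((str(c) for c in model.classes_), scores))


def loocv(features, labels, **params):
    """Leave-one-out cross-validation.

    Returns ``(ConfusionMatrix, predictions)`` where predictions[i] is the
    label assigned to sample i by the model fitted on all other samples.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples for leave-one-out")
    classes = np.unique(y)
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        keep = np.arange(n) != i
        if len(np.unique(y[keep])) < 2:
            raise ValueError("a leave-one-out fold lost a class")
        model = FisherDiscriminant(**params).fit(X[keep], y[keep])
        preds[i] = model.predict(X[i:i + 1])[0]
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, preds):
        counts.loc[t, p] += 1
    return ConfusionMatrix(counts), preds
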