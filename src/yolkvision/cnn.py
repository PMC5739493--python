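"""Small LeNet-style convolutional network, implemented in plain numpy.

Architecture (1,012 trainable parameters):

    input 32x32
    -> conv 5x5, 4 maps, sigmoid        (4 x 28 x 28)
    -> average pool 2x2                 (4 x 14 x 14)
    -> conv 5x5, 6 maps, each connected to all 4 input maps, sigmoid
                                        (6 x 10 x 10)
    -> average pool 2x2                 (6 x 5 x 5)
    -> flatten                          (150)
    -> fully connected                  (2)
    -> softmax

Training is plain minibatch SGD with a fixed learning rate (no momentum,
no weight decay, no schedule) on softmax cross-entropy; a mean-squared
error on the softmax outputs is available behind the ``loss`` flag, as is
an optional sigmoid after the pooling layers.  Inputs are grayscale ROIs
scaled to [0, 1] (divided by 255).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .config import TrainConfig, DEFAULT_TRAIN
from .fld import ConfusionMatrix
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "LeNetClassifier",
    "build_cnn",
    "cnn_forward",
    "loss_and_grads",
    "train_cnn",
    "evaluate_repeated_splits",
    "parameter_count",
]

_LAYERS = ("W1", "b1", "W2", "b2", "W3", "b3")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_cnn(seed: int = 0) -> dict:
    """Initialize weights uniform in +-sqrt(6/(fan_in+fan_out)), biases 0."""
    rng = np.random.default_rng(seed)

    def u(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    return {
        "W1": u((4, 5, 5), 25, 4 * 25),
        "b1": np.zeros(4),
        "W2": u((6, 4, 5, 5), 4 * 25, 6 * 25),
        "b2": np.zeros(6),
        "W3": u((2, 150), 150, 2),
        "b3": np.zeros(2),
    }


def parameter_count(params: dict) -> int:
    return int(sum(v.size for v in params.values()))


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation.

    x (B, C, H, W) with w (O, C, k, k) -> (B, O, H-k+1, W-k+1).
    """
    k = w.shape[-1]
    win = sliding_window_view(x, (k, k), axis=(2, 3))   # B,C,H',W',k,k
    return np.einsum("bchwij,ocij->bohw", win, w, optimize=True)


def _avg_pool(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _unpool(g: np.ndarray) -> np.ndarray:
    """Backward of 2x2 average pooling: spread each gradient over its block."""
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


def _forward(params: dict, X: np.ndarray, pool_activation: bool = False) -> dict:
    """Forward pass; returns every intermediate needed for backprop."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != (32, 32):
        raise ValueError(f"expected (n, 32, 32) input, got {X.shape}")
    x = X[:, None]                                        # B,1,32,32
    z1 = _conv_valid(x, params["W1"][:, None]) + params["b1"][None, :, None, None]
    a1 = _sigmoid(z1)                                     # B,4,28,28
    q1 = _avg_pool(a1)                                    # B,4,14,14
    p1 = _sigmoid(q1) if pool_activation else q1
    z2 = _conv_valid(p1, params["W2"]) + params["b2"][None, :, None, None]
    a2 = _sigmoid(z2)                                     # B,6,10,10
    q2 = _avg_pool(a2)                                    # B,6,5,5
    p2 = _sigmoid(q2) if pool_activation else q2
    flat = p2.reshape(X.shape[0], -1)                     # B,150
    logits = flat @ params["W3"].T + params["b3"]
    logits -= logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return dict(x=x, z1=z1, a1=a1, p1=p1, z2=z2, a2=a2, p2=p2,
                flat=flat, probs=probs)


def cnn_forward(params: dict, X: np.ndarray, pool_activation: bool = False) -> np.ndarray:
    """Class probabilities, rows summing to 1, for a batch of 32x32 grids."""
    return _forward(params, X, pool_activation)["probs"]


def loss_and_grads(params: dict, X: np.ndarray, Y: np.ndarray,
                   loss: str = "cross_entropy",
                   pool_activation: bool = False):
    """Mean loss over the batch and analytic gradients for every parameter."""
    cache = _forward(params, X, pool_activation)
    probs = cache["probs"]
    B = probs.shape[0]
    Y = np.asarray(Y, dtype=np.float64)
    eps = 1e-12
    if loss == "cross_entropy":
        value = -float(np.sum(Y * np.log(probs + eps))) / B
        dlogits = (probs - Y) / B
    elif loss == "mse":
        value = float(np.sum((probs - Y) ** 2)) / B
        dp = 2.0 * (probs - Y) / B
        dlogits = probs * (dp - np.sum(dp * probs, axis=1, keepdims=True))
    else:
        raise ValueError(f"unknown loss {loss!r}")

    grads = {}
    grads["W3"] = dlogits.T @ cache["flat"]
    grads["b3"] = dlogits.sum(axis=0)
    dflat = dlogits @ params["W3"]
    dp2 = dflat.reshape(cache["p2"].shape)
    if pool_activation:
        dq2 = dp2 * cache["p2"] * (1.0 - cache["p2"])
    else:
        dq2 = dp2
    da2 = _unpool(dq2)
    dz2 = da2 * cache["a2"] * (1.0 - cache["a2"])

    k = params["W2"].shape[-1]
    win1 = sliding_window_view(cache["p1"], (k, k), axis=(2, 3))  # B,4,10,10,k,k
    grads["W2"] = np.einsum("bohw,bchwij->ocij", dz2, win1, optimize=True)
    grads["b2"] = dz2.sum(axis=(0, 2, 3))
    dp1 = np.zeros_like(cache["p1"])
    for i in range(k):
        for j in range(k):
            dp1[:, :, i:i + 10, j:j + 10] += np.einsum(
                "bohw,oc->bchw", dz2, params["W2"][:, :, i, j], optimize=True)
    if pool_activation:
        dq1 = dp1 * cache["p1"] * (1.0 - cache["p1"])
    else:
        dq1 = dp1
    da1 = _unpool(dq1)
    dz1 = da1 * cache["a1"] * (1.0 - cache["a1"])
    win0 = sliding_window_view(cache["x"], (5, 5), axis=(2, 3))   # B,1,28,28,5,5
    grads["W1"] = np.einsum("bohw,bhwij->oij", dz1, win0[:, 0], optimize=True)
    grads["b1"] = dz1.sum(axis=(0, 2, 3))
    return value, grads


def train_cnn(params: dict, X: np.ndarray, Y: np.ndarray,
              cfg: TrainConfig = DEFAULT_TRAIN,
              loss: str = "cross_entropy",
              pool_activation: bool = False):
    """Minibatch SGD; returns (trained params, per-epoch loss list)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    batch = min(cfg.batch_size, n)
    n_batches = max(1, n // batch)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = order[b * batch:(b + 1) * batch]
            value, grads = loss_and_grads(params, X[idx], Y[idx],
                                          loss=loss, pool_activation=pool_activation)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b}; "
                    "try a smaller learning rate")
            for key in _LAYERS:
                params[key] -= cfg.learning_rate * grads[key]
            epoch_loss += value
        history.append(epoch_loss / n_batches)
        log.debug("epoch %d: loss %.5f", epoch, history[-1])
    return params, history


class LeNetClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper around the numpy LeNet.

    ``X`` is an (n, 32, 32) array of grayscale ROIs in [0, 1]; ``y`` holds
    the two class labels.  One-hot targets follow the sorted class order,
    so with labels {"DY", "SY"} a DY egg is encoded [1, 0] and an SY egg
    [0, 1].
    """

    def __init__(self, learning_rate: float = 0.2, batch_size: int = 50,
                 epochs: int = 100, loss: str = "cross_entropy",
                 pool_activation: bool = False, random_state: int = 0):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.loss = loss
        self.pool_activation = pool_activation
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        Y = np.eye(2)[y_idx]
        self.params_ = build_cnn(self.random_state)
        cfg = TrainConfig(learning_rate=self.learning_rate,
                          batch_size=self.batch_size, epochs=self.epochs,
                          seed=self.random_state)
        self.params_, self.loss_curve_ = train_cnn(
            self.params_, X, Y, cfg, loss=self.loss,
            pool_activation=self.pool_activation)
        self.n_params_ = parameter_count(self.params_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        return cnn_forward(self.params_, X, self.pool_activation)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def save(self, path) -> None:
        """Portable archive: arrays in NPZ plus a JSON sidecar spec."""
        check_is_fitted(self, "params_")
        np.savez(path, classes=self.classes_.astype(str), **self.params_)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"hyperparameters": self.get_params(),
                       "n_params": self.n_params_}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "LeNetClassifier":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        try:
            with open(str(path).removesuffix(".npz") + ".json") as fh:
                hp = json.load(fh)["hyperparameters"]
        except FileNotFoundError:
            hp = {}
        model = cls(**hp)
        model.classes_ = data["classes"]
        model.params_ = {k: data[k] for k in _LAYERS}
        model.n_params_ = parameter_count(model.params_)
        model.loss_curve_ = []
        return model


def evaluate_repeated_splits(X, y, cfg: TrainConfig = DEFAULT_TRAIN,
                             loss: str = "cross_entropy",
                             pool_activation: bool = False) -> dict:
    """Repeated stratified-split evaluation of freshly trained networks.

    Each repeat draws a stratified ``split_ratio`` train / rest validation
    partition, trains a newly initialized network, and scores the held-out
    fold.  Returns per-repeat confusion matrices and the per-class
    accuracies averaged over repeats.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    n_val = len(y) - int(round(len(y) * cfg.split_ratio))
    if n_val < len(classes):
        raise ValueError("validation fold smaller than one sample per class")
    splitter = StratifiedShuffleSplit(n_splits=cfg.repeats,
                                      train_size=cfg.split_ratio,
                                      random_state=cfg.seed)
    matrices, per_class = [], []
    for rep, (tr, va) in enumerate(splitter.split(X, y)):
        model = LeNetClassifier(learning_rate=cfg.learning_rate,
                                batch_size=cfg.batch_size, epochs=cfg.epochs,
                                loss=loss, pool_activation=pool_activation,
                                random_state=cfg.seed + rep)
        model.fit(X[tr], y[tr])
        preds = model.predict(X[va])
        counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(y[va], preds):
            counts.loc[t, p] += 1
        cm = ConfusionMatrix(counts)
        matrices.append(cm)
        per_class.append(cm.per_class_accuracy)
        log.info("repeat %d: %s", rep, cm.per_class_accuracy)
    mean_acc = {cls: float(np.mean([pc[cls] for pc in per_class]))
                for cls in classes}
    return {"mean_per_class_accuracy": mean_acc,
            "per_repeat": per_class,
            "confusion_matrices": matrices,
            "config": asdict(cfg)}
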