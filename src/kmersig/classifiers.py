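"""The four base classifiers and their positive-class scoring interface.

Logistic regression, linear-kernel SVM (with Platt-calibrated probability
outputs) and Gaussian naive Bayes come from scikit-learn with the
documented settings. The feed-forward network is a compact NumPy
implementation of the fixed architecture 16-ReLU → dropout(0.5) → 4-ReLU →
1-sigmoid, trained with Adam on binary cross-entropy for at most 50
epochs, with early stopping (patience 10) monitored on an internal
stratified 10% split of the training fold and best-epoch weight restore.
Every stochastic element (weight init, dropout masks, minibatch shuffling)
is driven by the configured seed, so training is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .errors import ParameterError

MODEL_KINDS = ("LR", "SVM_linear", "GaussianNB", "FFNN")

FFNN_WIDTHS = (16, 4, 1)
FFNN_DROPOUT = 0.5
FFNN_MAX_EPOCHS = 50
FFNN_PATIENCE = 10
FFNN_VAL_FRACTION = 0.1
FFNN_BATCH_SIZE = 32
# with <=50 epochs on cohort-sized data there are only a few hundred Adam
# steps; a slightly hotter step size than the common 1e-3 default is needed
# for the loss to actually converge within the epoch budget
FFNN_LEARNING_RATE = 5e-3


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one base model."""

    kind: str
    seed: int = 0
    lr_max_iterations: int = 1000
    svm_C: float = 1.0
    nb_var_smoothing: float = 1e-9
    ffnn_max_epochs: int = FFNN_MAX_EPOCHS
    ffnn_patience: int = FFNN_PATIENCE
    ffnn_val_fraction: float = FFNN_VAL_FRACTION

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


@dataclass
class TrainedModel:
    kind: str
    estimator: Any
    n_features: int
    metadata: dict = field(default_factory=dict)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class NumpyFFNN:
    """Feed-forward binary classifier: 16-ReLU / dropout 0.5 / 4-ReLU / 1-sigmoid.

    Trained with Adam (lr 1e-3) on binary cross-entropy, minibatches of 32,
    inverted dropout, early stopping on an internal stratified validation
    split with best-weights restore.
    """

    def __init__(
        self,
        seed: int = 0,
        max_epochs: int = FFNN_MAX_EPOCHS,
        patience: int = FFNN_PATIENCE,
        val_fraction: float = FFNN_VAL_FRACTION,
    ) -> None:
        self.seed = seed
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.epochs_run_: int = 0
        self.n_features_: int = 0

    # -- internals ---------------------------------------------------------
    def _init_params(self, n_in: int, rng: np.random.Generator) -> None:
        widths = [n_in, *FFNN_WIDTHS]
        self.weights_ = []
        self.biases_ = []
        for a, b in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (a + b))  # Glorot uniform
            self.weights_.append(rng.uniform(-limit, limit, size=(a, b)))
            self.biases_.append(np.zeros(b))

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Forward pass; a generator enables (inverted) dropout after layer 1."""
        W, b = self.weights_, self.biases_
        z1 = X @ W[0] + b[0]
        a1 = _relu(z1)
        if rng is not None:
            mask = (rng.random(a1.shape) >= FFNN_DROPOUT) / (1.0 - FFNN_DROPOUT)
            a1d = a1 * mask
        else:
            mask = None
            a1d = a1
        z2 = a1d @ W[1] + b[1]
        a2 = _relu(z2)
        z3 = a2 @ W[2] + b[2]
        p = _sigmoid(z3)
        return p.ravel(), [X, z1, a1d, mask, z2, a2]

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        p = np.clip(p, eps, 1.0 - eps)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def _stratified_split(
        self, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Internal train/validation indices, at least one of each class held out."""
        val_idx: list[int] = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_val = max(1, int(round(self.val_fraction * idx.size)))
            if n_val >= idx.size:  # too few samples to hold any out
                continue
            val_idx.extend(idx[:n_val])
        val = np.array(sorted(val_idx), dtype=int)
        train = np.setdiff1d(np.arange(y.size), val)
        return train, val

    # -- API ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "NumpyFFNN":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        rng = np.random.default_rng(self.seed)
        self.n_features_ = X.shape[1]
        self._init_params(X.shape[1], rng)

        tr, va = self._stratified_split(y, rng)
        use_es = va.size > 0 and np.unique(y[tr]).size == 2
        if not use_es:
            tr = np.arange(y.size)
        Xtr, ytr = X[tr], y[tr]
        Xva, yva = X[va], y[va]

        m = [np.zeros_like(w) for w in self.weights_ + self.biases_]
        v = [np.zeros_like(w) for w in self.weights_ + self.biases_]
        beta1, beta2, eps, lr = 0.9, 0.999, 1e-8, FFNN_LEARNING_RATE
        t = 0

        best_loss = np.inf
        best_params = None
        stall = 0
        n = Xtr.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, FFNN_BATCH_SIZE):
                idx = order[start : start + FFNN_BATCH_SIZE]
                Xb, yb = Xtr[idx], ytr[idx]
                p, cache = self._forward(Xb, rng=rng)
                # BCE + sigmoid gradient: dL/dz3 = (p - y)/m
                X0, z1, a1d, mask, z2, a2 = cache
                mb = len(yb)
                d3 = ((p - yb) / mb)[:, None]
                gW3 = a2.T @ d3
                gb3 = d3.sum(axis=0)
                d2 = (d3 @ self.weights_[2].T) * (z2 > 0)
                gW2 = a1d.T @ d2
                gb2 = d2.sum(axis=0)
                d1 = (d2 @ self.weights_[1].T) * mask * (z1 > 0)
                gW1 = X0.T @ d1
                gb1 = d1.sum(axis=0)
                grads = [gW1, gW2, gW3, gb1, gb2, gb3]
                params = self.weights_ + self.biases_
                t += 1
                for i, (prm, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    prm -= lr * mhat / (np.sqrt(vhat) + eps)
            self.epochs_run_ = epoch
            if use_es:
                val_loss = self._bce(self._forward(Xva)[0], yva)
                if val_loss < best_loss - 1e-12:
                    best_loss = val_loss
                    best_params = (
                        [w.copy() for w in self.weights_],
                        [b.copy() for b in self.biases_],
                    )
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_params is not None:
            self.weights_, self.biases_ = best_params
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise ParameterError("FFNN is not fitted")
        X = np.asarray(X, dtype=np.float64)
        return self._forward(X)[0]


def train_model(config: ModelConfig, X_train: np.ndarray, y_train: np.ndarray) -> TrainedModel:
    """Train one base model on fully preprocessed (scaled, PCA-space) data."""
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train)
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("training labels contain a single class")
    y01 = (y == classes.max()).astype(int) if classes.size == 2 else y

    meta: dict = {}
    if config.kind == "LR":
        est = LogisticRegression(max_iter=config.lr_max_iterations, random_state=config.seed)
        est.fit(X, y01)
        meta["converged"] = bool(est.n_iter_[0] < config.lr_max_iterations)
    elif config.kind == "SVM_linear":
        with warnings.catch_warnings():
            # sklearn 1.9 deprecation chatter; Platt-calibrated SVC is the documented setup
            warnings.simplefilter("ignore", FutureWarning)
            est = SVC(kernel="linear", probability=True, C=config.svm_C, random_state=config.seed)
            est.fit(X, y01)
    elif config.kind == "GaussianNB":
        est = GaussianNB(var_smoothing=config.nb_var_smoothing)
        est.fit(X, y01)
    elif config.kind == "FFNN":
        est = NumpyFFNN(
            seed=config.seed,
            max_epochs=config.ffnn_max_epochs,
            patience=config.ffnn_patience,
            val_fraction=config.ffnn_val_fraction,
        )
        est.fit(X, y01)
        meta["epochs_run"] = est.epochs_run_
    else:  # pragma: no cover - guarded by ModelConfig
        raise ParameterError(f"unknown model kind {config.kind!r}")
    return TrainedModel(kind=config.kind, estimator=est, n_features=X.shape[1], metadata=meta)


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Positive-class scores in [0, 1], one per row; hard label is score > 0.5."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ParameterError(
            f"expected {model.n_features} features, got matrix of shape {X.shape}"
        )
    if model.kind == "FFNN":
        return model.estimator.predict_proba_pos(X)
    return model.estimator.predict_proba(X)[:, 1]
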