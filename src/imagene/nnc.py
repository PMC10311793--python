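"""Neural-network classifier used as a disease-driven feature extractor.

A fully connected softmax classifier is trained to predict diagnosis (NC vs
AD) from the processed imaging table; the post-activation values of its
second-to-last layer are the extracted imaging phenotypes that enter the
genetic association model.  Because the network is optimized to separate the
diagnostic classes, these penultimate activations are nonlinear functions of
the whole image that carry disease-relevant signal -- they sit "one logistic
regression away" from the diagnosis.

Defaults follow the reference configuration: one hidden layer of 35 units,
full-batch Adagrad with learning rate 0.01, no learning-rate decay, 350
epochs, training restricted to the NC/AD subjects (MCI excluded), with
per-feature z-scoring fitted on the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .schema import FeatureMatrix

__all__ = [
    "softmax",
    "nll_loss",
    "TrainConfig",
    "NeuralNetClassifier",
    "train_classifier",
    "predict_proba",
    "extract_features",
]

_PROB_FLOOR = 1e-12

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: ``o_j = exp(o*_j) / sum_k exp(o*_k)``."""
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(logits)):
        raise ValueError("softmax requires finite logits")
    shifted = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def nll_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Multinomial negative log-likelihood, summed over subjects.

    ``labels`` are integer class indices into the columns of
    ``probabilities``.  Zero probability at the true class is clipped at
    1e-12 with a warning rather than propagating -inf.
    """
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y = np.asarray(labels, dtype=int)
    if y.ndim != 1 or len(y) != P.shape[0]:
        raise ValueError("labels must be one class index per probability row")
    if y.min() < 0 or y.max() >= P.shape[1]:
        raise ValueError("label index out of range")
    p_true = P[np.arange(len(y)), y]
    if np.any(p_true < _PROB_FLOOR):
        warnings.warn("probability at true class below 1e-12; clipping", RuntimeWarning)
        p_true = np.maximum(p_true, _PROB_FLOOR)
    return float(-np.log(p_true).sum())


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for :class:`NeuralNetClassifier`."""

    n_hidden_layers: int = 1
    hidden_size: int = 35
    optimizer: str = "adagrad"
    learning_rate: float = 0.01
    lr_decay: float = 0.0
    epochs: int = 350
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 0 or self.hidden_size <= 0 or self.epochs <= 0:
            raise ValueError("sizes and epochs must be positive")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class NeuralNetClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Fully connected softmax classifier with Adagrad full-batch training.

    scikit-learn estimator: ``fit(X, y)`` with ``X`` of shape (n_subjects,
    n_features); ``transform`` returns the penultimate-layer activations
    (the extracted features).  ``hidden_layer_sizes=()`` gives plain
    multinomial logistic regression (a convex problem, useful for sanity
    checks); in that case the "penultimate layer" is the standardized input.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (35,)
    activation : {"relu", "tanh", "identity"}, default "relu"
    learning_rate, lr_decay, epochs : Adagrad step size, its decay
        (lr_t = lr / (1 + decay * t)), and the number of full-batch epochs.
    standardize : z-score inputs with training-set statistics.
    random_state : seed for weight initialization.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (35,),
        activation: str = "relu",
        learning_rate: float = 0.01,
        lr_decay: float = 0.0,
        epochs: int = 350,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.standardize = standardize
        self.random_state = random_state

    # -- internal ---------------------------------------------------------

    def _forward(self, A0: np.ndarray):
        """Return (activations per layer, logits). A0 is standardized input."""
        act, _ = _ACTIVATIONS[self.activation]
        A = [A0]
        for l in range(len(self.coefs_) - 1):
            A.append(act(A[-1] @ self.coefs_[l] + self.intercepts_[l]))
        logits = A[-1] @ self.coefs_[-1] + self.intercepts_[-1]
        return A, logits

    def _loss_and_grads(self, A0: np.ndarray, y_idx: np.ndarray):
        """Summed NLL and its gradients w.r.t. every weight and bias."""
        _, dact = _ACTIVATIONS[self.activation]
        A, logits = self._forward(A0)
        P = softmax(logits, axis=1)
        loss = nll_loss(P, y_idx)
        n = len(y_idx)
        delta = P.copy()
        delta[np.arange(n), y_idx] -= 1.0  # d loss / d logits
        gW = [None] * len(self.coefs_)
        gb = [None] * len(self.coefs_)
        for l in range(len(self.coefs_) - 1, -1, -1):
            gW[l] = A[l].T @ delta
            gb[l] = delta.sum(axis=0)
            if l > 0:
                Z_prev = A[l - 1] @ self.coefs_[l - 1] + self.intercepts_[l - 1]
                delta = (delta @ self.coefs_[l].T) * dact(Z_prev)
        return loss, gW, gb

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.mean_) / self.scale_

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_subjects, n_features) matching y")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError(
                f"training set must contain at least two classes, got {self.classes_}"
            )
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        A0 = self._standardize(X)

        sizes = [X.shape[1], *self.hidden_layer_sizes, len(self.classes_)]
        rng = np.random.default_rng(self.random_state)
        self.coefs_ = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[l]), size=(sizes[l], sizes[l + 1]))
            for l in range(len(sizes) - 1)
        ]
        self.intercepts_ = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]

        accW = [np.zeros_like(W) for W in self.coefs_]
        accb = [np.zeros_like(b) for b in self.intercepts_]
        eps = 1e-10
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            loss, gW, gb = self._loss_and_grads(A0, y_idx)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            self.loss_curve_.append(loss)
            lr = self.learning_rate / (1.0 + self.lr_decay * epoch)
            for l in range(len(self.coefs_)):
                accW[l] += gW[l] ** 2
                accb[l] += gb[l] ** 2
                self.coefs_[l] -= lr * gW[l] / (np.sqrt(accW[l]) + eps)
                self.intercepts_[l] -= lr * gb[l] / (np.sqrt(accb[l]) + eps)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} features; model expects {self.n_features_in_}"
            )
        _, logits = self._forward(self._standardize(X))
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def transform(self, X, pre_activation: bool = False) -> np.ndarray:
        """Penultimate-layer values: the extracted imaging features.

        Post-activation by default (the layer's "neurons"); pre-activation
        values are available behind the flag.
        """
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        A0 = self._standardize(X)
        if not self.hidden_layer_sizes:
            return A0
        act, _ = _ACTIVATIONS[self.activation]
        A = A0
        for l in range(len(self.coefs_) - 1):
            Z = A @ self.coefs_[l] + self.intercepts_[l]
            A = act(Z)
        return Z if pre_activation else A

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted model to a single portable .npz file."""
        check_is_fitted(self, "coefs_")
        payload = {
            "activation": np.array(self.activation),
            "classes": self.classes_.astype(str),
            "mean": self.mean_,
            "scale": self.scale_,
            "n_layers": np.array(len(self.coefs_)),
        }
        for l, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            payload[f"W{l}"] = W
            payload[f"b{l}"] = b
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "NeuralNetClassifier":
        data = np.load(path, allow_pickle=False)
        n_layers = int(data["n_layers"])
        coefs = [data[f"W{l}"] for l in range(n_layers)]
        model = cls(
            hidden_layer_sizes=tuple(W.shape[1] for W in coefs[:-1]),
            activation=str(data["activation"]),
        )
        model.coefs_ = coefs
        model.intercepts_ = [data[f"b{l}"] for l in range(n_layers)]
        model.classes_ = data["classes"]
        model.mean_ = data["mean"]
        model.scale_ = data["scale"]
        model.n_features_in_ = coefs[0].shape[0]
        return model


# -- FeatureMatrix-oriented wrappers --------------------------------------


def train_classifier(
    features: FeatureMatrix, labels, config: TrainConfig | None = None
) -> tuple[NeuralNetClassifier, list[float]]:
    """Train the classifier on a features x subjects table.

    The caller must restrict ``labels`` (and columns of ``features``) to the
    two training classes; MCI subjects are excluded from classifier training
    and only re-enter at feature extraction.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError(f"training labels contain a single class {present}")
    model = NeuralNetClassifier(
        hidden_layer_sizes=tuple([config.hidden_size] * config.n_hidden_layers),
        activation=config.activation,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        epochs=config.epochs,
        random_state=config.seed,
    )
    model.fit(features.values.T, labels)
    return model, list(model.loss_curve_)


def predict_proba(model: NeuralNetClassifier, features: FeatureMatrix) -> np.ndarray:
    """Class-probability matrix, one row per subject."""
    return model.predict_proba(features.values.T)


def extract_features(
    model: NeuralNetClassifier, features: FeatureMatrix, pre_activation: bool = False
) -> FeatureMatrix:
    """Penultimate-layer activations for every subject (including MCI)."""
    H = model.transform(features.values.T, pre_activation=pre_activation)
    ids = [f"nn_feature_{j + 1}" for j in range(H.shape[1])]
    return FeatureMatrix(H.T, ids, list(features.subject_ids))
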