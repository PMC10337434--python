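"""Supervised representation encoder.

A small feed-forward network is trained to discriminate septic patients
from non-septic controls on the standardized 40-variable snapshot; its
penultimate-layer activations serve as the low-dimensional representation
space in which phenotypes are derived. The rationale is the usual one for
supervised representation learning: the sepsis-prediction objective forces
the hidden layers to retain the physiologically informative directions of
the input while attenuating nuisance variation, which yields more
consistent downstream clusters than the raw standardized features.

The network is a multilayer perceptron (default 40 -> 128 -> d, ReLU,
sigmoid head, d = 10) trained by Adam on binary cross-entropy. The
exported representation is the *pre-activation* of the penultimate layer —
a linear read-out of the wide hidden layer — which preserves the geometry
of the hidden features far better than the rectified activations (ReLU
folds half of every direction to zero, collapsing within-class structure
the classification loss does not need). Which layer and width best
summarize the physiology is an open modeling choice, so both are
configurable and recorded with the model.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_array, check_X_y

__all__ = ["SepsisRepresentationEncoder", "train_encoder", "encode"]


class SepsisRepresentationEncoder(BaseEstimator, TransformerMixin):
    """MLP sepsis-label classifier exposing penultimate activations.

    Parameters
    ----------
    hidden_size : int, default 128
        Width of the first hidden layer.
    representation_dim : int, default 10
        Width of the second (penultimate) hidden layer; the dimension of
        the representation space. Must be >= 2.
    learning_rate : float, default 1e-3
    epochs : int, default 30
        Maximum Adam epochs (early-stopped by sklearn's loss tolerance).
    batch_size : int, default 64
    l2_penalty : float, default 1e-4
    random_state : int, default 0
        Seeds weight initialization and minibatch shuffling; identical
        configuration and data give identical final weights.

    Attributes
    ----------
    mlp_ : fitted :class:`sklearn.neural_network.MLPClassifier`
    training_history_ : ndarray
        Per-epoch training loss.
    n_features_in_ : int
    """

    def __init__(self, hidden_size: int = 128, representation_dim: int = 10,
                 learning_rate: float = 1e-3, epochs: int = 30,
                 batch_size: int = 64, l2_penalty: float = 1e-4,
                 random_state: int = 0):
        self.hidden_size = hidden_size
        self.representation_dim = representation_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.l2_penalty = l2_penalty
        self.random_state = random_state

    def fit(self, X, y) -> "SepsisRepresentationEncoder":
        X, y = check_X_y(X, y)
        if self.representation_dim < 2:
            raise ValueError("representation_dim must be >= 2")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=(self.hidden_size, self.representation_dim),
            activation="relu",
            solver="adam",
            alpha=self.l2_penalty,
            batch_size=min(self.batch_size, X.shape[0]),
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            shuffle=True,
            random_state=self.random_state,
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self.mlp_.fit(X, y)
        self.training_history_ = np.asarray(self.mlp_.loss_curve_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Penultimate-layer representation, shape (n, representation_dim).

        ReLU through the earlier hidden layers, then the linear map into
        the penultimate layer without rectification (see module docstring).
        """
        X = check_array(X)
        if not hasattr(self, "mlp_"):
            raise RuntimeError("encoder is not fitted")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, encoder expects {self.n_features_in_}"
            )
        a = X
        for W, b in zip(self.mlp_.coefs_[:-2], self.mlp_.intercepts_[:-2]):
            a = np.maximum(a @ W + b, 0.0)
        return a @ self.mlp_.coefs_[-2] + self.mlp_.intercepts_[-2]

    def predict_proba(self, X) -> np.ndarray:
        return self.mlp_.predict_proba(check_array(X))

    def save(self, path) -> None:
        """Serialize weights to an NPZ file (schema-versioned)."""
        arrays = {"schema_version": np.array(1),
                  "n_layers": np.array(len(self.mlp_.coefs_))}
        for i, (W, b) in enumerate(zip(self.mlp_.coefs_, self.mlp_.intercepts_)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)


def train_encoder(features, labels, **config) -> SepsisRepresentationEncoder:
    """Functional wrapper: fit an encoder on a feature matrix and labels."""
    X = getattr(features, "values", features)
    X = getattr(X, "to_numpy", lambda: X)()
    return SepsisRepresentationEncoder(**config).fit(np.asarray(X), np.asarray(labels))


def encode(model: SepsisRepresentationEncoder, features) -> np.ndarray:
    """Functional wrapper: map features to representations (row order kept)."""
    X = getattr(features, "values", features)
    X = getattr(X, "to_numpy", lambda: X)()
    return model.transform(np.asarray(X))
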