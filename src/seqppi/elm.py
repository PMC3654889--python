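"""Extreme learning machine: a single-hidden-layer network whose hidden
parameters are random and whose output weights are solved analytically.

Training draws the input weights w_i and biases b_i at random, forms the
hidden-layer output matrix H[j, i] = g(w_i . x_j + b_i), and computes
the output weights as the minimum-norm least-squares solution
beta = H^+ T via the Moore-Penrose pseudoinverse.  With L hidden
neurons and N <= L distinct samples the fit is exact with probability
one over the random weights.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
}

MODEL_FORMAT_VERSION = "seqppi-elm-v1"


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Extreme learning machine classifier.

    Parameters
    ----------
    n_hidden : int, default 200
        Number of hidden neurons L.
    activation : {"sigmoid", "tanh"}, default "sigmoid"
        Hidden-layer activation g.
    random_state : int or None
        Seed for the hidden weights/biases.  Weights and bias of each
        neuron are drawn together as one uniform[-1, 1] row of an
        (L, n+1) block, so for a fixed seed the first L' neurons of a
        larger network coincide with an L'-neuron network (hidden
        layers are nested across sizes).
    rcond : float, default 1e-8
        Relative cutoff for singular values in the pseudoinverse.

    Attributes
    ----------
    input_weights_ : (L, n) random input weights.
    biases_ : (L,) random hidden biases.
    output_weights_ : (L, m) analytically solved output weights, one
        column per class (one-hot targets, argmax decoding).
    classes_ : sorted class labels.
    """

    def __init__(
        self,
        n_hidden: int = 200,
        activation: str = "sigmoid",
        random_state: int | None = None,
        rcond: float = 1e-8,
    ):
        self.n_hidden = n_hidden
        self.activation = activation
        self.random_state = random_state
        self.rcond = rcond

    def _activation_fn(self):
        try:
            return ACTIVATIONS[self.activation]
        except KeyError:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {sorted(ACTIVATIONS)}"
            ) from None

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        g = self._activation_fn()
        return g(X @ self.input_weights_.T + self.biases_)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self._activation_fn()
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        m = len(self.classes_)
        T = np.zeros((n, m))
        T[np.arange(n), y_idx] = 1.0

        rng = np.random.default_rng(self.random_state)
        wb = rng.uniform(-1.0, 1.0, size=(self.n_hidden, d + 1))
        self.input_weights_ = wb[:, :d]
        self.biases_ = wb[:, d]
        H = self._hidden(X)
        self.output_weights_ = np.linalg.pinv(H, rcond=self.rcond) @ T
        self.n_features_in_ = d
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Raw output-node scores H @ beta, shape (n_samples, n_classes)."""
        check_is_fitted(self, "output_weights_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return self._hidden(X) @ self.output_weights_

    def decision_function(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        if scores.shape[1] == 2:
            return scores[:, 1] - scores[:, 0]
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        # argmax returns the first maximum, i.e. ties go to the lower class index
        return self.classes_[np.argmax(scores, axis=1)]

    def save(self, path) -> None:
        """Serialize weights, biases, output weights and metadata to .npz."""
        check_is_fitted(self, "output_weights_")
        np.savez(
            path,
            format_version=np.array(MODEL_FORMAT_VERSION),
            input_weights=self.input_weights_,
            biases=self.biases_,
            output_weights=self.output_weights_,
            classes=self.classes_,
            activation=np.array(self.activation),
            random_state=np.array(-1 if self.random_state is None else self.random_state),
        )

    @classmethod
    def load(cls, path) -> "ELMClassifier":
        with np.load(path, allow_pickle=False) as data:
            version = str(data["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ValueError(f"unsupported model format {version!r}")
            seed = int(data["random_state"])
            obj = cls(
                n_hidden=data["input_weights"].shape[0],
                activation=str(data["activation"]),
                random_state=None if seed < 0 else seed,
            )
            obj.input_weights_ = data["input_weights"]
            obj.biases_ = data["biases"]
            obj.output_weights_ = data["output_weights"]
            obj.classes_ = data["classes"]
        obj.n_features_in_ = obj.input_weights_.shape[1]
        return obj


def hidden_output_matrix(model: ELMClassifier, X) -> np.ndarray:
    """The N x L hidden-layer output matrix H[j, i] = g(w_i . x_j + b_i)."""
    check_is_fitted(model, "input_weights_")
    X = check_array(X)
    if X.shape[1] != model.input_weights_.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.input_weights_.shape[1]}"
        )
    return model._hidden(X)


def elm_train(
    X,
    y,
    n_hidden: int,
    activation: str = "sigmoid",
    random_state: int | None = None,
) -> ELMClassifier:
    """Train a single ELM (thin wrapper over :class:`ELMClassifier`)."""
    return ELMClassifier(
        n_hidden=n_hidden, activation=activation, random_state=random_state
    ).fit(X, y)


def elm_predict(model: ELMClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(scores, labels)`` for a trained model."""
    scores = model.predict_scores(X)
    return scores, model.classes_[np.argmax(scores, axis=1)]
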