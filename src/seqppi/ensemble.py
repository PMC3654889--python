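"""Ensembles of extreme learning machines with majority voting.

A single ELM's accuracy depends on its random hidden layer.  Training
several ELMs on the same data with the same hidden-layer size but
independent random weights and combining their hard predictions by
majority vote removes that dependence and stabilizes the classifier.
The member count is kept odd so binary votes cannot tie.

The hidden-layer size is a hyperparameter; ``select_hidden_count``
picks it by stratified cross-validated accuracy of a single ELM over a
grid (default 20..300 in steps of 10).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .elm import ELMClassifier

DEFAULT_NEURON_GRID: tuple[int, ...] = tuple(range(20, 301, 10))
DEFAULT_N_MEMBERS = 15

ENSEMBLE_FORMAT_VERSION = "seqppi-eelm-v1"

# fixed odd stride (2**31-scale golden-ratio constant) for the member
# seed counter: member i of a run seeded with `base` uses
# (base + (i+1)*_SEED_STRIDE) mod 2**31
_SEED_STRIDE = 2654435761


def _member_seed(base: int, i: int) -> int:
    return (base + (i + 1) * _SEED_STRIDE) % (2**31)


class EELMClassifier(ClassifierMixin, BaseEstimator):
    """Majority-vote ensemble of independently seeded ELMs.

    All members share ``n_hidden`` and the input dimension; their seeds
    are derived from ``random_state`` by a fixed counter scheme so runs
    are reproducible end to end.
    """

    def __init__(
        self,
        n_hidden: int = 200,
        n_members: int = DEFAULT_N_MEMBERS,
        activation: str = "sigmoid",
        random_state: int | None = None,
    ):
        self.n_hidden = n_hidden
        self.n_members = n_members
        self.activation = activation
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_members < 1 or self.n_members % 2 == 0:
            raise ValueError(
                f"n_members must be odd and >= 1 (got {self.n_members}) "
                "so binary votes cannot tie"
            )
        base = 0 if self.random_state is None else int(self.random_state)
        self.member_seeds_ = [_member_seed(base, i) for i in range(self.n_members)]
        self.members_ = [
            ELMClassifier(
                n_hidden=self.n_hidden,
                activation=self.activation,
                random_state=seed,
            ).fit(X, y)
            for seed in self.member_seeds_
        ]
        self.classes_ = self.members_[0].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def vote_counts(self, X) -> np.ndarray:
        """Per-sample member votes for each class, shape (n, n_classes)."""
        check_is_fitted(self, "members_")
        X = check_array(X)
        counts = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        class_index = {c: j for j, c in enumerate(self.classes_)}
        for member in self.members_:
            pred = member.predict(X)
            idx = np.fromiter((class_index[p] for p in pred), dtype=np.intp, count=len(pred))
            counts[np.arange(len(pred)), idx] += 1
        return counts

    def predict(self, X) -> np.ndarray:
        counts = self.vote_counts(X)
        # argmax ties break toward the lower class index (cannot occur
        # for binary labels with an odd member count)
        return self.classes_[np.argmax(counts, axis=1)]

    def save(self, path) -> None:
        """Serialize all members plus a manifest to one .npz file."""
        check_is_fitted(self, "members_")
        payload = {
            "format_version": np.array(ENSEMBLE_FORMAT_VERSION),
            "n_members": np.array(self.n_members),
            "classes": self.classes_,
            "activation": np.array(self.activation),
            "member_seeds": np.array(self.member_seeds_),
        }
        for i, m in enumerate(self.members_):
            payload[f"member{i}_input_weights"] = m.input_weights_
            payload[f"member{i}_biases"] = m.biases_
            payload[f"member{i}_output_weights"] = m.output_weights_
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "EELMClassifier":
        with np.load(path, allow_pickle=False) as data:
            version = str(data["format_version"])
            if version != ENSEMBLE_FORMAT_VERSION:
                raise ValueError(f"unsupported ensemble format {version!r}")
            n_members = int(data["n_members"])
            activation = str(data["activation"])
            seeds = [int(s) for s in data["member_seeds"]]
            members = []
            for i in range(n_members):
                m = ELMClassifier(
                    n_hidden=data[f"member{i}_input_weights"].shape[0],
                    activation=activation,
                    random_state=seeds[i],
                )
                m.input_weights_ = data[f"member{i}_input_weights"]
                m.biases_ = data[f"member{i}_biases"]
                m.output_weights_ = data[f"member{i}_output_weights"]
                m.classes_ = data["classes"]
                m.n_features_in_ = m.input_weights_.shape[1]
                members.append(m)
            obj = cls(
                n_hidden=members[0].n_hidden,
                n_members=n_members,
                activation=activation,
            )
            obj.members_ = members
            obj.member_seeds_ = seeds
            obj.classes_ = data["classes"]
        obj.n_features_in_ = members[0].n_features_in_
        return obj


def eelm_train(
    X,
    y,
    n_hidden: int,
    n_members: int = DEFAULT_N_MEMBERS,
    random_state: int | None = None,
) -> EELMClassifier:
    """Train a majority-vote ELM ensemble (thin wrapper)."""
    return EELMClassifier(
        n_hidden=n_hidden, n_members=n_members, random_state=random_state
    ).fit(X, y)


def eelm_predict(ensemble: EELMClassifier, X) -> np.ndarray:
    """Majority-vote labels for a trained ensemble."""
    return ensemble.predict(X)


def select_hidden_count(
    X,
    y,
    grid: tuple[int, ...] | None = None,
    folds: int = 5,
    random_state: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the hidden-layer size by stratified-CV accuracy of one ELM.

    Returns ``(best_L, table)`` where the table lists mean CV accuracy
    per grid value.  Ties break toward the smaller size.  The same fold
    split is reused across the grid so sizes are compared on identical
    data.
    """
    X, y = check_X_y(X, y)
    grid = tuple(sorted(DEFAULT_NEURON_GRID if grid is None else grid))
    if not grid:
        raise ValueError("neuron grid must be non-empty")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    base = 0 if random_state is None else int(random_state)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=base % (2**31))
    splits = list(skf.split(X, y))
    means = []
    for L in grid:
        accs = []
        for f, (tr, te) in enumerate(splits):
            seed = (base + 131 * L + f * _SEED_STRIDE) % (2**31)
            clf = ELMClassifier(n_hidden=L, random_state=seed).fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        means.append(float(np.mean(accs)))
    table = pd.DataFrame({"n_hidden": grid, "cv_accuracy": means})
    best = int(table.loc[int(np.argmax(means)), "n_hidden"])  # first max -> smallest L
    return best, table
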