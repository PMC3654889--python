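"""End-to-end predictor: encoding -> [-1,1] scaling -> PCA -> EELM.

``PPIPredictor`` is the deployable object the CLI trains and applies.
Its ``X`` is a sequence of ``(seq_a, seq_b)`` string pairs, so it plugs
into sklearn model-selection utilities directly on sequence data.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .decomposition import PCAReducer
from .elm import ELMClassifier
from .ensemble import DEFAULT_N_MEMBERS, EELMClassifier
from .features import EncoderConfig, PairEncoder
from .preprocessing import IntervalScaler

BUNDLE_FORMAT_VERSION = "seqppi-model-v1"


class PPIPredictor(ClassifierMixin, BaseEstimator):
    """Sequence-pair interaction classifier.

    Fits, in order: the pair encoder (stateless), an :class:`IntervalScaler`
    on the training feature matrix, a :class:`PCAReducer`, and an
    :class:`EELMClassifier` on the reduced features.
    """

    def __init__(
        self,
        lg: int = 30,
        dmax: int = 30,
        ct_relative: bool = True,
        n_components: int | float = 0.95,
        n_hidden: int = 200,
        n_members: int = DEFAULT_N_MEMBERS,
        clip: bool = True,
        random_state: int | None = None,
    ):
        self.lg = lg
        self.dmax = dmax
        self.ct_relative = ct_relative
        self.n_components = n_components
        self.n_hidden = n_hidden
        self.n_members = n_members
        self.clip = clip
        self.random_state = random_state

    def _encoder(self) -> PairEncoder:
        return PairEncoder(lg=self.lg, dmax=self.dmax, ct_relative=self.ct_relative)

    def fit(self, X, y):
        y = np.asarray(y)
        self.encoder_ = self._encoder().fit(X)
        F = self.encoder_.transform(X)
        self.scaler_ = IntervalScaler(clip=self.clip).fit(F)
        Fs = self.scaler_.transform(F)
        self.pca_ = PCAReducer(n_components=self.n_components).fit(Fs)
        Z = self.pca_.transform(Fs)
        self.classifier_ = EELMClassifier(
            n_hidden=self.n_hidden,
            n_members=self.n_members,
            random_state=self.random_state,
        ).fit(Z, y)
        self.classes_ = self.classifier_.classes_
        return self

    def _reduce(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        F = self.encoder_.transform(X)
        return self.pca_.transform(self.scaler_.transform(F))

    def predict(self, X) -> np.ndarray:
        return self.classifier_.predict(self._reduce(X))

    def vote_counts(self, X) -> np.ndarray:
        return self.classifier_.vote_counts(self._reduce(X))

    def save(self, path) -> None:
        """Serialize the whole fitted pipeline to one .npz file."""
        check_is_fitted(self, "classifier_")
        meta = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "params": self.get_params(),
        }
        payload = {
            "meta": np.array(json.dumps(meta)),
            "scaler_min": self.scaler_.data_min_,
            "scaler_max": self.scaler_.data_max_,
            "pca_mean": self.pca_.mean_,
            "pca_components": self.pca_.components_,
            "pca_eigenvalues": self.pca_.eigenvalues_,
            "pca_explained_fraction": self.pca_.explained_fraction_,
            "classes": self.classes_,
            "member_seeds": np.array(self.classifier_.member_seeds_),
        }
        for i, m in enumerate(self.classifier_.members_):
            payload[f"member{i}_input_weights"] = m.input_weights_
            payload[f"member{i}_biases"] = m.biases_
            payload[f"member{i}_output_weights"] = m.output_weights_
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "PPIPredictor":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format {meta.get('format_version')!r}"
                )
            obj = cls(**meta["params"])
            obj.encoder_ = obj._encoder().fit([])

            scaler = IntervalScaler(clip=obj.clip)
            scaler.data_min_ = data["scaler_min"]
            scaler.data_max_ = data["scaler_max"]
            scaler.range_ = scaler.data_max_ - scaler.data_min_
            scaler.constant_mask_ = scaler.range_ == 0
            scaler.n_features_in_ = len(scaler.data_min_)
            obj.scaler_ = scaler

            pca = PCAReducer(n_components=obj.n_components)
            pca.mean_ = data["pca_mean"]
            pca.components_ = data["pca_components"]
            pca.eigenvalues_ = data["pca_eigenvalues"]
            pca.explained_fraction_ = data["pca_explained_fraction"]
            pca.n_features_in_ = pca.components_.shape[0]
            pca.n_components_ = pca.components_.shape[1]
            obj.pca_ = pca

            seeds = [int(s) for s in data["member_seeds"]]
            members = []
            for i, seed in enumerate(seeds):
                m = ELMClassifier(
                    n_hidden=data[f"member{i}_input_weights"].shape[0],
                    random_state=seed,
                )
                m.input_weights_ = data[f"member{i}_input_weights"]
                m.biases_ = data[f"member{i}_biases"]
                m.output_weights_ = data[f"member{i}_output_weights"]
                m.classes_ = data["classes"]
                m.n_features_in_ = m.input_weights_.shape[1]
                members.append(m)
            clf = EELMClassifier(
                n_hidden=members[0].n_hidden,
                n_members=len(members),
                random_state=obj.random_state,
            )
            clf.members_ = members
            clf.member_seeds_ = seeds
            clf.classes_ = data["classes"]
            clf.n_features_in_ = members[0].n_features_in_
            obj.classifier_ = clf
            obj.classes_ = data["classes"]
        return obj


def pair_sequences(proteome, pairs) -> list[tuple[str, str]]:
    """Resolve a pair table against a proteome into (seq_a, seq_b) tuples."""
    return [
        (proteome[a].sequence, proteome[b].sequence)
        for a, b in zip(pairs["id_a"], pairs["id_b"])
    ]
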