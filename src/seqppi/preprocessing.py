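"""Input rescaling to [-1, 1] on training statistics."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class IntervalScaler(TransformerMixin, BaseEstimator):
    """Per-feature affine map sending the training min/max to -1/+1.

    Constant features (zero training range) map to 0.  Unseen data can
    fall outside the training range; with ``clip=True`` (default) the
    output is clipped to [-1, 1] so the classifier input domain stays
    bounded.
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.range_ = self.data_max_ - self.data_min_
        self.constant_mask_ = self.range_ == 0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, scaler was fit on {self.n_features_in_}"
            )
        denom = np.where(self.constant_mask_, 1.0, self.range_)
        Z = 2.0 * (X - self.data_min_) / denom - 1.0
        Z[:, self.constant_mask_] = 0.0
        if self.clip:
            np.clip(Z, -1.0, 1.0, out=Z)
        return Z


def rescale_minmax(X_train, X_apply=None, clip: bool = True):
    """Fit a [-1, 1] scaler on X_train and apply it.

    Returns ``(train_scaled, apply_scaled, scaler)``; ``apply_scaled``
    is None when no X_apply is given.
    """
    scaler = IntervalScaler(clip=clip).fit(X_train)
    train_scaled = scaler.transform(X_train)
    apply_scaled = scaler.transform(X_apply) if X_apply is not None else None
    return train_scaled, apply_scaled, scaler
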