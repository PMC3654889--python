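"""Principal component analysis for feature reduction.

Fit a linear projection on training features only and transform train
and test matrices into the reduced space.  ``PCAReducer`` exposes the
projection pieces explicitly — mean vector, orthonormal component
matrix (columns are eigenvectors of the sample covariance), eigenvalues
in decreasing order — and serializes them to a single file.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

FORMAT_VERSION = "seqppi-pca-v1"


class PCAReducer(TransformerMixin, BaseEstimator):
    """PCA projection fitted on training data.

    Parameters
    ----------
    n_components : int or float, default 0.95
        An integer keeps exactly that many leading components; a float
        in (0, 1) keeps the smallest number of components whose
        cumulative explained-variance fraction reaches the target.

    Attributes
    ----------
    mean_ : (M,) training column means.
    components_ : (M, k) matrix whose columns are the top-k
        eigenvectors of the 1/(N-1) sample covariance, orthonormal,
        sign-fixed so each component's largest-magnitude loading is
        positive.
    eigenvalues_ : (k,) covariance eigenvalues, non-increasing.
    explained_fraction_ : (k,) per-component share of total variance.
    """

    def __init__(self, n_components: int | float = 0.95):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        n, m = X.shape
        if np.allclose(X, X[0]):
            raise ValueError("all rows identical: covariance is zero, PCA undefined")
        k = self.n_components
        if isinstance(k, (int, np.integer)):
            if not 1 <= k <= min(n - 1, m):
                raise ValueError(
                    f"n_components={k} out of range 1..{min(n - 1, m)} "
                    f"for a {n}x{m} matrix"
                )
        elif not 0 < k < 1:
            raise ValueError("fractional n_components must lie in (0, 1)")
        self._pca = PCA(n_components=k, svd_solver="full").fit(X)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_.T  # M x k, columns = eigenvectors
        self.eigenvalues_ = self._pca.explained_variance_
        self.explained_fraction_ = self._pca.explained_variance_ratio_
        self.n_features_in_ = m
        self.n_components_ = self._pca.n_components_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, projection was fit on {self.n_features_in_}"
            )
        return (X - self.mean_) @ self.components_

    def inverse_transform(self, Y) -> np.ndarray:
        check_is_fitted(self, "components_")
        Y = check_array(Y)
        return Y @ self.components_.T + self.mean_

    def save(self, path) -> None:
        """Serialize mean, components and eigenvalues to one .npz file."""
        check_is_fitted(self, "components_")
        np.savez(
            path,
            format_version=np.array(FORMAT_VERSION),
            mean=self.mean_,
            components=self.components_,
            eigenvalues=self.eigenvalues_,
            explained_fraction=self.explained_fraction_,
        )

    @classmethod
    def load(cls, path) -> "PCAReducer":
        with np.load(path, allow_pickle=False) as data:
            version = str(data["format_version"])
            if version != FORMAT_VERSION:
                raise ValueError(f"unsupported projection format {version!r}")
            obj = cls(n_components=int(data["components"].shape[1]))
            obj.mean_ = data["mean"]
            obj.components_ = data["components"]
            obj.eigenvalues_ = data["eigenvalues"]
            obj.explained_fraction_ = data["explained_fraction"]
        obj.n_features_in_ = obj.components_.shape[0]
        obj.n_components_ = obj.components_.shape[1]
        return obj


def pca_fit(X, k: int | None = None, variance_target: float | None = None) -> PCAReducer:
    """Fit a PCA projection, either with exactly k components or with the
    smallest count reaching ``variance_target`` cumulative explained
    variance (default 0.95)."""
    if k is not None and variance_target is not None:
        raise ValueError("give either k or variance_target, not both")
    n_components = k if k is not None else (variance_target if variance_target is not None else 0.95)
    return PCAReducer(n_components=n_components).fit(X)


def pca_transform(proj: PCAReducer, X) -> np.ndarray:
    """Project X into the reduced space: (X - mean) @ components."""
    return proj.transform(X)
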