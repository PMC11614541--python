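"""Body-size scoring: correlation-matrix PCA of three adult size traits.

Head width, pronotum width and pronotum length are strongly collinear in
crickets; their first principal component serves as a single body-size index.
The PCA runs on the correlation matrix (standardized traits), so eigenvalues
sum to the trait count and PC1's share of variance is eigenvalue / 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

TRAIT_COLUMNS = ("head_width_mm", "pronotum_width_mm", "pronotum_length_mm")


class BodySizePCA(TransformerMixin, BaseEstimator):
    """Correlation-matrix PCA reducing size traits to principal-component scores.

    Parameters
    ----------
    n_components : int, default 3
        Number of components to keep when transforming.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_traits, n_components)
        Unit-norm eigenvectors, PC1 sign fixed so all its loadings are >= 0.
    eigenvalues_ : ndarray of shape (n_traits,)
        Eigenvalues of the trait correlation matrix, descending; they sum to
        the number of traits.
    proportion_variance_ : ndarray of shape (n_traits,)
        eigenvalue / n_traits.
    mean_, scale_ : ndarray of shape (n_traits,)
        Per-trait standardization constants (mean and sample sd).
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            bad = int(np.flatnonzero(self.scale_ == 0)[0])
            raise ValueError(f"trait column {bad} has zero variance; PCA is degenerate")
        Z = (X - self.mean_) / self.scale_
        corr = np.corrcoef(Z, rowvar=False)
        vals, vecs = np.linalg.eigh(corr)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        # sign convention: PC1 loadings all nonnegative (size axis points "up");
        # other components follow the largest-absolute-loading-positive rule
        for j in range(vecs.shape[1]):
            pivot = vecs[:, j].sum() if j == 0 else vecs[np.argmax(np.abs(vecs[:, j])), j]
            if pivot < 0:
                vecs[:, j] = -vecs[:, j]
        self.eigenvalues_ = np.clip(vals, 0.0, None)
        self.proportion_variance_ = self.eigenvalues_ / X.shape[1]
        self.loadings_ = vecs[:, : self.n_components]
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.loadings_

    def get_feature_names_out(self, input_features=None):
        return np.array([f"pc{i + 1}" for i in range(self.loadings_.shape[1])])


def body_size_pc1(
    adults: pd.DataFrame, columns: tuple[str, ...] = TRAIT_COLUMNS
) -> tuple[pd.Series, BodySizePCA]:
    """PC1 body-size score per subject from measurer-averaged trait columns.

    Rows with any missing trait are excluded from the fit and get NaN scores.
    Returns the score series (aligned to the input index) and the fitted PCA.
    """
    X = adults.loc[:, list(columns)]
    complete = X.notna().all(axis=1)
    if complete.sum() < 3:
        raise ValueError("need at least 3 subjects with complete trait triples")
    pca = BodySizePCA().fit(X.loc[complete].to_numpy(float))
    scores = pd.Series(np.nan, index=adults.index, name="size_pc1")
    scores.loc[complete] = pca.transform(X.loc[complete].to_numpy(float))[:, 0]
    return scores, pca
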