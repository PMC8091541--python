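"""Dimensionality reduction of the primary modality before fitting.

Fitting in a reduced space (PCA/NMF/truncated SVD) is the standard workflow
for expression matrices: the factors become the primary features whose weights
are learned, and the retained loading matrix maps those weights back to genes
via :func:`modalign.api.softmax_feature_scores`.  PCA centers and decomposes
along directions of high variance; NMF suits non-negative counts; truncated
SVD skips centering and therefore works on sparse matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from sklearn.decomposition import NMF, PCA, TruncatedSVD

from .exceptions import InvalidInputError

_METHODS = ("pca", "nmf", "truncated_svd", "none")


@dataclass(frozen=True)
class ReductionSpec:
    method: str = "none"
    n_components: int = 50

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise InvalidInputError(
                f"unknown reduction method {self.method!r}; choose from {_METHODS}"
            )
        if self.method != "none" and self.n_components < 1:
            raise InvalidInputError("n_components must be >= 1")


def reduce(
    X: np.ndarray | scipy.sparse.spmatrix,
    spec: ReductionSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce ``X`` (N x G) to factors (N x d) plus loadings (d x G).

    The factors serve as the primary modality passed to the optimizer; the
    loadings feed score back-mapping.  ``method="none"`` returns the input
    (densified) with identity loadings.  No log or scaling transform is
    applied here: count normalization is the caller's decision.
    """
    sparse_in = scipy.sparse.issparse(X)
    if spec.method == "none":
        Xd = np.asarray(X.todense() if sparse_in else X, dtype=float)
        return Xd, np.eye(Xd.shape[1])
    n, g = X.shape
    if spec.n_components > min(n, g):
        raise InvalidInputError(
            f"n_components={spec.n_components} exceeds min(N, G)={min(n, g)}"
        )
    if spec.method == "truncated_svd":
        if spec.n_components >= min(n, g):
            raise InvalidInputError(
                "truncated_svd requires n_components < min(N, G)"
            )
        model = TruncatedSVD(
            n_components=spec.n_components, random_state=seed, algorithm="arpack"
        )
        factors = model.fit_transform(X)
        return factors, model.components_
    Xd = np.asarray(X.todense() if sparse_in else X, dtype=float)
    if not np.all(np.isfinite(Xd)):
        raise InvalidInputError("non-finite entries in input matrix")
    if spec.method == "pca":
        model = PCA(n_components=spec.n_components, svd_solver="full")
        factors = model.fit(Xd).transform(Xd)
        return factors, model.components_
    # nmf
    if Xd.min() < 0:
        raise InvalidInputError("nmf requires non-negative input")
    model = NMF(
        n_components=spec.n_components,
        init="nndsvda",
        random_state=seed,
        max_iter=500,
    )
    factors = model.fit_transform(Xd)
    return factors, model.components_
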