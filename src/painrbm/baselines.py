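"""Linear comparator models: class-conditional linear discriminant and a
principal-component projection feeding a linear max-margin classifier.

Both return scoring objects with the same contract as the RBM
discriminant — callable on a feature matrix, returning one real score per
row, higher meaning more pain-like — so the evaluation code treats all
models identically.  These are controls, not contributions: the
projection/margin pipeline delegates to scikit-learn; the discriminant is
the classical pooled-covariance direction, implemented directly so the
singular-covariance behaviour (explicit error vs. ridge) is under our
control for binary inputs, which are frequently rank-deficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

__all__ = [
    "LinearModelConfig",
    "LinearDiscriminantScorer",
    "PCAMarginScorer",
    "fit_linear_discriminant",
    "fit_pca_margin_classifier",
]


@dataclass
class LinearModelConfig:
    """Settings for the linear comparators.

    ``n_components`` is the retained principal-subspace dimension
    (default 4).  The discriminant direction is one-dimensional for two
    classes, so it has no free dimension parameter.  The margin classifier
    is a linear-kernel SVM with ``C = 1`` by default.
    """

    n_components: int = 4
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be positive")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    return labels


@dataclass
class LinearDiscriminantScorer:
    """Fisher/LDA scoring function: score(x) = x . Sigma^-1 (mu1 - mu0).

    ``direction`` is the discriminant direction in feature space; scores
    are monotone in the estimated class-1 posterior under the shared-
    covariance Gaussian model.
    """

    direction: np.ndarray
    offset: float

    def __call__(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.direction.size:
            raise ValueError("feature dimension does not match fitted model")
        return X @ self.direction + self.offset


def fit_linear_discriminant(X, labels, ridge: float = 1e-6) -> LinearDiscriminantScorer:
    """Fit the two-class linear discriminant on a (binary) feature matrix.

    The pooled within-class covariance of binary indicators is often
    singular; ``ridge`` adds ``ridge * I`` before solving (default 1e-6).
    Passing ``ridge = 0`` raises an explicit error on singular covariance
    recommending the ridge option.
    """
    X = np.asarray(X, dtype=float)
    labels = _check_two_classes(labels)
    X0, X1 = X[labels == 0], X[labels == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = X0.shape[0], X1.shape[0]
    S = (
        (n0 - 1) * np.cov(X0, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
        + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
    ) / max(n0 + n1 - 2, 1)
    if ridge > 0:
        S = S + ridge * np.eye(S.shape[0])
    try:
        if ridge == 0 and np.linalg.matrix_rank(S) < S.shape[0]:
            raise np.linalg.LinAlgError("singular pooled covariance")
        direction = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-class covariance is singular; refit with a "
            "positive ridge (e.g. ridge=1e-6) to regularize"
        ) from exc
    offset = float(-0.5 * direction @ (mu0 + mu1))
    return LinearDiscriminantScorer(direction=direction, offset=offset)


@dataclass
class PCAMarginScorer:
    """PCA projection followed by a linear max-margin decision function."""

    pca: PCA
    svm: SVC
    n_components_used: int

    def __call__(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.svm.decision_function(self.pca.transform(X))


def fit_pca_margin_classifier(
    X, labels, config: LinearModelConfig | None = None
) -> PCAMarginScorer:
    """Project onto the top-k variance directions, then fit a linear SVM.

    If ``k`` exceeds the rank of the centered data the projection is
    reduced to the rank with a warning.  Scores are the SVM decision
    function on the projected coordinates (positive = class 1).
    """
    config = config or LinearModelConfig()
    X = np.asarray(X, dtype=float)
    labels = _check_two_classes(labels)
    if config.n_components > X.shape[1]:
        raise ValueError("n_components cannot exceed the number of features")

    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    k = config.n_components
    if k > rank:
        warnings.warn(
            f"requested {k} components but centered data has rank {rank}; "
            f"reducing to {rank}",
            stacklevel=2,
        )
        k = max(rank, 1)

    pca = PCA(n_components=k, svd_solver="full").fit(X)
    proj = pca.transform(X)
    svm = SVC(kernel="linear", C=config.svm_c).fit(proj, labels)
    return PCAMarginScorer(pca=pca, svm=svm, n_components_used=k)
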