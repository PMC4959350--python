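"""Free-energy discriminant classification with a trained RBM.

The classifier trains a generative RBM on visible vectors ``v = (x, c)``
where ``x`` are binary abnormality features and ``c`` is the binary pain
label, occupying the **last** visible position.  At prediction time the
label is unknown, so both completions ``(x, 0)`` and ``(x, 1)`` are scored
by their free energies.  The intractable partition function cancels in the
ratio

    p(c=0 | x) / p(c=1 | x) = p(x, 0) / p(x, 1) = exp(f1 - f0),

so the posterior is the logistic of the free-energy difference:
``p1 = logistic(f0 - f1)``.  This form is overflow-safe and makes
``p0 + p1 = 1`` exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .rbm import RBMParameters, free_energy, hidden_conditional

__all__ = [
    "LabeledInstance",
    "append_label",
    "class_posterior",
    "posterior_scores",
    "posterior_table",
    "predict_label",
    "hidden_representation",
]

#: Index convention: the pain label is the last visible unit.
LABEL_INDEX = -1


@dataclass(frozen=True)
class LabeledInstance:
    """Binary feature vector ``x`` plus pain label ``c`` (1 = pain).

    ``v`` is the (n_features + 1)-dimensional visible vector fed to the
    RBM, formed by appending ``c`` to ``x``.
    """

    x: np.ndarray
    c: int

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if not np.all((x == 0) | (x == 1)):
            raise ValueError("features must be 0/1 bits")
        if self.c not in (0, 1):
            raise ValueError("label must be 0 or 1")
        object.__setattr__(self, "x", x)

    @property
    def v(self) -> np.ndarray:
        return append_label(self.x, self.c)


def append_label(x, c) -> np.ndarray:
    """Visible vector with the label appended at the last index."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.concatenate([x, [float(c)]])
    c_col = np.full((x.shape[0], 1), float(c))
    return np.hstack([x, c_col])


def _check_feature_dim(x: np.ndarray, params: RBMParameters) -> None:
    n_features = params.n_visible - 1
    if n_features < 1:
        raise ValueError("discriminant model needs at least 2 visible units")
    if x.shape[-1] != n_features:
        raise ValueError(
            f"feature vector of length {x.shape[-1]} does not match model "
            f"trained on {n_features} features (+1 label unit)"
        )


def class_posterior(x, params: RBMParameters) -> tuple[float, float]:
    """Posterior (p0, p1) over the pain label for one feature vector.

    ``p1 = logistic(f(x+0) - f(x+1))``; ``p0 = 1 - p1`` exactly.
    """
    x = np.asarray(x, dtype=float)
    _check_feature_dim(x, params)
    f0 = free_energy(append_label(x, 0), params)
    f1 = free_energy(append_label(x, 1), params)
    p1 = float(expit(f0 - f1))
    return 1.0 - p1, p1


def posterior_scores(X, params: RBMParameters) -> np.ndarray:
    """Vectorized ``p1`` for each row of a binary feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_feature_dim(X, params)
    f0 = free_energy(append_label(X, 0), params)
    f1 = free_energy(append_label(X, 1), params)
    return expit(f0 - f1)


def posterior_table(X, params: RBMParameters, threshold: float = 0.5) -> pd.DataFrame:
    """Two-column posterior table for downstream ROC sweeps.

    Columns: instance index, p0, p1 and the thresholded prediction.
    """
    p1 = posterior_scores(X, params)
    return pd.DataFrame(
        {
            "instance": np.arange(len(p1)),
            "p0": 1.0 - p1,
            "p1": p1,
            "prediction": (p1 >= threshold).astype(int),
        }
    )


def predict_label(x, params: RBMParameters, threshold: float = 0.5) -> int:
    """Threshold the posterior: 1 iff p1 >= threshold (ties -> pain).

    Classifying the exact tie as positive is the conservative choice for a
    pain-detection task.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    _, p1 = class_posterior(x, params)
    return int(p1 >= threshold)


def hidden_representation(x, params: RBMParameters) -> np.ndarray:
    """Hidden-unit activation probabilities used as learned features.

    The label unit is unknown at feature-extraction time; by convention it
    is clamped to 0 ("off") before computing the hidden conditional.  The
    result can be fed to any downstream classifier.
    """
    x = np.asarray(x, dtype=float)
    _check_feature_dim(x, params)
    return hidden_conditional(append_label(x, 0), params)
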