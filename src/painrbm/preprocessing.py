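"""Personalized binarization of numeric flowsheet readings.

Each patient has their own "normal" physiological regime, so a per-patient
Gaussian baseline (mu, sigma) is fitted to every retained data item.  A
reading ``t`` is mapped to the probability that it is abnormal via the
two-sided central coverage of the fitted Gaussian,

    p(abnormal) = 2 * Phi(|t - mu| / sigma) - 1,

which is 0 at the patient's mean, symmetric in the deviation, strictly
increasing in |t - mu| and approaches 1 in the tails.  Thresholding this
probability at 0.5 is equivalent to flagging readings more than
``z0 = Phi^-1(0.75) ~ 0.6745`` standard deviations from the mean, so by
construction half of in-regime Gaussian readings are coded abnormal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "FeatureNormalizer",
    "fit_normalizer",
    "abnormality_probability",
    "binarize_dataset",
    "load_flowsheet",
]

#: |z| above which the two-sided coverage exceeds the 0.5 threshold.
ABNORMAL_Z = float(ndtri(0.75))  # ~0.674490


@dataclass
class FeatureNormalizer:
    """Per-patient Gaussian baseline and abnormality threshold.

    Fitted on exactly one patient's data (the personalization contract).
    Features that cannot support a Gaussian fit (all missing, fewer than
    two observations, or zero variance) are dropped and recorded in
    ``dropped`` with the reason.
    """

    feature_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    threshold: float = 0.5
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.feature_names) == len(self.mu) == len(self.sigma)):
            raise ValueError("feature_names, mu, sigma must align")
        if np.any(self.sigma <= 0):
            raise ValueError("every retained feature must have sigma > 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                    "threshold": self.threshold,
                    "dropped": self.dropped,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureNormalizer":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(d["feature_names"]),
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            threshold=float(d["threshold"]),
            dropped=[tuple(x) for x in d["dropped"]],
        )


def fit_normalizer(
    patient_table: pd.DataFrame | np.ndarray,
    feature_names: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> FeatureNormalizer:
    """Fit per-feature (mu, sigma) on one patient's numeric table.

    Missing cells (NaN) are ignored.  ``sigma`` uses the n-1 denominator.
    Features with fewer than two observations or zero variance are dropped
    with a warning and recorded on the returned normalizer.
    """
    if isinstance(patient_table, pd.DataFrame):
        if feature_names is None:
            feature_names = list(patient_table.columns)
        values = patient_table.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        values = np.asarray(patient_table, dtype=float)
        if values.ndim != 2:
            raise ValueError("patient_table must be 2-D (rows x features)")
        if feature_names is None:
            feature_names = [f"feature_{i}" for i in range(values.shape[1])]
        if len(feature_names) != values.shape[1]:
            raise ValueError("feature_names does not match table width")

    kept, mus, sigmas, dropped = [], [], [], []
    for j, name in enumerate(feature_names):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            dropped.append((name, "fewer than 2 observations"))
            continue
        sd = float(np.std(obs, ddof=1))
        if sd == 0.0:
            dropped.append((name, "zero variance"))
            continue
        kept.append(name)
        mus.append(float(np.mean(obs)))
        sigmas.append(sd)

    for name, reason in dropped:
        warnings.warn(f"dropping feature {name!r}: {reason}", stacklevel=2)
    if not kept:
        raise ValueError("no feature with a valid Gaussian fit; cannot binarize")
    return FeatureNormalizer(
        feature_names=kept,
        mu=np.array(mus),
        sigma=np.array(sigmas),
        threshold=threshold,
        dropped=dropped,
    )


def abnormality_probability(t, mu, sigma):
    """Probability that reading ``t`` is abnormal under baseline N(mu, sigma).

    Two-sided central coverage ``2 Phi(|t - mu| / sigma) - 1``: the
    probability that a baseline draw lies closer to the mean than ``t``.
    Vectorized over any broadcastable arguments.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = np.abs((np.asarray(t, dtype=float) - mu) / sigma)
    return 2.0 * ndtr(z) - 1.0


def binarize_dataset(
    patient_table: pd.DataFrame | np.ndarray,
    normalizer: FeatureNormalizer,
) -> tuple[np.ndarray, np.ndarray]:
    """Map numeric readings to binary abnormality indicators.

    A cell becomes 1 when its abnormality probability exceeds the
    normalizer's threshold; with the default 0.5 this is
    ``|t - mu| > 0.6745 sigma``.  Missing cells are imputed as 0
    ("normal") and flagged in the returned boolean mask.

    Returns ``(X, missing_mask)`` with shape (rows, retained features).
    """
    if isinstance(patient_table, pd.DataFrame):
        missing_cols = [
            n for n in normalizer.feature_names if n not in patient_table.columns
        ]
        if missing_cols:
            raise ValueError(f"table lacks fitted features: {missing_cols}")
        values = patient_table.loc[:, normalizer.feature_names].to_numpy(dtype=float)
    else:
        values = np.asarray(patient_table, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(normalizer.feature_names):
            raise ValueError(
                "table width does not match the normalizer's retained features"
            )

    mask = np.isnan(values)
    with np.errstate(invalid="ignore"):
        p = abnormality_probability(values, normalizer.mu, normalizer.sigma)
    X = (p > normalizer.threshold).astype(int)
    X[mask] = 0
    return X, mask


def load_flowsheet(
    path: str | Path, label_column: str = "pain", timestamp_column: str | None = "timestamp"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a flowsheet-style CSV: one row per timestamp, numeric item
    columns, a binary pain-label column; empty cells are missing.

    Returns ``(feature table, labels)`` with the timestamp and label
    columns removed from the table.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].to_numpy()
    if not np.all(np.isin(labels[~pd.isna(labels)], [0, 1])):
        raise ValueError("pain labels must be 0/1")
    drop = [label_column]
    if timestamp_column and timestamp_column in df.columns:
        drop.append(timestamp_column)
    return df.drop(columns=drop), labels.astype(int)
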