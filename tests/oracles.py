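"""Independent brute-force oracles used by the test suite.

Everything here works by explicit enumeration or pairwise counting and
deliberately avoids the closed forms used by the implementation, so the
two routes stay independent.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp

from painrbm.rbm import RBMParameters, energy


def bit_vectors(k: int) -> list[np.ndarray]:
    return [np.array(bits, dtype=float) for bits in itertools.product([0, 1], repeat=k)]


def enum_free_energy(v, params: RBMParameters) -> float:
    """-log sum_h e^{-E(v,h)} by enumerating all hidden states."""
    energies = [energy(v, h, params) for h in bit_vectors(params.n_hidden)]
    return float(-logsumexp([-e for e in energies]))


def enum_log_partition(params: RBMParameters) -> float:
    """log Z by the double sum over all (v, h) pairs."""
    energies = [
        energy(v, h, params)
        for v in bit_vectors(params.n_visible)
        for h in bit_vectors(params.n_hidden)
    ]
    return float(logsumexp([-e for e in energies]))


def enum_label_posterior(x, params: RBMParameters) -> tuple[float, float]:
    """p(c | x) for the label-last convention, by full enumeration of the
    joint Boltzmann distribution (unnormalized weights; Z cancels)."""
    weights = []
    for c in (0, 1):
        v = np.concatenate([np.asarray(x, dtype=float), [float(c)]])
        w = sum(
            np.exp(-energy(v, h, params)) for h in bit_vectors(params.n_hidden)
        )
        weights.append(w)
    total = weights[0] + weights[1]
    return weights[0] / total, weights[1] / total


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of positive/negative pairs correctly
    ordered, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_optimal_point(roc) -> tuple[float, float, float]:
    """Exhaustive search for the curve point nearest (0, 1), with the
    documented tie-breaks (higher TPR, then lower threshold)."""
    best = None
    for thr, fpr, tpr in zip(roc.thresholds, roc.fpr, roc.tpr):
        d = np.hypot(fpr, 1.0 - tpr)
        key = (d, -tpr, thr)
        if best is None or key < best[0]:
            best = (key, (float(thr), float(fpr), float(tpr)))
    return best[1]


def random_params(rng: np.random.Generator, m: int, n: int, scale: float = 1.0):
    return RBMParameters(
        W=rng.normal(0, scale, (m, n)),
        b=rng.normal(0, scale, m),
        c=rng.normal(0, scale, n),
    )
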