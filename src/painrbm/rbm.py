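"""Binary restricted Boltzmann machine: energy model, exact small-scale
inference, and contrastive-divergence training.

The RBM is an undirected bipartite model over ``m`` binary visible units
``v`` and ``n`` binary hidden units ``h`` with energy

    E(v, h) = - b.v - c.h - v' W h

and joint distribution ``p(v, h) = exp(-E(v, h)) / Z``.  Because the graph
is bipartite, the hidden units can be summed out in closed form, giving the
free energy

    f(v) = - b.v - sum_j softplus(c_j + W[:, j].v),

so that ``p(v) = exp(-f(v)) / Z``.  The partition function ``Z`` is
intractable in general; :func:`exact_log_partition` enumerates it for tiny
models and exists purely as a testing oracle.

Training maximises the data log-likelihood by stochastic gradient ascent
with the CD-k approximation (k = 1 by default): the intractable model
expectation is replaced by statistics gathered after k steps of Gibbs
sampling started from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "RBMParameters",
    "TrainingConfig",
    "energy",
    "free_energy",
    "exact_log_partition",
    "exact_mean_log_likelihood",
    "exact_log_likelihood_gradient",
    "hidden_conditional",
    "visible_conditional",
    "gibbs_step",
    "cd_k_gradient",
    "train_rbm",
    "initial_parameters",
    "all_binary_vectors",
]

#: Largest layer size for which exhaustive enumeration is permitted.  The
#: enumeration routines are test oracles, not production inference paths.
ENUMERATION_CAP = 20


@dataclass
class RBMParameters:
    """Weights and biases defining the energy surface.

    Attributes
    ----------
    W : ndarray of shape (m, n)
        Pairwise couplings ``w_ij`` between visible unit i and hidden unit j.
    b : ndarray of shape (m,)
        Visible biases.
    c : ndarray of shape (n,)
        Hidden biases.
    """

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.c.ndim != 1:
            raise ValueError("W must be a matrix, b and c vectors")
        m, n = self.W.shape
        if self.b.shape != (m,) or self.c.shape != (n,):
            raise ValueError(
                f"shape mismatch: W is {self.W.shape}, b is {self.b.shape}, "
                f"c is {self.c.shape}"
            )
        if m < 1 or n < 1:
            raise ValueError("need at least one visible and one hidden unit")
        self.validate_finite()

    def validate_finite(self) -> None:
        for name, arr in (("W", self.W), ("b", self.b), ("c", self.c)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    # -- serialization: flat JSON so trained models are portable/diffable --

    def to_dict(self) -> dict:
        return {
            "n_visible": self.n_visible,
            "n_hidden": self.n_hidden,
            "W": self.W.ravel().tolist(),  # row-major
            "b": self.b.tolist(),
            "c": self.c.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBMParameters":
        m, n = int(d["n_visible"]), int(d["n_hidden"])
        return cls(
            W=np.asarray(d["W"], dtype=float).reshape(m, n),
            b=np.asarray(d["b"], dtype=float),
            c=np.asarray(d["c"], dtype=float),
        )

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RBMParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainingConfig:
    """Hyperparameters of CD-k stochastic gradient training.

    ``n_hidden`` defaults to 20, the midpoint of the 15-30 range that is
    appropriate for flowsheet-scale inputs (a couple of dozen visible
    units).  The optimizer defaults (learning rate 0.1, 800 epochs,
    minibatches of 64) are sized for cohort-scale problems — a thousand
    rows of a few dozen bits — where CD-1 needs this much data exposure
    to couple the label unit reliably.  ``seed`` fully determines the
    training trajectory: weight initialization, minibatch order and every
    Gibbs sample.
    """

    n_hidden: int = 20
    k: int = 1
    learning_rate: float = 0.1
    epochs: int = 800
    batch_size: int = 64
    seed: int = 0
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.init_scale < 0:
            raise ValueError("init_scale must be non-negative")


# ---------------------------------------------------------------------------
# validation helpers


def _as_binary_matrix(data, length: int | None = None, name: str = "v") -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a vector or matrix of bits")
    if length is not None and arr.shape[1] != length:
        raise ValueError(f"{name} has length {arr.shape[1]}, expected {length}")
    if not np.all((arr == 0.0) | (arr == 1.0)):
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x) without overflow: logaddexp handles the linear branch.
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# energy and exact inference


def energy(v, h, params: RBMParameters) -> float:
    """Energy E(v, h) = -b.v - c.h - v'Wh of one joint configuration."""
    v = _as_binary_matrix(v, params.n_visible, "v")[0]
    h = _as_binary_matrix(h, params.n_hidden, "h")[0]
    return float(-params.b @ v - params.c @ h - v @ params.W @ h)


def free_energy(v, params: RBMParameters):
    """Free energy f(v) = -b.v - sum_j softplus(c_j + W[:,j].v).

    Accepts a single bit vector (returns a float) or a matrix of rows
    (returns an array).  Evaluated with a stable softplus so large biases
    or weights cannot overflow.
    """
    single = np.asarray(v).ndim == 1
    V = _as_binary_matrix(v, params.n_visible, "v")
    out = -V @ params.b - _softplus(params.c + V @ params.W).sum(axis=1)
    return float(out[0]) if single else out


def all_binary_vectors(k: int) -> np.ndarray:
    """All 2**k bit vectors of length k, as a (2**k, k) float matrix."""
    if k > ENUMERATION_CAP:
        raise ValueError(
            f"enumeration of 2^{k} states exceeds the oracle cap "
            f"({ENUMERATION_CAP}); this routine is for oracle/testing use only"
        )
    idx = np.arange(2**k, dtype=np.int64)
    return ((idx[:, None] >> np.arange(k)[None, :]) & 1).astype(float)


def exact_log_partition(params: RBMParameters) -> float:
    """log Z by exhaustive enumeration of visible states (oracle only).

    Refuses models with more than ``ENUMERATION_CAP`` units in either
    layer; the enumeration exists to check other code, not to scale.
    """
    m, n = params.n_visible, params.n_hidden
    if m > ENUMERATION_CAP or n > ENUMERATION_CAP:
        raise ValueError(
            f"model ({m} visible, {n} hidden) exceeds the enumeration cap of "
            f"{ENUMERATION_CAP}; exact_log_partition is an oracle-only routine"
        )
    V = all_binary_vectors(m)
    return float(logsumexp(-free_energy(V, params)))


def exact_mean_log_likelihood(data, params: RBMParameters) -> float:
    """Mean log p(v) over data rows, via the enumerated partition function."""
    V = _as_binary_matrix(data, params.n_visible, "data")
    log_z = exact_log_partition(params)
    return float(np.mean(-free_energy(V, params)) - log_z)


def exact_log_likelihood_gradient(data, params: RBMParameters):
    """Exact gradient of mean log-likelihood w.r.t. (W, b, c) (oracle only).

    Positive phase from the data, negative phase from the fully enumerated
    model distribution over visible states.
    """
    V = _as_binary_matrix(data, params.n_visible, "data")
    B = V.shape[0]
    PH = expit(params.c + V @ params.W)
    pos_W = V.T @ PH / B
    pos_b = V.mean(axis=0)
    pos_c = PH.mean(axis=0)

    Vall = all_binary_vectors(params.n_visible)
    logp = -free_energy(Vall, params)
    p = np.exp(logp - logsumexp(logp))
    PHall = expit(params.c + Vall @ params.W)
    neg_W = Vall.T @ (p[:, None] * PHall)
    neg_b = p @ Vall
    neg_c = p @ PHall
    return pos_W - neg_W, pos_b - neg_b, pos_c - neg_c


# ---------------------------------------------------------------------------
# conditionals and sampling


def hidden_conditional(v, params: RBMParameters) -> np.ndarray:
    """p(h_j = 1 | v) = logistic(c_j + v.W[:, j]) for each hidden unit."""
    single = np.asarray(v).ndim == 1
    V = _as_binary_matrix(v, params.n_visible, "v")
    P = expit(params.c + V @ params.W)
    return P[0] if single else P


def visible_conditional(h, params: RBMParameters) -> np.ndarray:
    """p(v_i = 1 | h) = logistic(b_i + W[i, :].h) for each visible unit."""
    single = np.asarray(h).ndim == 1
    H = _as_binary_matrix(h, params.n_hidden, "h")
    P = expit(params.b + H @ params.W.T)
    return P[0] if single else P


def gibbs_step(v, params: RBMParameters, rng: np.random.Generator):
    """One block-Gibbs sweep: sample h | v, then v' | h.

    Returns ``(h_sample, v_next)``; deterministic given the generator
    state.
    """
    ph = hidden_conditional(v, params)
    h = (rng.random(ph.shape) < ph).astype(float)
    pv = visible_conditional(h, params)
    v_next = (rng.random(pv.shape) < pv).astype(float)
    return h, v_next


# ---------------------------------------------------------------------------
# CD-k training


def cd_k_gradient(batch, params: RBMParameters, k: int, rng: np.random.Generator):
    """CD-k stochastic estimate of the log-likelihood gradient.

    Positive statistics are ``<v_i p(h_j=1|v)>`` over the batch; negative
    statistics are the same quantity evaluated after ``k`` Gibbs steps
    started at the data.  Hidden states along the chain are sampled, but
    the final reconstruction and final hidden statistics use conditional
    probabilities rather than samples — the usual variance-reduction
    choice for CD.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    V0 = _as_binary_matrix(batch, params.n_visible, "batch")
    if V0.shape[0] == 0:
        raise ValueError("empty batch")
    B = V0.shape[0]

    PH0 = expit(params.c + V0 @ params.W)
    Vk = V0
    for step in range(k):
        PH = PH0 if step == 0 else expit(params.c + Vk @ params.W)
        H = (rng.random(PH.shape) < PH).astype(float)
        PV = expit(params.b + H @ params.W.T)
        if step == k - 1:
            Vk = PV  # probabilities, not samples, for the final statistics
        else:
            Vk = (rng.random(PV.shape) < PV).astype(float)
    PHk = expit(params.c + Vk @ params.W)

    dW = (V0.T @ PH0 - Vk.T @ PHk) / B
    db = (V0 - Vk).mean(axis=0)
    dc = (PH0 - PHk).mean(axis=0)
    return dW, db, dc


def initial_parameters(n_visible: int, config: TrainingConfig) -> RBMParameters:
    """Initialization used by :func:`train_rbm`: W ~ N(0, init_scale^2),
    zero biases.  Exposed so likelihood-improvement checks can evaluate the
    exact starting point."""
    rng = np.random.default_rng(config.seed)
    W = rng.normal(0.0, config.init_scale, size=(n_visible, config.n_hidden))
    return RBMParameters(W=W, b=np.zeros(n_visible), c=np.zeros(config.n_hidden))


def train_rbm(data, config: TrainingConfig) -> RBMParameters:
    """Train a binary RBM by minibatch CD-k gradient ascent.

    The trajectory is a pure function of ``(data, config)``: the generator
    seeded by ``config.seed`` drives initialization, epoch shuffles and all
    Gibbs sampling, so two identical calls return bit-identical parameters.
    """
    V = _as_binary_matrix(data, None, "data")
    if V.shape[0] == 0:
        raise ValueError("empty training data")
    m = V.shape[1]

    rng = np.random.default_rng(config.seed)
    W = rng.normal(0.0, config.init_scale, size=(m, config.n_hidden))
    b = np.zeros(m)
    c = np.zeros(config.n_hidden)
    params = RBMParameters(W=W, b=b, c=c)

    n = V.shape[0]
    lr = config.learning_rate
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = V[order[start : start + config.batch_size]]
            dW, db, dc = cd_k_gradient(batch, params, config.k, rng)
            params.W += lr * dW
            params.b += lr * db
            params.c += lr * dc
    params.validate_finite()
    return params
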