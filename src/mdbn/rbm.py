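"""Restricted Boltzmann machine: energy, conditionals, CD-K training.

An RBM over visible units ``v`` (length n) and hidden units ``h`` (length m)
assigns energy

    E(v, h) = - sum_i a_i v_i - sum_j b_j h_j - sum_ij v_i W_ij h_j

and probability P(v, h) proportional to exp(-E).  Because the bipartite graph
has no intra-layer connections, the conditionals factorize:
P(h_j = 1 | v) = sigmoid(b_j + v . W[:, j]) and symmetrically for the visible
units.  Training maximizes the data log-likelihood approximately via
contrastive divergence with K Gibbs reconstruction steps (CD-1 by default):

    dW_ij = eps * (<v_i h_j>_data - <v_i h_j>_recon)
    da_i  = eps * (<v_i>_data - <v_i>_recon)
    db_j  = eps * (<h_j>_data - <h_j>_recon)

Visible units are treated as unit-interval valued (min-max normalized peak
intensities are used directly in the positive phase).  Phase conventions:
hidden states are sampled binary to drive the reconstruction, the
reconstruction uses visible probabilities, and the negative-phase association
uses hidden probabilities — the standard low-variance CD recipe.

For tiny models (n, m <= 12) :func:`exact_loglik_grad` evaluates the exact
gradient of the mean log-likelihood by exhaustive state enumeration; it is
the oracle the CD approximation is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "RBMParams",
    "CDConfig",
    "RBMTrainTrace",
    "sigmoid",
    "energy",
    "hidden_probs",
    "visible_probs",
    "sample_bernoulli",
    "cd_k_update",
    "train_rbm",
    "exact_loglik_grad",
]


def sigmoid(x):
    """Elementwise logistic function 1 / (1 + e^-x), stable for large |x|."""
    return expit(np.asarray(x, dtype=float))


@dataclass
class RBMParams:
    """One RBM's parameters: weights ``W`` (n x m), biases ``a`` (n), ``b`` (m)."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.a.ndim != 1 or self.b.ndim != 1:
            raise ValueError("W must be a matrix; a and b must be vectors")
        n, m = self.W.shape
        if self.a.shape[0] != n or self.b.shape[0] != m:
            raise ValueError(
                f"inconsistent shapes: W {self.W.shape}, a {self.a.shape}, "
                f"b {self.b.shape}"
            )
        for arr in (self.W, self.a, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class CDConfig:
    """Contrastive-divergence training configuration.

    Attributes
    ----------
    learning_rate
        Step size ``eps`` multiplying the CD update.
    epochs
        Number of full-batch update sweeps.
    K
        Gibbs reconstruction steps per update (CD-1 by default).
    dropout_rate
        Fraction of hidden units zeroed per epoch during pretraining.
    seed
        Seed making training a pure function of its inputs.
    weight_init_scale
        Standard deviation of the zero-mean Gaussian weight initialization.
    batch_size
        Optional mini-batch size; ``None`` (the default) trains full-batch.
    """

    learning_rate: float = 0.1
    epochs: int = 100
    K: int = 1
    dropout_rate: float = 0.2
    seed: int = 0
    weight_init_scale: float = 0.01
    batch_size: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.weight_init_scale <= 0:
            raise ValueError("weight_init_scale must be positive")


@dataclass
class RBMTrainTrace:
    """Per-epoch reconstruction error (mean squared difference between the
    input batch and the reconstructed visible probabilities)."""

    reconstruction_error: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reconstruction_error)


def _check_v(params: RBMParams, v: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != params.n_visible:
        raise ValueError(
            f"visible vector length {v.shape[1]} != n_visible {params.n_visible}"
        )
    return v


def _check_h(params: RBMParams, h: np.ndarray) -> np.ndarray:
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != params.n_hidden:
        raise ValueError(
            f"hidden vector length {h.shape[1]} != n_hidden {params.n_hidden}"
        )
    return h


def energy(params: RBMParams, v: Sequence[float], h: Sequence[float]) -> float:
    """Energy E(v, h) of a joint visible/hidden state."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError(
            f"expected v of length {params.n_visible} and h of length "
            f"{params.n_hidden}, got {v.shape} and {h.shape}"
        )
    return float(-(params.a @ v) - (params.b @ h) - v @ params.W @ h)


def hidden_probs(params: RBMParams, v) -> np.ndarray:
    """P(h_j = 1 | v) = sigmoid(b_j + v . W[:, j]), vector or batch."""
    vv = _check_v(params, v)
    out = sigmoid(params.b + vv @ params.W)
    return out[0] if np.ndim(v) == 1 else out


def visible_probs(params: RBMParams, h) -> np.ndarray:
    """P(v_i = 1 | h) = sigmoid(a_i + W[i, :] . h), vector or batch."""
    hh = _check_h(params, h)
    out = sigmoid(params.a + hh @ params.W.T)
    return out[0] if np.ndim(h) == 1 else out


def sample_bernoulli(p, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws (as floats) at probabilities ``p``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("Bernoulli probabilities must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(float)


def _cd_step(
    params: RBMParams,
    batch: np.ndarray,
    config: CDConfig,
    rng: np.random.Generator,
    hidden_mask: np.ndarray | None = None,
):
    """One CD-K update on a batch; returns (dW, da, db, recon_error)."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("batch must be non-empty")
    if batch.shape[1] != params.n_visible:
        raise ValueError(
            f"batch has {batch.shape[1]} columns, RBM has {params.n_visible} "
            "visible units"
        )
    mask = np.ones(params.n_hidden) if hidden_mask is None else np.asarray(hidden_mask)

    pos_h = hidden_probs(params, batch) * mask
    h_state = sample_bernoulli(pos_h, rng)
    v_prob = visible_probs(params, h_state)
    for _ in range(config.K - 1):
        h_prob = hidden_probs(params, v_prob) * mask
        h_state = sample_bernoulli(h_prob, rng)
        v_prob = visible_probs(params, h_state)
    neg_v = v_prob
    neg_h = hidden_probs(params, neg_v) * mask

    B = batch.shape[0]
    eps = config.learning_rate
    dW = eps * (batch.T @ pos_h - neg_v.T @ neg_h) / B
    da = eps * (batch - neg_v).mean(axis=0)
    db = eps * (pos_h - neg_h).mean(axis=0)
    recon_error = float(np.mean((batch - neg_v) ** 2))
    return dW, da, db, recon_error


def cd_k_update(
    params: RBMParams,
    batch: np.ndarray,
    config: CDConfig,
    rng: np.random.Generator,
    hidden_mask: np.ndarray | None = None,
):
    """CD-K parameter increments ``(dW, da, db)`` for one batch.

    Positive-phase hidden probabilities are computed on the data (with binary
    hidden samples driving the reconstruction); after K Gibbs half-steps the
    negative phase uses visible probabilities and their hidden probabilities.
    Associations are averaged over the batch and scaled by the learning rate.
    """
    dW, da, db, _ = _cd_step(params, batch, config, rng, hidden_mask)
    return dW, da, db


def train_rbm(
    data: np.ndarray, n_hidden: int, config: CDConfig
) -> tuple[RBMParams, RBMTrainTrace]:
    """Train one RBM with full-batch CD-K for ``config.epochs`` sweeps.

    Weights start from a zero-mean Gaussian scaled by
    ``config.weight_init_scale``; biases start at zero.  When
    ``config.dropout_rate > 0`` a fresh 0/1 hidden mask is resampled each
    epoch and multiplies the hidden probabilities in both CD phases.  The
    trace records the per-epoch reconstruction error.  Deterministic given
    ``config.seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("training data must be non-empty")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_visible = data.shape[1]
    params = RBMParams(
        W=rng.normal(0.0, config.weight_init_scale, size=(n_visible, n_hidden)),
        a=np.zeros(n_visible),
        b=np.zeros(n_hidden),
    )
    trace = RBMTrainTrace()
    for _ in range(config.epochs):
        if config.dropout_rate > 0:
            mask = sample_bernoulli(
                np.full(n_hidden, 1.0 - config.dropout_rate), rng
            )
        else:
            mask = None
        if config.batch_size is None:
            batches = [data]
        else:
            order = rng.permutation(data.shape[0])
            batches = [
                data[order[i : i + config.batch_size]]
                for i in range(0, data.shape[0], config.batch_size)
            ]
        errs = []
        for batch in batches:
            dW, da, db, err = _cd_step(params, batch, config, rng, mask)
            params.W += dW
            params.a += da
            params.b += db
            errs.append(err)
        trace.reconstruction_error.append(float(np.mean(errs)))
    return params, trace


def _binary_states(k: int) -> np.ndarray:
    """All 2^k binary vectors of length k as a (2^k, k) float array."""
    return (
        (np.arange(2**k)[:, None] >> np.arange(k)[None, :]) & 1
    ).astype(float)


def exact_loglik_grad(params: RBMParams, data: np.ndarray):
    """Exact gradient of the mean log-likelihood by state enumeration.

    Evaluates d/dtheta of mean_v log P(v) with
    P(v) = sum_h exp(-E(v, h)) / Z, enumerating all 2^n x 2^m joint states.
    Feasible only for n, m <= 12; used as the oracle for CD updates.
    """
    n, m = params.n_visible, params.n_hidden
    if n > 12 or m > 12:
        raise ValueError("exact enumeration limited to n, m <= 12")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != n:
        raise ValueError(f"data has {data.shape[1]} columns, expected {n}")

    # Data-dependent term: hidden conditionals given each observed v.
    p_h = hidden_probs(params, data)
    dW_data = data.T @ p_h / data.shape[0]
    da_data = data.mean(axis=0)
    db_data = p_h.mean(axis=0)

    # Model term: expectations under the full Boltzmann distribution.
    V = _binary_states(n)
    H = _binary_states(m)
    neg_E = (V @ params.a)[:, None] + (H @ params.b)[None, :] + V @ params.W @ H.T
    neg_E -= neg_E.max()
    P = np.exp(neg_E)
    P /= P.sum()
    dW_model = V.T @ P @ H
    da_model = P.sum(axis=1) @ V
    db_model = P.sum(axis=0) @ H

    return dW_data - dW_model, da_data - da_model, db_data - db_model
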