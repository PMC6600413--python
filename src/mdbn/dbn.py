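"""Deep belief network: greedy layer-wise pretraining and feed-forward pass.

A DBN is an ordered stack of RBMs in which each RBM is trained on the hidden
representation produced by the one below it.  Greedy pretraining here feeds
each layer the *hidden probabilities* (mean-field activations) of the
previous layer, so layer inputs are deterministic given the seed.  The
resulting weights initialize the supervised network that the classifier
module fine-tunes.

Dropout follows the standard convention: during training each hidden layer's
output is multiplied elementwise by a fresh Bernoulli(1 - rate) 0/1 mask; at
inference no units are dropped and activations are scaled by (1 - rate) so
expected activations match training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rbm import (
    CDConfig,
    RBMParams,
    RBMTrainTrace,
    hidden_probs,
    sample_bernoulli,
    train_rbm,
)

__all__ = ["DBNModel", "DropoutSpec", "pretrain", "forward", "apply_dropout_mask"]


@dataclass
class DBNModel:
    """Ordered RBM stack; ``layer_sizes`` = [visible dim, hidden dims...]."""

    layer_sizes: list[int]
    rbms: list[RBMParams]
    traces: list[RBMTrainTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rbms) != len(self.layer_sizes) - 1:
            raise ValueError(
                f"{len(self.rbms)} RBMs inconsistent with layer sizes "
                f"{self.layer_sizes}"
            )
        for l, rbm in enumerate(self.rbms):
            if rbm.n_visible != self.layer_sizes[l] or (
                rbm.n_hidden != self.layer_sizes[l + 1]
            ):
                raise ValueError(
                    f"RBM {l} shaped {rbm.n_visible}x{rbm.n_hidden} does not "
                    f"match layer sizes {self.layer_sizes[l]}-{self.layer_sizes[l+1]}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.rbms)

    def copy(self) -> "DBNModel":
        return DBNModel(
            layer_sizes=list(self.layer_sizes),
            rbms=[r.copy() for r in self.rbms],
            traces=list(self.traces),
        )


@dataclass
class DropoutSpec:
    """Dropout configuration: rate, mode ('train' or 'inference'), seed."""

    rate: float = 0.0
    mode: str = "inference"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.mode not in ("train", "inference"):
            raise ValueError(f"unknown dropout mode {self.mode!r}")


def apply_dropout_mask(
    activations: np.ndarray, spec: DropoutSpec, rng: np.random.Generator
) -> np.ndarray:
    """Mask activations (train mode) or scale them by 1 - rate (inference)."""
    activations = np.asarray(activations, dtype=float)
    if spec.mode == "train":
        if spec.rate == 0:
            return activations.copy()
        mask = sample_bernoulli(
            np.full(activations.shape, 1.0 - spec.rate), rng
        )
        return activations * mask
    return activations * (1.0 - spec.rate)


def pretrain(data: np.ndarray, layer_sizes: list[int], config: CDConfig) -> DBNModel:
    """Greedily pretrain a DBN: RBM l trains on RBM l-1's hidden probabilities.

    ``layer_sizes[0]`` must equal the data's column count.  Each layer trains
    with :func:`mdbn.rbm.train_rbm` under a seed derived from ``config.seed``
    and the layer index, so the result is deterministic and layer l depends
    only on the layers below it.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    layer_sizes = [int(s) for s in layer_sizes]
    if len(layer_sizes) < 2:
        raise ValueError("need at least one hidden layer")
    if any(s < 1 for s in layer_sizes):
        raise ValueError("all layer sizes must be >= 1")
    if layer_sizes[0] != data.shape[1]:
        raise ValueError(
            f"layer_sizes[0] = {layer_sizes[0]} != data columns {data.shape[1]}"
        )
    rbms: list[RBMParams] = []
    traces: list[RBMTrainTrace] = []
    current = data
    for l, n_hidden in enumerate(layer_sizes[1:]):
        layer_cfg = CDConfig(
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            K=config.K,
            dropout_rate=config.dropout_rate,
            seed=config.seed + l,
            weight_init_scale=config.weight_init_scale,
            batch_size=config.batch_size,
        )
        rbm, trace = train_rbm(current, n_hidden, layer_cfg)
        rbms.append(rbm)
        traces.append(trace)
        current = hidden_probs(rbm, current)
    return DBNModel(layer_sizes=layer_sizes, rbms=rbms, traces=traces)


def forward(model: DBNModel, data: np.ndarray, dropout: DropoutSpec) -> np.ndarray:
    """Feed data through every layer's hidden conditionals; return top layer.

    In train mode each hidden layer's output is multiplied by a fresh
    Bernoulli(1 - rate) mask; in inference mode activations are scaled by
    (1 - rate) instead.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"data has {data.shape[1]} columns, network expects "
            f"{model.layer_sizes[0]}"
        )
    rng = np.random.default_rng(dropout.seed)
    h = data
    for rbm in model.rbms:
        h = hidden_probs(rbm, h)
        h = apply_dropout_mask(h, dropout, rng)
    return h
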