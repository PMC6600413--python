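"""End-to-end classifier: DBN features + softmax head, jointly fine-tuned.

The supervised network is the sigmoid feed-forward net induced by the
pretrained DBN (weights ``W_l`` and hidden biases ``b_l`` of each RBM)
followed by a softmax regression head.  Its cost is the mean multiclass
cross-entropy plus an L2 weight-decay term (lambda/2) * sum of squared
weights, biases excluded:

    J = -(1/N) sum_s sum_c Y_sc log P_sc + (lambda/2) (sum_l ||W_l||^2 + ||A||^2)

Training follows the pretrain-then-fine-tune protocol: the head is first
fitted on frozen DBN features (so the softmax starts from informed rather
than random weights), then all parameters are optimized jointly by either
plain full-batch gradient descent or L-BFGS.  Dropout masks on the hidden
layers are resampled every fine-tuning iteration; within an iteration the
masks are held fixed so the line search sees a consistent objective.

Per-iteration traces record FMSE (mean squared error between predicted
probability vectors and one-hot targets on training data), FMR (training
misclassification rate) and TMR (test misclassification rate); the test set
never influences parameter updates.

Parameter flattening order (used for the optimizers and serialization):
layer 1 weights, layer 1 hidden biases, ..., softmax weights, softmax biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import line_search, minimize
from scipy.special import logsumexp

from .data_io import NormalizationState
from .dbn import DBNModel, DropoutSpec, forward
from .rbm import sample_bernoulli, sigmoid

__all__ = [
    "SoftmaxParams",
    "MDBNModel",
    "FinetuneConfig",
    "TrainingTrace",
    "softmax_probs",
    "cost_and_grad",
    "train_softmax_head",
    "finetune",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class SoftmaxParams:
    """Softmax regression head: ``weights`` (k x features), ``biases`` (k)."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.ndim != 2 or self.biases.ndim != 1:
            raise ValueError("weights must be a matrix, biases a vector")
        if self.weights.shape[0] != self.biases.shape[0]:
            raise ValueError("weights and biases disagree on class count")
        if not (
            np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.biases))
        ):
            raise ValueError("softmax parameters must be finite")

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "SoftmaxParams":
        return SoftmaxParams(self.weights.copy(), self.biases.copy())


@dataclass
class MDBNModel:
    """The end-to-end classifier: DBN, softmax head and dropout settings."""

    dbn: DBNModel
    softmax: SoftmaxParams
    dropout_rate: float = 0.0
    class_order: list[str] = field(default_factory=list)
    normalization: NormalizationState | None = None

    def __post_init__(self) -> None:
        if self.softmax.weights.shape[1] != self.dbn.layer_sizes[-1]:
            raise ValueError(
                f"softmax expects {self.softmax.weights.shape[1]} features, "
                f"DBN produces {self.dbn.layer_sizes[-1]}"
            )
        if self.class_order and len(self.class_order) != self.softmax.n_classes:
            raise ValueError("class order length must equal the class count")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    def copy(self) -> "MDBNModel":
        return MDBNModel(
            dbn=self.dbn.copy(),
            softmax=self.softmax.copy(),
            dropout_rate=self.dropout_rate,
            class_order=list(self.class_order),
            normalization=self.normalization,
        )


@dataclass
class FinetuneConfig:
    """Joint fine-tuning configuration.

    ``method`` is ``"gd"`` (plain full-batch gradient descent with fixed step
    ``learning_rate``) or ``"lbfgs"`` (limited-memory quasi-Newton with
    strong-Wolfe line search and ``lbfgs_history`` stored pairs).
    ``weight_decay`` is the L2 coefficient lambda; ``tolerance`` stops either
    method early when the gradient sup-norm falls below it.
    """

    method: str = "lbfgs"
    iterations: int = 300
    learning_rate: float = 0.1
    weight_decay: float = 1e-4
    lbfgs_history: int = 20
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("gd", "lbfgs"):
            raise ValueError(f"unknown fine-tuning method {self.method!r}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class TrainingTrace:
    """Per-iteration FMSE / FMR / TMR curves recorded during fine-tuning.

    ``cost`` additionally records the deterministic training objective
    (cross-entropy plus weight decay, no dropout masks) at each iteration;
    it is kept in memory for optimizer diagnostics and is not part of the
    exported CSV columns.
    """

    fmse: list[float] = field(default_factory=list)
    fmr: list[float] = field(default_factory=list)
    tmr: list[float] = field(default_factory=list)
    cost: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fmse)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.fmse) + 1),
                "fmse": self.fmse,
                "fmr": self.fmr,
                "tmr": self.tmr,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def softmax_probs(params: SoftmaxParams, features: np.ndarray) -> np.ndarray:
    """Class probabilities from affine logits, max-subtracted for stability."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != params.weights.shape[1]:
        raise ValueError(
            f"features have {features.shape[1]} columns, head expects "
            f"{params.weights.shape[1]}"
        )
    logits = features @ params.weights.T + params.biases
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Parameter flattening (documented fixed order: W_1, b_1, ..., W_L, b_L,
# softmax weights, softmax biases).
# ---------------------------------------------------------------------------

def flatten_params(model: MDBNModel) -> np.ndarray:
    parts = []
    for rbm in model.dbn.rbms:
        parts.append(rbm.W.ravel())
        parts.append(rbm.b.ravel())
    parts.append(model.softmax.weights.ravel())
    parts.append(model.softmax.biases.ravel())
    return np.concatenate(parts)


def set_flat_params(model: MDBNModel, x: np.ndarray) -> None:
    """Write a flat parameter vector back into the model (in place)."""
    i = 0
    for rbm in model.dbn.rbms:
        for arr in (rbm.W, rbm.b):
            arr.flat[:] = x[i : i + arr.size]
            i += arr.size
    for arr in (model.softmax.weights, model.softmax.biases):
        arr.flat[:] = x[i : i + arr.size]
        i += arr.size
    if i != x.size:
        raise ValueError(f"flat vector of size {x.size} does not fit model ({i})")


def _check_one_hot(Y: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not (
        np.all(np.isin(Y, (0.0, 1.0))) and np.allclose(Y.sum(axis=1), 1.0)
    ):
        raise ValueError("Y must be a one-hot matrix (rows summing to 1)")
    return Y


def _forward_train(
    model: MDBNModel, X: np.ndarray, masks: list[np.ndarray] | None
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Forward pass storing pre-mask sigmoid outputs and masked activations."""
    sigmoids: list[np.ndarray] = []
    acts: list[np.ndarray] = [X]
    h = X
    for l, rbm in enumerate(model.dbn.rbms):
        s = sigmoid(h @ rbm.W + rbm.b)
        sigmoids.append(s)
        h = s if masks is None else s * masks[l]
        acts.append(h)
    logits = h @ model.softmax.weights.T + model.softmax.biases
    return sigmoids, acts, logits


def cost_and_grad(
    model: MDBNModel,
    X: np.ndarray,
    Y: np.ndarray,
    weight_decay: float,
    dropout_masks: list[np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Cross-entropy + weight-decay cost and its exact analytic gradient.

    When ``dropout_masks`` (one 0/1 array per hidden layer, broadcastable to
    that layer's activations) is supplied, both cost and gradient are
    computed under those fixed masks, which makes finite-difference checks
    well-posed.  The gradient is flattened in the documented parameter order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = _check_one_hot(Y)
    if dropout_masks is not None:
        masks = [np.asarray(m, dtype=float) for m in dropout_masks]
        if len(masks) != len(model.dbn.rbms):
            raise ValueError(
                f"{len(masks)} dropout masks for {len(model.dbn.rbms)} hidden layers"
            )
    else:
        masks = None

    sigmoids, acts, logits = _forward_train(model, X, masks)
    N = X.shape[0]
    log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
    cost = -float(np.sum(Y * log_probs)) / N
    cost += 0.5 * weight_decay * (
        sum(float(np.sum(r.W**2)) for r in model.dbn.rbms)
        + float(np.sum(model.softmax.weights**2))
    )

    P = np.exp(log_probs)
    dlogits = (P - Y) / N
    dA = dlogits.T @ acts[-1] + weight_decay * model.softmax.weights
    dc = dlogits.sum(axis=0)
    dh = dlogits @ model.softmax.weights

    grads_W: list[np.ndarray] = [None] * len(model.dbn.rbms)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.dbn.rbms)  # type: ignore
    for l in range(len(model.dbn.rbms) - 1, -1, -1):
        if masks is not None:
            dh = dh * masks[l]
        s = sigmoids[l]
        dz = dh * s * (1.0 - s)
        grads_W[l] = acts[l].T @ dz + weight_decay * model.dbn.rbms[l].W
        grads_b[l] = dz.sum(axis=0)
        dh = dz @ model.dbn.rbms[l].W.T

    parts = []
    for l in range(len(model.dbn.rbms)):
        parts.append(grads_W[l].ravel())
        parts.append(grads_b[l].ravel())
    parts.append(dA.ravel())
    parts.append(dc.ravel())
    return cost, np.concatenate(parts)


def _softmax_cost_grad(
    x: np.ndarray, features: np.ndarray, Y: np.ndarray, weight_decay: float
) -> tuple[float, np.ndarray]:
    n, d = features.shape
    k = Y.shape[1]
    A = x[: k * d].reshape(k, d)
    c = x[k * d :]
    logits = features @ A.T + c
    log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
    cost = -float(np.sum(Y * log_probs)) / n + 0.5 * weight_decay * float(
        np.sum(A**2)
    )
    dlogits = (np.exp(log_probs) - Y) / n
    dA = dlogits.T @ features + weight_decay * A
    dc = dlogits.sum(axis=0)
    return cost, np.concatenate([dA.ravel(), dc])


def train_softmax_head(
    features: np.ndarray,
    Y: np.ndarray,
    weight_decay: float = 1e-4,
    iterations: int = 200,
    seed: int = 0,
) -> SoftmaxParams:
    """Fit the softmax head on frozen DBN features with L-BFGS.

    Starting the head from this fit (rather than from random weights) gives
    the joint fine-tuning an informed initialization.  ``iterations == 0``
    returns the zero initialization unchanged.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    Y = _check_one_hot(Y)
    if Y.shape[1] < 2 or np.any(Y.sum(axis=0) == Y.shape[0]):
        raise ValueError("head training needs at least two represented classes")
    k, d = Y.shape[1], features.shape[1]
    x0 = np.zeros(k * d + k)
    if iterations == 0:
        return SoftmaxParams(weights=x0[: k * d].reshape(k, d), biases=x0[k * d :])
    res = minimize(
        _softmax_cost_grad,
        x0,
        args=(features, Y, weight_decay),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": iterations},
    )
    x = res.x
    return SoftmaxParams(weights=x[: k * d].reshape(k, d), biases=x[k * d :])


def _sample_masks(
    model: MDBNModel, n: int, rng: np.random.Generator
) -> list[np.ndarray] | None:
    if model.dropout_rate == 0:
        return None
    return [
        sample_bernoulli(
            np.full((n, size), 1.0 - model.dropout_rate), rng
        )
        for size in model.dbn.layer_sizes[1:]
    ]


def _trace_point(
    model: MDBNModel,
    train_X: np.ndarray,
    train_Y: np.ndarray,
    test_X: np.ndarray,
    test_labels_idx: np.ndarray,
    trace: TrainingTrace,
    weight_decay: float,
) -> None:
    spec = DropoutSpec(rate=model.dropout_rate, mode="inference")
    feats = forward(model.dbn, train_X, spec)
    probs = softmax_probs(model.softmax, feats)
    trace.fmse.append(float(np.mean((probs - train_Y) ** 2)))
    pred = probs.argmax(axis=1)
    trace.fmr.append(float(np.mean(pred != train_Y.argmax(axis=1))))
    feats_t = forward(model.dbn, test_X, spec)
    pred_t = softmax_probs(model.softmax, feats_t).argmax(axis=1)
    trace.tmr.append(float(np.mean(pred_t != test_labels_idx)))
    ce = -float(np.mean(np.log(np.maximum(np.sum(probs * train_Y, axis=1), 1e-300))))
    decay = 0.5 * weight_decay * (
        sum(float(np.sum(r.W**2)) for r in model.dbn.rbms)
        + float(np.sum(model.softmax.weights**2))
    )
    trace.cost.append(ce + decay)


def _lbfgs_direction(
    g: np.ndarray, s_hist: list[np.ndarray], y_hist: list[np.ndarray]
) -> np.ndarray:
    """Two-loop recursion for the L-BFGS search direction -H g."""
    q = g.copy()
    alphas = []
    rhos = [1.0 / float(y @ s) for s, y in zip(s_hist, y_hist)]
    for s, y, rho in zip(reversed(s_hist), reversed(y_hist), reversed(rhos)):
        a = rho * (s @ q)
        alphas.append(a)
        q -= a * y
    if s_hist:
        s, y = s_hist[-1], y_hist[-1]
        q *= (s @ y) / (y @ y)
    for (s, y, rho), a in zip(zip(s_hist, y_hist, rhos), reversed(alphas)):
        beta = rho * (y @ q)
        q += (a - beta) * s
    return -q


def finetune(
    model: MDBNModel,
    train_X: np.ndarray,
    train_Y: np.ndarray,
    test_X: np.ndarray,
    test_Y: np.ndarray,
    config: FinetuneConfig,
) -> tuple[MDBNModel, TrainingTrace]:
    """Jointly optimize all DBN and softmax parameters; record traces.

    ``gd`` runs plain full-batch gradient descent with a fixed step;
    ``lbfgs`` runs a limited-memory quasi-Newton iteration with strong-Wolfe
    line search (Armijo backtracking fallback).  Dropout masks are resampled
    at the start of every iteration and held fixed within it.  After each
    iteration FMSE and FMR on the training data and TMR on the test data are
    appended to the trace; test labels are used for TMR bookkeeping only and
    never touch the parameter updates.  The input model is not modified.
    """
    model = model.copy()
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_Y = _check_one_hot(train_Y)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    test_Y = _check_one_hot(test_Y)
    test_idx = test_Y.argmax(axis=1)
    trace = TrainingTrace()
    if config.iterations == 0:
        return model, trace

    rng = np.random.default_rng(config.seed)
    x = flatten_params(model)
    lam = config.weight_decay
    n = train_X.shape[0]

    def objective(xv: np.ndarray, masks) -> tuple[float, np.ndarray]:
        set_flat_params(model, xv)
        return cost_and_grad(model, train_X, train_Y, lam, masks)

    if config.method == "gd":
        for _ in range(config.iterations):
            masks = _sample_masks(model, n, rng)
            cost, g = objective(x, masks)
            if not np.isfinite(cost):
                raise FloatingPointError("non-finite fine-tuning cost")
            x = x - config.learning_rate * g
            set_flat_params(model, x)
            _trace_point(model, train_X, train_Y, test_X, test_idx, trace, lam)
            if np.max(np.abs(g)) < config.tolerance:
                break
        return model, trace

    # L-BFGS with per-iteration mask resampling.
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    for it in range(config.iterations):
        masks = _sample_masks(model, n, rng)
        f, g = objective(x, masks)
        if not np.isfinite(f):
            raise FloatingPointError("non-finite fine-tuning cost")
        if np.max(np.abs(g)) < config.tolerance:
            set_flat_params(model, x)
            break
        d = _lbfgs_direction(g, s_hist, y_hist) if s_hist else -g
        if d @ g >= 0:  # not a descent direction; restart memory
            s_hist.clear()
            y_hist.clear()
            d = -g
        ls = line_search(
            lambda xv: objective(xv, masks)[0],
            lambda xv: objective(xv, masks)[1],
            x,
            d,
            gfk=g,
            old_fval=f,
            c1=1e-4,
            c2=0.9,
            maxiter=20,
        )
        alpha = ls[0]
        if alpha is None:
            # Armijo backtracking fallback for nonsmooth line-search failures.
            alpha = 1.0
            for _ in range(30):
                if objective(x + alpha * d, masks)[0] <= f + 1e-4 * alpha * (g @ d):
                    break
                alpha *= 0.5
            else:
                alpha = 0.0
        if alpha == 0.0:
            set_flat_params(model, x)
            _trace_point(model, train_X, train_Y, test_X, test_idx, trace, lam)
            continue
        x_new = x + alpha * d
        f_new, g_new = objective(x_new, masks)
        s, yv = x_new - x, g_new - g
        if s @ yv > 1e-10:
            s_hist.append(s)
            y_hist.append(yv)
            if len(s_hist) > config.lbfgs_history:
                s_hist.pop(0)
                y_hist.pop(0)
        x = x_new
        set_flat_params(model, x)
        _trace_point(model, train_X, train_Y, test_X, test_idx, trace, lam)
    set_flat_params(model, x)
    return model, trace


def predict(model: MDBNModel, X: np.ndarray) -> list[str]:
    """Argmax class labels in inference mode (no mask sampling).

    Ties break toward the earliest class in ``class_order`` (argmax keeps
    the first maximal index).
    """
    spec = DropoutSpec(rate=model.dropout_rate, mode="inference")
    feats = forward(model.dbn, X, spec)
    probs = softmax_probs(model.softmax, feats)
    idx = probs.argmax(axis=1)
    order = model.class_order or [str(i) for i in range(model.softmax.n_classes)]
    return [order[i] for i in idx]


# ---------------------------------------------------------------------------
# Serialization: versioned NumPy container.
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: MDBNModel, path: str | Path) -> None:
    """Save an MDBNModel to a versioned ``.npz`` container."""
    arrays = {
        "format_version": np.array(_FORMAT_VERSION),
        "layer_sizes": np.array(model.dbn.layer_sizes),
        "dropout_rate": np.array(model.dropout_rate),
        "class_order": np.array(model.class_order, dtype=object),
        "softmax_weights": model.softmax.weights,
        "softmax_biases": model.softmax.biases,
    }
    for l, rbm in enumerate(model.dbn.rbms):
        arrays[f"rbm{l}_W"] = rbm.W
        arrays[f"rbm{l}_a"] = rbm.a
        arrays[f"rbm{l}_b"] = rbm.b
    if model.normalization is not None:
        arrays["norm_min"] = model.normalization.minimum
        arrays["norm_max"] = model.normalization.maximum
        arrays["norm_n"] = np.array(model.normalization.fitted_on_n)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> MDBNModel:
    """Load an MDBNModel saved by :func:`save_model`."""
    from .rbm import RBMParams

    with np.load(path, allow_pickle=True) as z:
        version = int(z["format_version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        layer_sizes = [int(s) for s in z["layer_sizes"]]
        rbms = [
            RBMParams(z[f"rbm{l}_W"], z[f"rbm{l}_a"], z[f"rbm{l}_b"])
            for l in range(len(layer_sizes) - 1)
        ]
        norm = None
        if "norm_min" in z:
            norm = NormalizationState(
                minimum=z["norm_min"],
                maximum=z["norm_max"],
                fitted_on_n=int(z["norm_n"]),
            )
        return MDBNModel(
            dbn=DBNModel(layer_sizes=layer_sizes, rbms=rbms),
            softmax=SoftmaxParams(z["softmax_weights"], z["softmax_biases"]),
            dropout_rate=float(z["dropout_rate"]),
            class_order=[str(c) for c in z["class_order"]],
            normalization=norm,
        )
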