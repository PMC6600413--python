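"""Metrics, cross-validation driver, baselines and comparison tables.

The evaluation protocol mirrors the study design: stratified k-fold
cross-validation (k = 5) in which, for every fold, the min-max normalizer is
fitted on the training fold only, the DBN is pretrained on the (unlabelled)
training inputs, the softmax head is fitted on frozen features, the whole
network is fine-tuned, and the held-out fold is scored.  Baseline
classifiers (SVM, KNN, and a one-hidden-layer perceptron, "BPNN") are called
off the shelf from scikit-learn on the same normalized folds.

Accuracies are reported as percentages rounded half-up to two decimals, and
a report's mean is the mean of the *rounded* per-fold accuracies, itself
rounded to two decimals — the same arithmetic the comparative tables use.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    FinetuneConfig,
    MDBNModel,
    TrainingTrace,
    finetune,
    predict,
    train_softmax_head,
)
from .data_io import (
    FoldPlan,
    PeakMatrix,
    apply_normalizer,
    fit_normalizer,
    one_hot,
    stratified_kfold,
)
from .dbn import DropoutSpec, forward, pretrain
from .rbm import CDConfig

__all__ = [
    "FoldResult",
    "CVReport",
    "MDBNSpec",
    "BaselineSpec",
    "ComparisonTable",
    "SizeSweepResult",
    "accuracy_percent",
    "mse_onehot",
    "round_half_up",
    "run_cv",
    "compare_models",
    "run_size_sweep",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def accuracy_percent(predicted: Sequence, true: Sequence) -> float:
    """Percentage of matching labels, rounded half-up to two decimals."""
    predicted = list(predicted)
    true = list(true)
    if len(predicted) == 0 or len(predicted) != len(true):
        raise ValueError("label vectors must be non-empty and of equal length")
    matches = sum(p == t for p, t in zip(predicted, true))
    return round_half_up(100.0 * matches / len(true))


def mse_onehot(probs: np.ndarray, Y: np.ndarray) -> float:
    """Mean over all entries of squared differences to the one-hot targets."""
    probs = np.asarray(probs, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if probs.shape != Y.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {Y.shape}")
    return float(np.mean((probs - Y) ** 2))


@dataclass
class FoldResult:
    fold_index: int
    accuracy_percent: float
    n_train: int
    n_test: int
    trace: TrainingTrace | None = None


@dataclass
class CVReport:
    """Per-fold accuracies and their mean for one model.

    The mean is the arithmetic mean of per-fold accuracies, each first
    rounded to two decimals, then itself rounded to two decimals.
    """

    model_name: str
    fold_results: list[FoldResult]
    config_fingerprint: str = ""
    fold_fingerprint: str = ""

    @property
    def fold_accuracies(self) -> list[float]:
        return [f.accuracy_percent for f in self.fold_results]

    @property
    def mean_accuracy_percent(self) -> float:
        rounded = [round_half_up(a) for a in self.fold_accuracies]
        return round_half_up(float(np.mean(rounded)))

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "config_fingerprint": self.config_fingerprint,
            "fold_fingerprint": self.fold_fingerprint,
            "folds": [
                {
                    "fold": f.fold_index,
                    "accuracy_percent": f.accuracy_percent,
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                }
                for f in self.fold_results
            ],
            "mean_accuracy_percent": self.mean_accuracy_percent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass(frozen=True)
class MDBNSpec:
    """Configuration of one MDBN run inside the evaluation harness."""

    hidden_sizes: tuple[int, ...] = (500, 100)
    pretrain_epochs: int = 500
    pretrain_learning_rate: float = 0.1
    pretrain_dropout: float = 0.2
    finetune_method: str = "lbfgs"
    finetune_iterations: int = 300
    finetune_learning_rate: float = 0.1
    finetune_dropout: float = 0.5
    weight_decay: float = 1e-4
    head_iterations: int = 200
    weight_init_scale: float = 0.01
    name: str | None = None

    @property
    def model_name(self) -> str:
        if self.name:
            return self.name
        return f"MDBN-{self.finetune_method.upper()}"

    def fingerprint_payload(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class BaselineSpec:
    """Off-the-shelf baseline: ``kind`` in {svm, knn, bpnn} + hyperparameters."""

    kind: str
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "knn", "bpnn"):
            raise ValueError(f"unrecognized baseline kind {self.kind!r}")

    @property
    def model_name(self) -> str:
        return {"svm": "SVM", "knn": "KNN", "bpnn": "BPNN"}[self.kind]

    def build(self, seed: int):
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.neural_network import MLPClassifier
        from sklearn.svm import SVC

        hp = dict(self.hyperparameters)
        if self.kind == "svm":
            return SVC(C=hp.get("C", 1.0), kernel=hp.get("kernel", "rbf"),
                       gamma=hp.get("gamma", "scale"))
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (100,)),
            max_iter=hp.get("max_iter", 500),
            random_state=seed,
        )

    def fingerprint_payload(self) -> dict:
        return {"kind": self.kind, "hyperparameters": dict(self.hyperparameters)}


def _derived_seed(seed: int, *offsets: int) -> int:
    mix = hashlib.sha256(
        json.dumps([int(seed), *map(int, offsets)]).encode()
    ).digest()
    return int.from_bytes(mix[:4], "big") % (2**31)


def _fit_mdbn_fold(
    spec: MDBNSpec,
    train: PeakMatrix,
    test: PeakMatrix,
    class_order: list[str],
    seed: int,
) -> tuple[MDBNModel, TrainingTrace]:
    """Fit one normalized train/test split with the full MDBN protocol."""
    state = fit_normalizer(train)
    train_n = apply_normalizer(state, train)
    test_n = apply_normalizer(state, test)
    train_Y = one_hot(train_n.labels, class_order)
    test_Y = one_hot(test_n.labels, class_order)

    layer_sizes = [train_n.n_variables, *spec.hidden_sizes]
    cd_cfg = CDConfig(
        learning_rate=spec.pretrain_learning_rate,
        epochs=spec.pretrain_epochs,
        dropout_rate=spec.pretrain_dropout,
        seed=_derived_seed(seed, 1),
        weight_init_scale=spec.weight_init_scale,
    )
    dbn = pretrain(train_n.intensities, layer_sizes, cd_cfg)

    # Head fitted on inference-mode features (scaled by 1 - dropout rate) so
    # the initialization matches the prediction-time feature distribution.
    feats = forward(
        dbn, train_n.intensities,
        DropoutSpec(rate=spec.finetune_dropout, mode="inference"),
    )
    head = train_softmax_head(
        feats, train_Y,
        weight_decay=spec.weight_decay,
        iterations=spec.head_iterations,
        seed=_derived_seed(seed, 2),
    )
    model = MDBNModel(
        dbn=dbn,
        softmax=head,
        dropout_rate=spec.finetune_dropout,
        class_order=class_order,
        normalization=state,
    )
    ft_cfg = FinetuneConfig(
        method=spec.finetune_method,
        iterations=spec.finetune_iterations,
        learning_rate=spec.finetune_learning_rate,
        weight_decay=spec.weight_decay,
        seed=_derived_seed(seed, 3),
    )
    model, trace = finetune(
        model,
        train_n.intensities,
        train_Y,
        test_n.intensities,
        test_Y,
        ft_cfg,
    )
    return model, trace


def _spec_fingerprint(spec, k: int, seed: int) -> str:
    raw = json.dumps(
        {"spec": spec.fingerprint_payload(), "k": k, "seed": seed},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(raw.encode()).hexdigest()[:16]


def run_cv(
    data: PeakMatrix,
    model_spec: MDBNSpec | BaselineSpec,
    k: int = 5,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of one model on a labelled matrix.

    For each fold, everything (normalization, pretraining, head fit,
    fine-tuning / baseline fit) uses only the training fold; the held-out
    fold is scored with :func:`accuracy_percent`.  Supplying a shared
    ``fold_plan`` lets several models be compared on identical folds.
    """
    if data.labels is None:
        raise ValueError("cross-validation requires labelled data")
    plan = fold_plan or stratified_kfold(data.labels, k, seed)
    class_order = sorted(set(data.labels))
    results: list[FoldResult] = []
    for fold_index, test_idx in enumerate(plan.folds):
        train_idx = plan.train_indices(fold_index)
        train, test = data.subset(train_idx), data.subset(test_idx)
        trace = None
        if isinstance(model_spec, MDBNSpec):
            model, trace = _fit_mdbn_fold(
                model_spec, train, test, class_order,
                _derived_seed(seed, 10, fold_index),
            )
            state = model.normalization
            predicted = predict(model, apply_normalizer(state, test).intensities)
        else:
            state = fit_normalizer(train)
            clf = model_spec.build(_derived_seed(seed, 10, fold_index))
            clf.fit(apply_normalizer(state, train).intensities, train.labels)
            predicted = list(clf.predict(apply_normalizer(state, test).intensities))
        results.append(
            FoldResult(
                fold_index=fold_index,
                accuracy_percent=accuracy_percent(predicted, test.labels),
                n_train=len(train_idx),
                n_test=len(test_idx),
                trace=trace,
            )
        )
    return CVReport(
        model_name=model_spec.model_name,
        fold_results=results,
        config_fingerprint=_spec_fingerprint(model_spec, plan.k, seed),
        fold_fingerprint=plan.fingerprint(),
    )


@dataclass
class ComparisonTable:
    """Fold-by-model accuracy table with the best value per row flagged."""

    table: pd.DataFrame
    best: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_json(self) -> str:
        payload = {
            "accuracies": {
                str(r): {c: self.table.loc[r, c] for c in self.table.columns}
                for r in self.table.index
            },
            "best": {
                str(r): [c for c in self.best.columns if self.best.loc[r, c]]
                for r in self.best.index
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def compare_models(reports: Sequence[CVReport]) -> ComparisonTable:
    """Assemble fold-by-model accuracies; reports must share one fold plan."""
    if not reports:
        raise ValueError("need at least one report")
    fingerprints = {r.fold_fingerprint for r in reports}
    if len(fingerprints) > 1:
        raise ValueError("reports were computed on different fold plans")
    n_folds = len(reports[0].fold_results)
    index = [str(i + 1) for i in range(n_folds)] + ["Mean"]
    table = pd.DataFrame(index=index)
    for rep in reports:
        col = [round_half_up(a) for a in rep.fold_accuracies]
        table[rep.model_name] = col + [rep.mean_accuracy_percent]
    best = table.eq(table.max(axis=1), axis=0)
    return ComparisonTable(table=table, best=best)


@dataclass
class SizeSweepResult:
    """Accuracy-vs-training-size table plus retained fine-tuning traces."""

    table: pd.DataFrame
    traces: dict[tuple[str, int], TrainingTrace] = field(default_factory=dict)


def run_size_sweep(
    data: PeakMatrix,
    model_specs: Sequence[MDBNSpec | BaselineSpec],
    train_sizes: Sequence[int],
    seed: int = 0,
) -> SizeSweepResult:
    """Train each model once per stratified train/test split size.

    Each requested training-set size produces one stratified random split
    (the remaining samples form the test set); every model is fitted on that
    split and its test accuracy recorded, with MDBN misclassification-rate
    traces retained.
    """
    from sklearn.model_selection import train_test_split

    if data.labels is None:
        raise ValueError("size sweep requires labelled data")
    class_order = sorted(set(data.labels))
    n = data.n_samples
    rows = []
    traces: dict[tuple[str, int], TrainingTrace] = {}
    for size in train_sizes:
        size = int(size)
        if not len(class_order) <= size < n:
            raise ValueError(
                f"training size {size} invalid for {n} samples and "
                f"{len(class_order)} classes"
            )
        idx_train, idx_test = train_test_split(
            np.arange(n),
            train_size=size,
            stratify=data.labels,
            random_state=_derived_seed(seed, 20, size),
        )
        train, test = data.subset(idx_train), data.subset(idx_test)
        row: dict[str, object] = {"training_set": size, "test_set": n - size}
        for spec in model_specs:
            run_seed = _derived_seed(seed, 21, size)
            if isinstance(spec, MDBNSpec):
                model, trace = _fit_mdbn_fold(
                    spec, train, test, class_order, run_seed
                )
                predicted = predict(
                    model,
                    apply_normalizer(model.normalization, test).intensities,
                )
                traces[(spec.model_name, size)] = trace
            else:
                state = fit_normalizer(train)
                clf = spec.build(run_seed)
                clf.fit(apply_normalizer(state, train).intensities, train.labels)
                predicted = list(
                    clf.predict(apply_normalizer(state, test).intensities)
                )
            row[spec.model_name] = accuracy_percent(predicted, test.labels)
        rows.append(row)
    return SizeSweepResult(table=pd.DataFrame(rows), traces=traces)
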