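"""Peak-matrix I/O, unit-interval normalization and stratified fold plans.

A *peak matrix* is the aligned sample x (m/z, retention-time) feature table
produced from LC-MS runs: rows are samples, columns are aligned features,
entries are non-negative intensities.  Group labels (e.g. CG / MG / RG for
control, disease-model and treatment animals) may accompany the samples.

Intensities are scaled per variable to [0, 1] with min-max statistics fitted
on training samples only, because the downstream networks treat visible units
as unit-interval valued.  Cross-validation fold plans are stratified so every
fold reflects the class balance of the full cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mdbn")

__all__ = [
    "PeakMatrix",
    "NormalizationState",
    "FoldPlan",
    "PeakMatrixParseError",
    "read_peak_matrix",
    "write_peak_matrix",
    "fit_normalizer",
    "apply_normalizer",
    "stratified_kfold",
    "one_hot",
]


class PeakMatrixParseError(ValueError):
    """Raised when a delimited peak-matrix file violates the format contract."""


@dataclass
class PeakMatrix:
    """Sample x variable intensity table with identifiers and optional labels.

    Parameters
    ----------
    intensities
        ``(n_samples, n_variables)`` array of non-negative, finite reals.
    sample_ids
        Unique sample identifiers, one per row.
    variable_ids
        Unique variable identifiers (m/z_RT tokens), one per column.
    labels
        Optional categorical group label per sample.
    """

    intensities: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        n, d = self.intensities.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} intensity rows"
            )
        if len(self.variable_ids) != d:
            raise ValueError(
                f"{len(self.variable_ids)} variable ids for {d} intensity columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.variable_ids)) != d:
            raise ValueError("variable ids must be unique")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite (impute missing cells first)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError(f"{len(self.labels)} labels for {n} samples")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    def subset(self, rows: Sequence[int]) -> "PeakMatrix":
        """Return a new PeakMatrix restricted to the given sample rows."""
        rows = np.asarray(rows, dtype=int)
        return PeakMatrix(
            intensities=self.intensities[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            variable_ids=list(self.variable_ids),
            labels=None if self.labels is None else [self.labels[i] for i in rows],
        )


@dataclass
class NormalizationState:
    """Per-variable min-max statistics fitted on a training set."""

    minimum: np.ndarray
    maximum: np.ndarray
    fitted_on_n: int

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape or self.minimum.ndim != 1:
            raise ValueError("minimum and maximum must be 1-D vectors of equal length")
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum elementwise")


@dataclass
class FoldPlan:
    """Partition of sample indices into k stratified cross-validation folds."""

    k: int
    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        self.folds = [np.asarray(f, dtype=int) for f in self.folds]
        if len(self.folds) != self.k:
            raise ValueError(f"expected {self.k} folds, got {len(self.folds)}")
        all_idx = np.concatenate(self.folds) if self.folds else np.array([], dtype=int)
        if len(set(all_idx.tolist())) != len(all_idx):
            raise ValueError("folds must be pairwise disjoint")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    @property
    def n_samples(self) -> int:
        return sum(len(f) for f in self.folds)

    def train_indices(self, fold_index: int) -> np.ndarray:
        """All sample indices outside the given fold, in ascending order."""
        test = set(self.folds[fold_index].tolist())
        return np.array(
            [i for i in range(self.n_samples) if i not in test], dtype=int
        )

    def to_json(self, sample_ids: Sequence[str] | None = None) -> str:
        """Serialize as JSON mapping fold index -> sample IDs (or indices)."""
        payload = {
            "k": self.k,
            "seed": self.seed,
            "folds": {
                str(i): (
                    [sample_ids[j] for j in f] if sample_ids is not None
                    else f.tolist()
                )
                for i, f in enumerate(self.folds)
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def fingerprint(self) -> str:
        import hashlib

        raw = json.dumps(
            {"k": self.k, "seed": self.seed, "folds": [f.tolist() for f in self.folds]},
            sort_keys=True,
        )
        return hashlib.sha256(raw.encode()).hexdigest()[:16]


def read_peak_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    label_column: str | None = None,
    label_set: Sequence[str] | None = None,
) -> PeakMatrix:
    """Read a delimited peak matrix (CSV or TSV) into a :class:`PeakMatrix`.

    The file must have a header row of variable IDs and a first column of
    sample IDs.  ``orientation="samples_in_columns"`` transposes on load so
    the result is always samples-in-rows.  Missing cells are imputed to 0
    (peak absent) and the imputation count is logged.

    Parameters
    ----------
    path
        CSV (``.csv``) or TSV (``.tsv``/``.txt``) file.
    orientation
        ``samples_in_rows`` or ``samples_in_columns``.
    label_column
        Name of the column (after orientation normalization) holding group
        labels; it is removed from the variables.
    label_set
        If given, labels outside this set raise :class:`PeakMatrixParseError`.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "samples_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise PeakMatrixParseError(
                f"duplicate column ID {name!r} in header of {path}"
            )
        seen.add(name)
    try:
        frame = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PeakMatrixParseError(f"could not parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise PeakMatrixParseError(f"duplicate row ID {dup!r} in {path}")
    if orientation == "samples_in_columns":
        frame = frame.T

    labels: list[str] | None = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise PeakMatrixParseError(
                f"label column {label_column!r} not found in {path}"
            )
        raw_labels = frame[label_column]
        if raw_labels.isna().any():
            row = raw_labels.index[raw_labels.isna()][0]
            raise PeakMatrixParseError(f"missing label for sample {row!r}")
        labels = [str(v) for v in raw_labels]
        if label_set is not None:
            allowed = set(map(str, label_set))
            for sid, lab in zip(frame.index, labels):
                if lab not in allowed:
                    raise PeakMatrixParseError(
                        f"label {lab!r} of sample {sid!r} outside declared set "
                        f"{sorted(allowed)}"
                    )
        frame = frame.drop(columns=[label_column])

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise PeakMatrixParseError(
            f"non-numeric intensity at sample {frame.index[r]!r}, "
            f"variable {frame.columns[c]!r}"
        )
    n_missing = int(numeric.isna().values.sum())
    if n_missing:
        logger.info("imputed %d missing cell(s) to 0 while reading %s", n_missing, path)
        numeric = numeric.fillna(0.0)
    values = numeric.values.astype(float)
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise PeakMatrixParseError(
            f"negative intensity at sample {frame.index[r]!r}, "
            f"variable {frame.columns[c]!r}"
        )
    return PeakMatrix(
        intensities=values,
        sample_ids=[str(s) for s in frame.index],
        variable_ids=[str(c) for c in frame.columns],
        labels=labels,
    )


def write_peak_matrix(
    matrix: PeakMatrix, path: str | Path, label_column: str = "group"
) -> None:
    """Write a PeakMatrix as delimited text (CSV or TSV chosen by suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    frame = pd.DataFrame(
        matrix.intensities, index=matrix.sample_ids, columns=matrix.variable_ids
    )
    if matrix.labels is not None:
        frame.insert(0, label_column, matrix.labels)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep)


def fit_normalizer(train: PeakMatrix) -> NormalizationState:
    """Fit per-variable min-max statistics on training samples only."""
    if train.n_samples < 1:
        raise ValueError("cannot fit a normalizer on an empty matrix")
    return NormalizationState(
        minimum=train.intensities.min(axis=0),
        maximum=train.intensities.max(axis=0),
        fitted_on_n=train.n_samples,
    )


def apply_normalizer(state: NormalizationState, data: PeakMatrix) -> PeakMatrix:
    """Scale each variable to [0, 1] using fitted extremes, clipping overshoot.

    Values map to ``(x - min_j) / (max_j - min_j)`` and are clipped to [0, 1];
    constant training variables (``max_j == min_j``) map to 0.
    """
    if data.n_variables != state.minimum.shape[0]:
        raise ValueError(
            f"normalizer fitted on {state.minimum.shape[0]} variables, "
            f"data has {data.n_variables}"
        )
    span = state.maximum - state.minimum
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (data.intensities - state.minimum) / span
    scaled = np.where(span == 0, 0.0, scaled)
    scaled = np.clip(scaled, 0.0, 1.0)
    return PeakMatrix(
        intensities=scaled,
        sample_ids=list(data.sample_ids),
        variable_ids=list(data.variable_ids),
        labels=None if data.labels is None else list(data.labels),
    )


def stratified_kfold(labels: Sequence[str], k: int, seed: int) -> FoldPlan:
    """Partition samples into k stratified folds, deterministically.

    Within each class (taken in sorted order) members are shuffled with the
    seeded generator and dealt cyclically into folds.  The starting fold
    advances across classes so that both per-class counts and total fold
    sizes differ by at most one, with remainders landing in the earliest
    folds.  For 56/56/56 samples and k=5 this yields fold sizes
    {34, 34, 34, 33, 33}.
    """
    labels = [str(l) for l in labels]
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = sorted(set(labels))
    by_class = {c: [i for i, l in enumerate(labels) if l == c] for c in classes}
    for c in classes:
        if len(by_class[c]) < k:
            raise ValueError(
                f"class {c!r} has only {len(by_class[c])} member(s); needs >= {k}"
            )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for c in classes:
        members = np.array(by_class[c], dtype=int)
        rng.shuffle(members)
        for idx in members:
            folds[cursor % k].append(int(idx))
            cursor += 1
    return FoldPlan(k=k, folds=[np.array(sorted(f), dtype=int) for f in folds], seed=seed)


def one_hot(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """Encode labels as an ``(n, k)`` 0/1 matrix following ``class_order``."""
    class_order = [str(c) for c in class_order]
    index = {c: j for j, c in enumerate(class_order)}
    out = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        lab = str(lab)
        if lab not in index:
            raise ValueError(f"label {lab!r} not in class order {class_order}")
        out[i, index[lab]] = 1.0
    return out
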