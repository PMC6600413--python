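"""Shared fixtures: tiny peak matrices and small pre-built models."""

from __future__ import annotations

import numpy as np
import pytest

from mdbn import (
    DBNModel,
    MDBNModel,
    PeakMatrix,
    RBMParams,
    SoftmaxParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 variables with labels, for I/O round-trips."""
    return PeakMatrix(
        intensities=np.array([[1.5, 0.0], [2.25, 3.0], [0.5, 7.125]]),
        sample_ids=["s1", "s2", "s3"],
        variable_ids=["100.0001_1.00", "200.0002_2.00"],
        labels=["CG", "MG", "RG"],
    )


def make_small_model(
    arch=(5, 4, 3), k=2, dropout=0.0, seed=0, scale=0.5
) -> MDBNModel:
    """Random small MDBN for gradient and prediction tests."""
    r = np.random.default_rng(seed)
    rbms = [
        RBMParams(
            W=r.normal(0, scale, (arch[i], arch[i + 1])),
            a=np.zeros(arch[i]),
            b=r.normal(0, 0.2, arch[i + 1]),
        )
        for i in range(len(arch) - 1)
    ]
    return MDBNModel(
        dbn=DBNModel(layer_sizes=list(arch), rbms=rbms),
        softmax=SoftmaxParams(
            weights=r.normal(0, scale, (k, arch[-1])),
            biases=r.normal(0, 0.2, k),
        ),
        dropout_rate=dropout,
        class_order=[chr(ord("A") + i) for i in range(k)],
    )


@pytest.fixture
def small_model():
    return make_small_model()
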