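"""Synthetic metabolomic peak matrices with planted group structure.

Generates sample x variable intensity tables that mimic aligned LC-MS peak
tables: non-negative, right-skewed (log-normal) intensities, a configurable
fraction of absent peaks (exact zeros), and three balanced groups — control
(CG), disease model (MG) and treatment (RG) — in which the treatment group
sits between control and model.  Informative variables carry a log-scale
mean shift between CG and MG; RG receives ``(1 - treatment_recovery)`` of
that shift, so ``treatment_recovery = 1`` restores the control profile
exactly.  A configurable fraction of informative variables expresses its
effect through the product of two per-sample latent factors instead of
additively, giving the classifier a nonlinear signal component.

This module is explicitly a stand-in for real acquisitions: it plants the
ground truth it reports, and every draw is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import PeakMatrix

__all__ = [
    "SyntheticConfig",
    "generate",
    "generate_negative_mode",
    "planted_truth",
]

CLASS_NAMES = ("CG", "MG", "RG")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Attributes
    ----------
    n_per_class
        Samples per group (three balanced groups).
    n_variables
        Total aligned peak variables (positive-mode table width by default).
    n_informative
        Variables carrying a planted class effect.
    effect_size
        Log-scale mean shift between CG and MG on informative variables.
    treatment_recovery
        Fraction of the CG-MG shift removed in RG
        (RG mean = CG mean + (1 - recovery) * effect).
    sparsity
        Independent probability that an entry is zeroed (peak absent).
    noise_sd
        Standard deviation of the additive log-scale (multiplicative
        intensity) noise; 0.3 corresponds to roughly 30% coefficient of
        variation, typical of serum LC-MS peak areas passing QC.
    nonlinear_fraction
        Fraction of informative variables whose effect is modulated by the
        product of two per-sample latent factors.
    seed
        Seed; the generated matrix is bit-identical for equal configs.
    """

    n_per_class: int = 56
    n_variables: int = 2889
    n_informative: int = 60
    effect_size: float = 2.0
    treatment_recovery: float = 0.6
    sparsity: float = 0.4
    noise_sd: float = 0.3
    nonlinear_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_variables < 1:
            raise ValueError("n_per_class and n_variables must be >= 1")
        if not 0 <= self.n_informative <= self.n_variables:
            raise ValueError("n_informative must lie in [0, n_variables]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.treatment_recovery <= 1:
            raise ValueError("treatment_recovery must lie in [0, 1]")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.nonlinear_fraction <= 1:
            raise ValueError("nonlinear_fraction must lie in [0, 1]")


def _class_shifts(config: SyntheticConfig) -> dict[str, float]:
    """Log-scale shift applied to informative variables per class."""
    return {
        "CG": 0.0,
        "MG": config.effect_size,
        "RG": (1.0 - config.treatment_recovery) * config.effect_size,
    }


def _plan(config: SyntheticConfig, rng: np.random.Generator):
    """Draw the per-dataset structure: baselines and informative sets."""
    baseline = rng.normal(5.0, 1.0, size=config.n_variables)
    informative = np.sort(
        rng.choice(config.n_variables, size=config.n_informative, replace=False)
    )
    n_nonlinear = int(round(config.nonlinear_fraction * config.n_informative))
    shuffled = rng.permutation(informative)
    nonlinear = np.sort(shuffled[:n_nonlinear])
    return baseline, informative, nonlinear


def generate(config: SyntheticConfig) -> PeakMatrix:
    """Generate a labelled peak matrix with the configured planted structure."""
    rng = np.random.default_rng(config.seed)
    baseline, informative, nonlinear = _plan(config, rng)
    n = 3 * config.n_per_class
    d = config.n_variables
    shifts = _class_shifts(config)
    labels = [c for c in CLASS_NAMES for _ in range(config.n_per_class)]

    log_x = np.tile(baseline, (n, 1))
    # Per-sample latent factors modulating the nonlinear effect component.
    u = rng.normal(1.0, 0.2, size=n)
    w = rng.normal(1.0, 0.2, size=n)
    nonlinear_set = set(nonlinear.tolist())
    additive = np.array(
        [j for j in informative if j not in nonlinear_set], dtype=int
    )
    shift_per_sample = np.array([shifts[l] for l in labels])
    if additive.size:
        log_x[:, additive] += shift_per_sample[:, None]
    if nonlinear.size:
        log_x[:, nonlinear] += (shift_per_sample * u * w)[:, None]
    log_x += rng.normal(0.0, config.noise_sd, size=(n, d))
    x = np.exp(log_x)
    if config.sparsity > 0:
        x *= rng.random((n, d)) >= config.sparsity

    sample_ids = [
        f"{labels[i]}_{(i % config.n_per_class) + 1:03d}" for i in range(n)
    ]
    # Deterministic m/z_RT-style tokens, unique by construction.
    variable_ids = [
        f"{50.0 + 0.37 * j:.4f}_{0.5 + (9.5 * j) / max(d - 1, 1):.3f}"
        for j in range(d)
    ]
    return PeakMatrix(
        intensities=x,
        sample_ids=sample_ids,
        variable_ids=variable_ids,
        labels=labels,
    )


def generate_negative_mode(**overrides) -> PeakMatrix:
    """Generate a negative-ion-mode-sized table (353 variables by default)."""
    config = SyntheticConfig(n_variables=353, **{
        k: v for k, v in overrides.items() if k != "n_variables"
    })
    if "n_variables" in overrides:
        config = replace(config, n_variables=overrides["n_variables"])
    return generate(config)


def planted_truth(config: SyntheticConfig, generated: PeakMatrix) -> dict:
    """Ground truth behind a generated matrix, for recovery tests.

    Verifies (by regeneration) that ``generated`` was produced by this module
    under ``config``, then reports the planted informative variable indices,
    the nonlinear subset, and the expected per-class log-scale means on the
    informative variables.
    """
    reference = generate(config)
    if (
        reference.intensities.shape != generated.intensities.shape
        or not np.array_equal(reference.intensities, generated.intensities)
    ):
        raise ValueError("matrix does not match this config (fingerprint mismatch)")
    rng = np.random.default_rng(config.seed)
    baseline, informative, nonlinear = _plan(config, rng)
    shifts = _class_shifts(config)
    return {
        "informative_indices": informative.tolist(),
        "nonlinear_indices": nonlinear.tolist(),
        "class_log_means": {
            c: (baseline[informative] + shifts[c]).tolist() for c in CLASS_NAMES
        },
        "class_shifts": shifts,
    }
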