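# mdbn — deep belief networks for metabolomic peak matrices

`mdbn` classifies high-dimensional, sparse metabolomic peak-intensity
tables — the sample × (m/z, retention-time) matrices produced by LC-MS
profiling — into experimental groups such as control (CG), disease model
(MG) and treatment (RG). It is aimed at metabolomics researchers who want a
nonlinear classifier for small-cohort, wide feature tables where classical
methods (SVM, KNN, shallow perceptrons) struggle, together with a
reproducible cross-validation harness to compare against exactly those
baselines.

## The model

The core is a **deep belief network (DBN) with a softmax regression head**,
trained in two phases.

**Unsupervised pretraining.** Adjacent layers form restricted Boltzmann
machines (RBMs). An RBM over visible units *v* (length *n*) and hidden
units *h* (length *m*) has energy

    E(v, h | θ) = − Σᵢ aᵢvᵢ − Σⱼ bⱼhⱼ − Σᵢⱼ vᵢ Wᵢⱼ hⱼ,   θ = {W, a, b}

with P(v, h) ∝ e^(−E) and factorized conditionals
P(hⱼ=1 | v) = δ(bⱼ + v·W₍·ⱼ₎), where δ(x) = 1/(1+e^(−x)). Each RBM is
trained by contrastive divergence with one Gibbs reconstruction (CD-1):

    ΔWᵢⱼ = ε (⟨vᵢhⱼ⟩_data − ⟨vᵢhⱼ⟩_recon)
    Δaᵢ  = ε (⟨vᵢ⟩_data − ⟨vᵢ⟩_recon)
    Δbⱼ  = ε (⟨hⱼ⟩_data − ⟨hⱼ⟩_recon)

full-batch, with the hidden probabilities of each trained RBM feeding the
next one. Intensities are min-max scaled to [0, 1] per variable (fitted on
training folds only) so visible units are unit-interval valued.

**Supervised fine-tuning.** A softmax head is first fitted on the frozen
top-layer features, then all weights are optimized jointly on the labelled
data under the cost

    J = −(1/N) Σₛ Σ_c Y_sc log P_sc + (λ/2) Σ‖W‖²

by either plain full-batch gradient descent (GD) or L-BFGS. Dropout
(Bernoulli 0/1 masks on hidden layers, resampled each epoch/iteration;
activations scaled by 1 − rate at inference) regularizes both phases.
Per-iteration traces record the fine-tuning mean squared error (FMSE), the
training misclassification rate (FMR) and the test misclassification rate
(TMR).

Evaluation follows a stratified five-fold cross-validation protocol: for a
balanced 168-sample cohort (56 per group), folds split 134/34, accuracies
are reported as percentages rounded half-up to two decimals, and the mean
row of a comparison table is the mean of the rounded per-fold values.

A synthetic peak-matrix generator (`mdbn.synthetic`) plants a known
three-group structure — log-normal intensities, a log-scale CG→MG shift on
a chosen set of informative variables, a treatment group placed between
control and model, multiplicative noise, and random peak absences — so the
whole pipeline is testable without any proprietary acquisition.

## Worked example

Five-fold cross-validation of the DBN+softmax classifier against SVM and
KNN baselines on a generated 168 × 300 peak matrix with a planted
2-log-unit disease effect and 60% treatment recovery:

```python
from mdbn import SyntheticConfig, generate, run_cv
from mdbn.evaluation import MDBNSpec, BaselineSpec, compare_models

data = generate(SyntheticConfig(n_variables=300, seed=0))
mdbn = MDBNSpec(
    hidden_sizes=(100, 20), pretrain_epochs=100,
    finetune_method="lbfgs", finetune_iterations=300,
)
reports = [
    run_cv(data, spec, k=5, seed=0)
    for spec in (mdbn, BaselineSpec(kind="svm"), BaselineSpec(kind="knn"))
]
print(compare_models(reports).table)
```

which prints

```
      MDBN-LBFGS    SVM    KNN
1          88.24  76.47  52.94
2          88.24  70.59  64.71
3          82.35  70.59  50.00
4          81.82  72.73  45.45
5          93.94  75.76  39.39
Mean       86.92  73.23  50.50
```

Rows are test folds (sizes 34/34/34/33/33, so per-fold accuracies are
multiples of 1/34 or 1/33); the Mean row averages the rounded fold values.
The pretrained-and-fine-tuned network clearly separates the three groups
where the distance-based baselines degrade under the table's 40% random
peak absences. GD fine-tuning at its 5000-iteration budget
(`finetune_method="gd"`) typically scores a few points higher still at this
width; see `docs/methods.md` for why.

## Command line

```bash
mdbn simulate  --out runs/sim --seed 1 --n-per-class 5 --n-variables 20 --n-informative 6
mdbn crossval  --preset smoke --out runs/cv --seed 1 --k 3 --baselines knn
mdbn report    --run-dir runs/cv --plot
```

`crossval` writes per-model CV reports (JSON), per-fold FMSE/FMR/TMR trace
CSVs, a fold plan, a comparison table and a resolved-config snapshot that
reproduces the run bit-for-bit. Presets `positive` (2889-500-100-3, 500 CD
epochs per RBM, L-BFGS cap 300 / GD cap 5000) and `negative`
(353-100-20-3, 100 CD epochs, 300 fine-tuning iterations) encode the two
study protocols; `smoke` is a seconds-scale sanity configuration.
`size-sweep` trains on increasing training-set sizes (default 50…120 of
168) and tabulates accuracy against size.

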