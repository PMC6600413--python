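# Methods

This note documents the model, the conventions chosen where the method
leaves them open, the synthetic-data generator and its limits, and the
numerical details that matter for reproducing results.

## Model and training protocol

The classifier is a sigmoid feed-forward network initialized by greedy RBM
pretraining and finished by supervised fine-tuning.

**RBM energy and conditionals.** Each adjacent pair of layers is a binary
RBM with energy E(v, h) = −aᵀv − bᵀh − vᵀWh and conditionals
P(hⱼ=1|v) = δ(bⱼ + v·W₍·ⱼ₎), P(vᵢ=1|h) = δ(aᵢ + Wᵢ·ⱼhⱼ summed over j). Visible units are
treated as unit-interval valued: min-max-normalized intensities enter the
positive phase directly rather than being binarized. This matches the
sigmoid-unit formulation and avoids discarding intensity information;
Gaussian visible units are deliberately out of scope.

**CD-1 conventions.** The contrastive-divergence phases are the standard
low-variance recipe: hidden probabilities on the data, *binary sampled*
hidden states driving the reconstruction, visible *probabilities* (not
samples) as the reconstruction, and hidden *probabilities* in the negative
association. Associations are batch means; updates are full-batch (the
training protocol uses no mini-batches, though `CDConfig.batch_size`
enables them). Weights start from N(0, 0.01²); biases start at zero.

**Greedy stacking.** Layer *l* trains on the hidden probabilities
(mean-field activations) of layer *l−1*, so layer inputs are deterministic
given the seed and each layer depends only on the layers below it.

**Dropout.** During training, each hidden layer's output is multiplied by a
fresh Bernoulli(1 − rate) 0/1 mask — one mask per epoch during pretraining
(shared across the batch), one per iteration during fine-tuning (per
sample). At inference no units are dropped and activations are scaled by
1 − rate, preserving expected pre-activations layer by layer. Defaults:
0.2 while pretraining, 0.5 while fine-tuning, none on the input layer; the
rates were unstated in the protocol and are configurable.

**Cost and gradient.** Fine-tuning minimizes mean multiclass cross-entropy
plus (λ/2)·Σ‖W‖² over all layer weights and softmax weights (biases are
not decayed), λ = 1e-4 by default. The gradient is exact backpropagation
through the sigmoid layers and, when masks are supplied, through the fixed
masks — which makes finite-difference checks well-posed. Parameters
flatten in a fixed documented order: layer-1 weights, layer-1 hidden
biases, …, softmax weights, softmax biases.

**Head initialization.** Before joint fine-tuning, the softmax head is
fitted (scipy L-BFGS-B, 200 iterations by default) on the *frozen* DBN
features, taken in inference mode — i.e. scaled by 1 − rate — so the
head's starting point matches the feature distribution it will see at
prediction time.

**Optimizers.** `gd` is plain full-batch gradient descent with a fixed
step (default 0.1, no momentum). `lbfgs` is a limited-memory quasi-Newton
iteration written for this package: two-loop recursion with 20 stored
pairs, strong-Wolfe line search (c₁ = 1e-4, c₂ = 0.9) with an Armijo
backtracking fallback, curvature pairs skipped when sᵀy ≤ 1e-10, and a
steepest-descent restart whenever the proposed direction is not a descent
direction. A hand-rolled driver (rather than `scipy.optimize.minimize`) is
used because dropout masks must be resampled at every iteration while
staying fixed *within* an iteration's line search, and because FMSE / FMR /
TMR traces are recorded after every iteration; both requirements sit
outside the scipy driver's contract. Iteration budgets default to the
protocol's: 300 for L-BFGS, 5000 for GD. Gradient-sup-norm tolerance
1e-6 stops either method early.

**Traces.** After each fine-tuning iteration the model is evaluated in
inference mode: FMSE (mean squared error of predicted probabilities
against one-hot targets) and FMR on training data, TMR on test data, plus
the deterministic training objective. Test labels feed only the TMR
bookkeeping, never the updates.

## Data handling

**Normalization.** Per-variable min-max scaling to [0, 1], fitted on
training folds only and applied to held-out folds with clipping; constant
variables map to 0. Min-max was chosen (the upstream preprocessing is
otherwise unspecified) because the RBM visible layer is unit-interval
valued; fitting on training folds only prevents test-set leakage.

**Missing cells** are imputed to 0 (peak absent) at load time and counted
in the log.

**Fold plans.** Stratified k-fold: within each class (sorted order),
members are shuffled with the seeded generator and dealt cyclically into
folds, with the starting fold advancing across classes. Both per-class
counts and total fold sizes differ by at most one, and remainders land in
the earliest folds; 56/56/56 with k = 5 gives sizes {34, 34, 34, 33, 33}
and train/test splits of 134/34 or 135/33. (A uniform 134/34 split for all
five folds of 168 samples is arithmetically impossible; the near-equal
plan is used without claiming exact fidelity to any particular historical
split.)

**Reported accuracies** are percentages rounded half-up to two decimals;
a cross-validation mean is the mean of the *rounded* per-fold values,
itself rounded — the same arithmetic as the comparative tables this format
mirrors, under which fold accuracies are multiples of 1/34 or 1/33.

**Baselines** are off-the-shelf scikit-learn estimators on the same
normalized folds: RBF-kernel SVC (C = 1, scale gamma), KNN (k = 5), and a
one-hidden-layer MLP of width 100 ("BPNN"), all configurable and recorded
in the report fingerprint.

## Synthetic data

The generator emulates an aligned serum LC-MS peak table with a planted
three-group design:

- per-variable baseline log-intensities ~ N(5, 1);
- `n_informative` variables (default 60) carry a CG→MG log-shift of
  `effect_size` (default 2); the treatment group RG gets
  (1 − `treatment_recovery`) of that shift (default recovery 0.6, placing
  RG between CG and MG);
- a `nonlinear_fraction` (default 0.25) of informative variables expresses
  its shift multiplied by the product of two per-sample latent factors
  ~ N(1, 0.2), giving a correlated nonlinear signal component;
- i.i.d. log-scale noise with `noise_sd` = 0.3 by default (≈ 30%
  multiplicative coefficient of variation, typical of QC-passing serum
  profiling);
- entries zeroed independently with probability `sparsity` (default 0.4)
  to mimic absent peaks;
- intensities exponentiated, so all values are non-negative; three exactly
  balanced groups of `n_per_class` (default 56) samples.

`planted_truth` returns the informative set and expected per-class
log-means after verifying (by regeneration) that the matrix came from the
stated config.

**What it does and does not emulate.** It reproduces the shapes
(168 × 2889 or 168 × 353), right-skew, sparsity and a
treatment-intermediate group structure. It does *not* reproduce the
correlation structure of real spectra, where one metabolite contributes
many correlated features (adducts, isotopes) and pathway-level shifts
couple hundreds of variables. Two consequences matter for interpreting
test results. First, missingness here is independent of class and
intensity, whereas real absences are censoring-like; independent zeroing
is pure noise and is the dominant difficulty at the default 40% rate.
Second, with only 60 of 2889 variables informative (≈ 2%), unsupervised
CD pretraining at full width captures the dominant noise structure rather
than the class signal, so full-width synthetic runs understate what
pretraining contributes on real data; the evaluation therefore runs at a
width (300) where the informative fraction is closer to realistic
profiling data. Passing tests demonstrate correctness of the machinery
and recovery of planted structure, not field performance.

**A scaling caveat.** Under per-variable min-max normalization the
variable's maximum is typically attained by the most-shifted group, so
increasing `effect_size` *compresses* the control-vs-treatment contrast
(their normalized values shrink toward 0 as e^(−effect)). Group
separability is therefore not monotone in the effect size once the effect
is large; the default of 2 log-units is near the most favorable operating
point for three-group recovery.

## Problem sizes used by the test suite and acceptance script

Cross-validation checks run on 168 × 300 matrices with a 300-100-20-3
network, 100 CD epochs per RBM, and the protocol budgets (L-BFGS 300, GD
5000) — the low-dimensional variant of the study design, sized so the full
suite completes in minutes. The optimizer-contrast check uses the default
full-width table with a d-32-16-3 network and no dropout, comparing
training cost at equal iteration caps. Oracle checks (Boltzmann
enumeration, exact likelihood gradients, finite differences) run on RBMs
and networks with at most a dozen units per layer, where enumeration is
exact.

## Observed behavior and limitations

- Pretraining measurably helps at moderate width: fine-tuning from a
  pretrained stack clearly outperforms the same network fine-tuned from
  random initialization (the cross-validation harness reproduces this).
- With the fixed iteration budgets and no early stopping, the network
  typically reaches its best test error well before the budget is spent
  and then partially overfits; GD's slower convergence acts as implicit
  regularization, so at low width GD fine-tuning often *generalizes*
  better than L-BFGS even though L-BFGS reaches a far lower training cost
  at the same cap. Residual confusion concentrates on the
  control-vs-treatment pair, whose planted contrast is the smallest.
- Determinism: every stochastic step (initialization, Gibbs sampling,
  dropout masks, fold shuffles, generator draws) is a pure function of its
  seed; runs and CLI outputs are byte-reproducible. Seeds for sub-tasks
  are derived by hashing the user seed with a role tag.
- Degenerate inputs: empty matrices, single-class targets, classes smaller
  than k, architecture/data mismatches and non-finite costs fail fast with
  descriptive errors (the CLI maps these to exit codes 2/3/4).
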