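# Methods

## Problem

A longitudinal multi-view omics study measures several *views* — omics
panels, biochemical classes, or modalities — on the same subjects at several
timepoints. A **missing view** is the complete absence of one view at one
timepoint (a block of the data table), a common situation when platforms
change or assays are dropped between follow-ups. The task is to complete
the missing block `D(v2, t2)` given the observed blocks `D(v1, t1)`,
`D(v2, t1)`, and `D(v1, t2)`.

Cross-sectional imputers (missForest, PMM, a conditional GAN) learn a
direct `v1 -> v2` mapping from rows where both views are present. That
mapping can only be learned at timepoints where the pair exists, and it
cannot recover subject-level variation private to `v2`; when the data
distribution drifts between timepoints, the learned mapping is applied
out of its training region.

## The completion model

Every view `v` is first mapped by a view-specific *pre-layer* (dense +
PReLU) to a shared width `d = 64`. Two encoders, **shared across all views
and timepoints**, factorize the embedding:

* the **content encoder** `E_c` (3 dense layers of 64, instance
  normalization after each dense layer, PReLU) produces a per-sample
  content vector intended to be timepoint-invariant and view-specific;
* the **temporal encoder** `E_t` (same stack without instance
  normalization) produces a temporal vector intended to be view-invariant
  and timepoint-specific.

The **generator** re-entangles a content vector with temporal knowledge via
adaptive instance normalization,

```
AdaIN(z_c, z_t) = sigma(z_t) * (z_c - mu(z_c)) / sigma(z_c) + mu(z_t)
```

with `mu`, `sigma` the mean and population standard deviation over the
vector's elements, followed by 3 dense/PReLU layers and a view-specific
linear *post-layer* back to omics units. A **multi-task discriminator**
(per-view input layer, two shared hidden layers of 128 with sigmoid
activations) emits one sigmoid head per source class `(view, timepoint)`;
only the head matching a row's class enters any loss.

Completion of the missing block takes, per sample, content from the
target view at the nearest observed timepoint and temporal knowledge from
the other view at the target timepoint:

```
x_hat(v2, t2) = G( E_c(pre(x(v2, t1))), E_t(pre(x(v1, t2))) )
```

## Objectives

The model minimizes `L = w_con L_con + w_rep L_rep + w_rec L_rec +
w_adv L_adv` with defaults `w_rec = 1, w_con = 0.1, w_rep = 0.1,
w_adv = 1` (tuned values adopted as fixed defaults).

* **Contrastive** `L_con`: mean of NT-Xent losses computed separately for
  content and temporal representations (temperature 0.05, no projection
  head). Content positives are same-subject, same-view pairs across
  timepoints; temporal positives are same-subject, same-timepoint pairs
  across views. The missing block is generated in-loop each iteration and
  its re-encoded representations participate. Negatives span the whole
  minibatch within a representation kind; the per-anchor loss is averaged
  over all `2N` anchors.
* **Reconstruction** `L_rec`: masked MSE between a real block and its
  reconstruction, computed **only** for outputs whose content and temporal
  sources come from two *different* source classes (cross-class
  constraint). Both the cross-view pair (content `(v, t')`, temporal
  `(v', t)`) and the within-view pair (content `(v, t')`, temporal
  `(v, t)`) are admissible and both are used; only same-class pairs are
  excluded. Missing data points in observed views are mean-encoded
  (per-variable training mean) and those cells are excluded from `L_rec`.
* **Representation** `L_rep`: mean of the content and temporal MSEs
  between representations re-encoded from reconstructed data and from the
  corresponding real data.
* **Adversarial** `L_adv`: least-squares form (targets 1 = real, 0 =
  generated) at the single head matching the source class. Classes with no
  real data in training (the fully missing block at obsNum = 0) contribute
  no adversarial term — their head has nothing genuine to contrast
  against, and training the generator against an untrainable head injects
  noise.

Training alternates one discriminator step and one generator-side step per
minibatch (Adam, learning rate 1e-3, batch size 64), with early stopping
on the cross-class reconstruction MSE of the observed validation blocks
(patience 30). The default epoch cap is 600; the test suite and the
acceptance script use 250-epoch fits, which on the default synthetic
cohort is past the point where the validation reconstruction MSE and the
probe accuracies plateau.

`obsNum` retained rows of the target block (revealed training samples)
enter as real data: they are reconstruction targets on the imputation path
and real instances for the discriminator head. Representations used in
contrastive pairs for the target class remain the re-encoded generated
ones for all rows, keeping the pair structure uniform.

## Conditional-GAN baseline

The reference imputer maps `v1` rows directly to `v2` rows with five
residual blocks of 64 (PReLU; batch normalization inside the first four
blocks) and a discriminator of three hidden layers of 128 (batch
normalization in the last two) carrying an auxiliary classifier that
scores concatenated `<v1, v2>` pairs as genuinely paired or not. The loss
is `0.5 L_rec + 0.25 L_adv + 0.25 L_aux`, all least-squares. It trains
only on rows where both views are present (all paired rows at the
non-target timepoint plus the `obsNum` revealed pairs) — the defining
contrast with the disentanglement model, which also learns from unpaired
rows.

## Quality control

Variable-level filters reproduce targeted-metabolomics / Olink practice:
no missing values; at least 50% (75% for the proteomics variant) of
measured values at or above the LOD of the corresponding plate; median
across plates of per-plate QC-replicate RSD strictly below 25%;
Spearman correlation with a remeasured platform strictly above 0.5.
Boundary semantics are exactly these: detectability is inclusive,
RSD and correlation are strict.

## Evaluation

Percent bias per variable over `m` imputations:

```
PB_i = (1/m) * sum_imp median_samples( |x_hat_i - x_i| / x_i )
```

Variables with any nonpositive observed value are excluded with a warning
(the ratio is ill-defined); multiple imputations are pooled by cellwise
averaging for dataset-level views. Methods are compared per variable with
two-sided paired Wilcoxon signed-rank tests against a reference,
Bonferroni-multiplied and binned ns/*/**/*** at 0.05/0.01/0.001. UMAP
(n_neighbors 15, min_dist 0.1, fixed seed) is fitted once on the training
blocks of the target view at both timepoints and the same fitted model
transforms the observed test block and every method's imputed block, so
embedding discrepancies reflect the data rather than refits. maskObs
experiments average PB across repetitions; the UMAP is shown for the
repetition with the lowest median PB.

## Synthetic cohort generator

The generator is a first-class module: it provides ground truth for every
pipeline stage without restricted cohort data. Per subject, a shared
latent content vector `c ~ N(0, I_8)` plus `private_dim = 4` view-private
factors per view (weight 1.4 relative to shared signal). Each view maps
latent state to variables through a linear loading matrix plus a
saturating `0.6 * tanh(2 * M c)` component. Temporal change at the second
timepoint is (i) an affine transform of the shared latent state
(`c -> a * c + d`, `a ~ N(1, 0.15)`, `d ~ N(0, 1.5^2)` per factor) and
(ii) a shared intensity offset of 1.2 units added to every variable of
every view (a batch/assay-version effect). Baseline abundances are
additive, with 20% of variables near a floor of 4.0 and the rest uniform
in [10, 18]; noise sd 0.1; optional MCAR masking.

Design rationale:

* the temporal shift acts on the *shared* latent state rather than
  per-(view, timepoint) in variable space, because a shift private to the
  masked view at the masked timepoint is unidentifiable for *any* method
  at obsNum = 0 — no data from that block exists. The latent form keeps
  the shift identifiable from the observed view while still defeating
  mappings learned at one timepoint (a per-(view, timepoint) offset knob,
  `view_shift_sd`, remains available and defaults to off);
* the saturating loading component makes the cross-view mapping
  region-dependent, so a `v1 -> v2` regression learned at `t1` degrades on
  the shifted `t2` inputs;
* view-private factors are what a direct regression irreducibly loses and
  a same-view content pathway trivially keeps — the structural reason the
  disentanglement model wins the method contrast;
* low-abundance variables inherit the same additive error scale as
  high-abundance ones, so their relative error (percent bias) blows up —
  reproducing the characteristic low-abundance pattern;
* magnitudes keep values positive with overwhelming probability, since
  percent bias requires positive observed denominators.

What the generator does **not** emulate: real marginal distributions
(log-normal tails, zero inflation), plate structure, nonlinear temporal
dynamics, or informative missingness. Passing tests therefore demonstrate
structural correctness of the pipeline and the qualitative phenomena
(disentanglement, method contrast, obsNum monotonicity, low-abundance
blow-up), not performance on any real cohort.

The disentanglement probe quantifies factorization by leave-one-out 5-NN
accuracy: view from content and timepoint from temporal should be high,
while the cross-probes should sit near an empirical chance level computed
by label permutation (100 shuffles), which respects class imbalance.

## Numerical choices

* AdaIN uses the exact population standard deviation with a hard error on
  (near-)constant content vectors (variance < 1e-24). An epsilon inside
  the square root would break the identity `AdaIN(z, z) = z` and the
  moment-matching property at the tolerances we assert; the
  instance-normalization layers, where the epsilon convention belongs, use
  eps = 1e-5.
* Inputs are z-scored per variable with training-set observed statistics
  pooled **per view across timepoints**, so the temporal shift survives
  standardization; predictions are mapped back to omics units on output.
* Split allocation: `n_test = floor(0.20 N)`, `n_val = floor(0.16 N)`,
  `n_train = N - n_test - n_val`; for N = 2085 this yields 1335/333/417.
* MCAR masking draws an exact count `round(rate * n_observed_cells)`
  without replacement, so repetition tables are deterministic.
* Neural-network stack: a small reverse-mode autodiff engine on numpy
  float64 (`leopard.nn`), single-threaded and bit-reproducible under a
  fixed seed; gradients are verified against central finite differences in
  the test suite. Initialization is seeded He-style uniform fan-in.
* Every experiment cell (obsNum x maskObs x repetition) receives a
  distinct seed below 2^31 derived from the base seed via
  `numpy.random.SeedSequence`.

## Problem sizes

The default synthetic study uses 600 subjects, views of 70 and 36
variables, 8 shared content factors, and a 64/16/20 split. Acceptance
fits run 250 epochs; training-loop unit tests use an 80-subject cohort
with a 16-dim embedding.

## Known limitations

* At obsNum = 0 the transfer of the temporal shift to the missing view
  rests entirely on inductive bias (shared trunk, linear post-layers,
  moment transfer); the model recovers only part of the shift, and its
  advantage over the cGAN baseline comes mainly from preserving
  view-private subject variation. Revealing even a few rows (obsNum 20)
  reduces percent bias severalfold.
* The discriminator's head for a never-observed class is inert; its
  parameters exist (the head count is fixed by the declared classes) but
  receive no gradient at obsNum = 0.
* GLMM / PMM / missForest comparisons are out of scope; the experiment
  runner supports the two built-in methods.
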