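# Methods and design notes

This note records the modeling choices behind `digestnn`: what each stage
assumes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## 1. Data model

A study table holds one row per protein isolate: eleven physicochemical
features in a frozen canonical order —

```
particle_size (nm), zeta_potential (mV, signed), solubility (%),
ionic_bond, hydrogen_bond, hydrophobic_interaction, disulfide_bond (mg/L),
alpha_helix, beta_sheet, beta_turn, random_coil (%)
```

— plus the digestibility target and provenance metadata (source, drying
technique).  The column order is part of the contract because weight-based
importance indexes the first network layer by column; importance reports
nevertheless key results by feature *name* so a reordered table cannot
silently mislabel attributions.  Digestibility is held internally as a
fraction in [0, 1]; CSV I/O accepts percent (any value > 1.5 marks the
column as percent).  The fraction convention is forced by the model metrics:
an MAE of 0.014 and RMSE of 0.023 are only meaningful on a [0, 1] target.
The four secondary-structure percentages must sum to 100 ± 0.5.

Standardization is the z-score with *population* standard deviation
(ddof = 0), matching the behavior of the standard machine-learning scaler;
the sample form is available via `ddof=1`.  The scaler is stored as an
explicit parameter object so every transform is exactly invertible
(round-trip identity to 1e-9 is a tested invariant).

Pearson screening bands follow the conventional inclusive thresholds:
high |r| ≥ 0.8, moderate 0.8 > |r| ≥ 0.5, low 0.5 > |r| ≥ 0.3, negligible
below; a zero-variance feature has no defined coefficient and is reported
as negligible with a warning flag.

## 2. Synthetic study table

The measured 23-isolate table was published only as figures, so the
generator emulates its stated summary structure rather than reproducing
per-isolate values.

**Construction.** A 12-dimensional latent Gaussian (11 features +
digestibility) is drawn with a target correlation matrix; each margin is
mapped monotonically onto its published range (uniform margins, except a
squared map for particle size, which skews mass toward the sub-1500 nm
regime most isolates occupy); the four structure fractions are closed to
sum to 100; the disulfide margin is split by drying technique.  Monotone
maps preserve rank correlations, which is what makes the construction
controllable.

**Correlation targets** (feature vs digestibility): α-helix 0.87,
β-turn 0.674, solubility 0.6, β-sheet −0.6, disulfide −0.5, and magnitudes
0.25–0.45 for the rest, with signs following the domain expectations
(smaller particles, stronger electrostatic repulsion, fewer disulfide
bridges, less β-sheet → more digestible).  Zeta potential is generated
negative (−25.61 to −2.05 mV): plant proteins at neutral pH are
predominantly negatively charged, and published magnitudes are absolute
values.  Unspecified feature–feature correlations default to the
single-factor form r_i·r_j (positive semidefinite by construction),
overridden for known groupings: hydrogen ≈ hydrophobic (0.7), and the
compositional structure block (strongly negative β-sheet pairings).

**Calibration.** Three mechanisms keep *realized* Pearson correlations on
target, which raw copula sampling cannot do at n = 23 (the sampling SE of r
alone is ~0.2 for weak correlations):

1. the latent correlation column is analytically inflated for the
   uniform-margin copula distortion, ρ = 2·sin(πr/6);
2. for n > 12 the latent draw is re-colored (whiten, then multiply by the
   Cholesky factor) so its sample correlation matrix equals the target
   exactly;
3. the latent digestibility column is then calibrated iteratively against
   the *final* margins: regenerate from the same fixed draw, measure,
   adjust, repair to the nearest PSD matrix (eigenvalue clipping), keeping
   the best iterate.

With all three, every feature lands within ±0.15 of its target at n = 23
across all tested seeds.  One structural limit remains: the structure
fractions are closed to 100, so their four correlations cannot converge
independently — at n = 1000 the free margins converge to ±0.05 but the
structure block saturates around ±0.08–0.10 against joint PSD feasibility.
The structure ranges (α 15–25, β-sheet 12–42, β-turn 17–27, coil 26–36)
were chosen so midpoints sum to 100 and the width-weighted sum of
digestibility correlations approximately cancels; β-sheet, the dominant and
most variable structure (up to 42%), absorbs most of the sum-to-100
residual (additive redistribution weighted by range width).

**Digestibility margin** is uniform on [0.3334, 0.8851], the published
extremes (potato-like low anchor, pea-like high anchor).  Drying is
assigned freeze to the 8 of 23 isolates with the highest latent disulfide
signal, keeping the piecewise disulfide margin globally monotone.

**What the generator does not emulate:** per-isolate published values,
measurement error structure, replicate variance, any mechanistic digestion
behavior, or the true (unpublished) feature–feature correlation matrix
beyond the group structure above.  Pipeline results on synthetic tables
therefore demonstrate that the *procedure* behaves as published under
matched summary statistics — not that the published per-sample numbers are
recovered.

## 3. Augmentation ensemble

Counts at default: Mixup 450, VAE 4, GAN 4, KNN 2 → 460 generated rows,
stacked once with the 23 originals → 483.  The published composition
percentages (1% / 1% / 98% / remainder) and the three hard numbers
(450 Mixup, 2 KNN, 483 total) are not mutually consistent under a single
formula; the counts above honor every hard number and approximate the
percentages.  "20-fold expansion" counts the generated batch (20 × 23 =
460); the config's `expansion_factor` is the *total* multiple, hence 21 by
default.  All four counts are configurable and validated against
`n·(expansion_factor − 1)` before any training.

All generators operate on the standardized joint 12-dim vector (features +
label): Mixup mixes labels by construction, and the others follow for
consistency, so every augmented row is usable for supervised training.
Augmented rows from the VAE/GAN are clamped to ±6 standardized units as a
numerical sanity bound.

**VAE.** Encoder 12→64→32→(μ, log σ²), decoder 10→32→64→12, Adam 1e-3,
300 epochs, batch 8.  Loss: reconstruction error summed over the 12
coordinates plus `kl_weight` × KL(q‖N(0,I)), both batch-averaged.  The KL
weight defaults to 0.5: at 1.0 the posterior partially collapses on ~23-row
training sets and prior samples land under-dispersed (per-feature std
~0.22–0.28 versus the originals' 1.0); 0.5 keeps sampled std at ~0.43–0.55
with means within ±0.22.  `kl_weight=0` gives the plain-autoencoder mode.

**GAN.** Least-squares adversarial objective (MSE on discriminator scores,
real → 1, fake → 0); generator 10→32→64→12 and discriminator 12→64→32→1
mirror the VAE widths; Adam 1e-3, 300 epochs.  Three standard small-sample
stabilizers are defaults: Adam β₁ = 0.5, instance noise on the
discriminator's inputs annealed 1.0 → 0 over training, and an exponential
moving average (decay 0.99) of the generator weights used for sampling.
Without them the 300-epoch adversarial pair on 23 rows drifts 1–3
standardized units off-center; with them sampled means stay within ±0.5.

**Mixup.** Uniform ordered pair i ≠ j, λ ~ Beta(0.3, 0.3) shared between
features and label.  The Beta(0.3, 0.3) is U-shaped, so most rows sit near
a parent; outputs lie in the convex hull of the originals by construction.

**KNN.** Euclidean distance on the 11 standardized features (the only
metric consistent with standardization), k = 20 capped at n − 1, step
α ~ U(0.1, 0.9) from a uniformly chosen base toward a uniformly chosen
neighbor, full row interpolated identically.

The ensemble re-uses one master seed: per-generator seeds are spawned from
it, making the full 483-row dataset bit-reproducible.

## 4. Regressor and evaluation

Architecture: input → 128 → 64 → 32 → 1, ReLU, dropout 0.3 after the first
two hidden layers (11,905 parameters at 11 inputs; 10,881 at 3).  Uniform
fan-in initialization, seed-pinned.  Training: Adam, lr 5e-4, batch 16
(reshuffled per epoch from the run seed), MSE loss, ≤ 300 epochs.

**Early stopping** stops after 15 consecutive epochs without improvement
> 1e-6 in the monitored loss and restores the best-epoch weights.  The
monitored quantity is, by default, the training-partition MSE evaluated
with dropout off at the end of each epoch.  Two alternatives were measured
and rejected as defaults: the running batch loss (dropout noise trips the
patience rule mid-descent) and a 10% validation slice of the training
partition (~39 rows; its MSE is noisy enough to truncate training during
transient plateaus and on some splits *anti-correlates* with test
performance).  The validation-slice monitor remains available as
`monitor="val"`.  The test partition is never consulted for stopping.

**Standardization happens twice** along the pipeline — once on the original
table before augmentation, and again (fresh scaler) on the stacked 483 rows
before model training.  The trained model stores the second scaler, so
`predict` accepts physical-unit inputs and returns digestibility fractions.

**Evaluation protocol.** The 80/20 split is taken on the augmented rows,
exactly replicating the source protocol.  Because Mixup/KNN test rows are
convex combinations of training parents, test R² is optimistic (~0.97–0.99
here).  This leakage is deliberate and documented; `train_honest` splits
the *original isolates* 80/20 first, augments only the training split, and
evaluates on untouched originals.  A label-shuffle ablation in the test
suite demonstrates the difference: with shuffled labels the honest split
collapses (R² ≤ 0.2) while the replicated protocol stays high.

**Cross-validation** folds the augmented rows by default (five folds of
97/97/97/96/96 on 483), with a per-fold fresh model and scaler; folding the
23 originals (augmenting each training split separately) is available by
passing the table instead of the dataset.  The original-fold mode with 4–5
isolates per validation fold could not plausibly produce the published
fold-level R² range, which is why the augmented-fold mode is the default.

R² is always the coefficient of determination (1 − SS_res/SS_tot).  The
external-validation report additionally prints the squared Pearson
correlation because the two diverge on the literature table: the published
prediction column gives Pearson² = 0.913 but determination = 0.905; the
published headline 0.91 is reproducible only as the squared correlation,
and the report labels both.

## 5. Attribution

*Weight importance*: mean |first-layer weight| per input column (inputs are
standardized, so scales are comparable).  *Permutation importance*: mean
ΔMSE over 20 seed-pinned shuffles of each feature column on held-out rows;
a feature with all-zero first-layer weights gets exactly 0.  The "top-3
contribution share" is the sum of the three largest permutation scores over
the sum of all positive scores (negatives floored at zero for the share
only).

*Shapley values* use permutation sampling: for each evaluated row, 256
random feature orderings are walked from a background row toward the row,
accumulating marginal contributions; absent features are imputed from the
background (training rows by default).  Background rows are cycled in
near-equal proportion so the efficiency identity `base + Σφ ≈ prediction`
holds to sampling tolerance (< 1e-2 at defaults; exact for additive models
when the background size divides the chain count).  The estimator is
validated against brute-force exact Shapley values (all 2^d coalitions) on
small toys.  A sampling estimator was chosen over gradient- or
tree-specific explainers because it is model-agnostic, dependency-free and
exactly testable at desk scale.

Published per-model importance magnitudes (specific weight values, ΔMSE
values, a 61.90% top-3 share) depend on one trained network and the
unpublished measurements; the package contracts only ranks and signs: the
dominant synthetic driver (α-helix) must top all three rankings on a
dominant-driver table, and its signed Shapley values must be positive for
above-average helix content.

## 6. External validation

Nine literature rows (solubility, α-helix, random coil, measured
digestibility, published prediction, percentage error) ship both as an
in-code constant and as a packaged CSV; a test pins their equality.
Self-check mode recomputes MAE (4.74), RMSE (5.82), both R² variants and
the per-row percentage errors |pred − meas|/meas·100 (rounded to 2 decimals
for display) from the printed columns.  Model mode runs a trained
simplified regressor on the rows' three features through the model's own
stored scaler; inputs beyond |z| = 3 against the training scaler are
flagged as extrapolation (the literature α-helix and random-coil values
often are, relative to a synthetic training table — predictions there are
a demonstration of the mechanism, not a claim of accuracy).

## 7. Reproducibility and orchestration

Every source of randomness flows through `numpy.random.Generator` objects
seeded from explicit integers; the pipeline spawns per-stage seeds from one
master seed via `SeedSequence` at fixed stage positions, so any stage can
be rerun in isolation.  Re-running a pipeline with the same config produces
byte-identical JSON artifacts and manifest checksums (SHA-256).  All
artifacts are plain CSV/JSON, including serialized models (architecture +
flattened weights + scaler).

The networks are implemented as a small explicit-backprop numpy core
(dense layers, ReLU, inverted dropout, Adam, MSE); at these sizes (≤ 12-dim
inputs, ≤ 483 rows, ≤ 128-wide layers) numpy is ample, and the core's
gradients are verified against finite differences in the test suite.

## 8. Problem sizes used in tests

The default test run exercises the study-scale objects everywhere: 23-row
tables, 483-row augmented datasets, full 300-epoch training budgets with
early stopping.  The fit-regime checks average five full pipeline runs;
generator fidelity checks use 100-sample draws; Shapley brute-force checks
use 3-feature toys where exact enumeration is trivial.  Large-n generator
convergence is checked at n = 1000.

## 9. Known limitations

- The synthetic table matches summary statistics, not the unpublished
  measurements; absolute model outputs on real isolates are untested.
- The replicated evaluation protocol overstates generalization by
  construction; honest-split results are substantially lower and should be
  preferred for any real decision.
- The GAN and VAE at n = 23 are demonstrations of the ensemble mechanism;
  with 8 of 460 generated rows they contribute little signal either way.
- The structure-block correlation targets cannot all be met simultaneously
  to better than ~±0.1 at large n because of compositional closure.
- Literature-row predictions from synthetic-trained models extrapolate and
  are only directionally meaningful.
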