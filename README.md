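# digestnn

Predicting the in-vitro digestibility of plant-based protein isolates from
their physicochemical profile, for food-protein scientists who want a
screening model instead of a multi-day INFOGEST digestion assay.

Plant proteins digest poorly (typically 45–80% versus >90% for animal
proteins), and measuring digestibility takes days and gram-scale samples.
Eleven routine physicochemical measurements — particle size, zeta potential,
solubility, four intermolecular-force contents (ionic, hydrogen, hydrophobic,
disulfide) and four secondary-structure fractions (α-helix, β-sheet, β-turn,
random coil) — carry enough signal to predict the digestibility fraction *y*
∈ [0, 1] with a small feedforward network.

`digestnn` implements the full small-sample pipeline:

1. **Synthetic study table.** The measured 23-isolate table behind this
   design exists only as figures, so a Gaussian-copula generator emulates it:
   published feature ranges, drying-technique structure (freeze-dried
   isolates carry 29,525–64,737 mg/L of disulfide bonds, spray-dried
   < 6,025 mg/L), secondary-structure fractions closed to 100%, and a
   calibrated correlation pattern (α-helix r ≈ 0.87 with digestibility,
   β-turn ≈ 0.674, β-sheet negative).
2. **Ensemble augmentation, 23 → 483 rows.** Four generators applied to the
   standardized joint (features, label) vector: Mixup — `λx_i + (1−λ)x_j`,
   `λ ~ Beta(0.3, 0.3)` — contributes 450 rows; a 10-dim-latent VAE and a
   least-squares GAN contribute 4 rows each; KNN interpolation (a
   U(0.1, 0.9) step toward one of 20 nearest neighbors) contributes 2.
3. **Feedforward regressor.** Input → 128 → 64 → 32 → 1, ReLU, dropout 0.3
   after the first two hidden layers; Adam (lr 5·10⁻⁴), batch 16, ≤ 300
   epochs, early stopping with patience 15 and best-weights restore; metrics
   MAE, MSE, RMSE and R² = 1 − SS_res/SS_tot; 5-fold cross-validation.
   A *simplified* variant uses only solubility, α-helix and random coil.
4. **Attribution.** Mean |first-layer weight| per feature, permutation
   importance (ΔMSE), and permutation-sampling Shapley values with the
   efficiency property `base + Σφ ≈ prediction`.
5. **External validation.** Nine published literature rows (lentil, quinoa,
   pearl millet, kiwifruit, sunflower-meal proteins) ship as a fixture; the
   package reproduces their error metrics exactly and can run a freshly
   trained simplified model on them.

## Worked example

```python
from digestnn import (SyntheticConfig, AugmentationConfig, TrainConfig,
                      RegressorSpec, generate_protein_table, augment_ensemble,
                      train_regressor, external_validate)

table = generate_protein_table(SyntheticConfig(n_samples=23, seed=7))
dataset = augment_ensemble(table, AugmentationConfig(seed=7))   # 483 rows
model = train_regressor(dataset, RegressorSpec.full(), TrainConfig(seed=7))
print(model.test_metrics)
print(external_validate().to_dict()["mae"])
```

Running this prints

```
MetricsReport(mae=0.0111..., mse=0.00027..., rmse=0.0164..., r2=0.9862..., n=97)
4.739999999999999
```

— the full model explains ~98.6% of test-partition variance with a ~1.6
percentage-point RMSE on the digestibility fraction, and the packaged
literature self-check reproduces the published MAE of 4.74 (percent scale).
Note the test split is taken on the *augmented* rows, so interpolated test
rows share parents with training rows; this replicates the original protocol
and is why R² sits in the optimistic ~0.97–0.99 regime
(`train_honest` provides the leakage-free alternative).

The same workflow is scriptable end to end:

```bash
digestnn run-all --seed 42 --out run42        # all stages + manifest
digestnn generate --n 23 --seed 7 --out t.csv
digestnn augment --input t.csv --seed 7 --out aug.csv
digestnn train --input aug.csv --features simplified --seed 7 --out model.json
digestnn validate --model model.json --out validation.json
```

Each capability also has a short narrative script under `examples/`.

## Layout

```
src/digestnn/
  feature_table.py    # data model, CSV I/O, standardization, Pearson screen
  synthetic.py        # copula generator + packaged literature fixture
  augmentation.py     # VAE, LSGAN, Mixup, KNN, ensemble stacking
  nn.py               # numpy MLP core (backprop, Adam, dropout)
  fnn.py              # regressor, metrics, early stopping, k-fold CV
  interpretability.py # weight / permutation / Shapley attribution
  validation.py       # external literature comparison
  pipeline.py, cli.py # orchestration and thin command-line layer
docs/methods.md       # modeling and design notes
examples/             # one runnable script per capability
```
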