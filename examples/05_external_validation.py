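"""External validation against nine published literature rows.

Self-check mode validates the published prediction column itself: it must
reproduce MAE 4.74, RMSE 5.82 and squared-Pearson R² 0.91 exactly, and it
shows that the coefficient-of-determination form of R² gives 0.90 on the
same columns.  A freshly trained simplified model can also be run on the
rows' (solubility, α-helix, random-coil) triples.
"""

from digestnn import (
    AugmentationConfig,
    RegressorSpec,
    SyntheticConfig,
    TrainConfig,
    augment_ensemble,
    external_validate,
    generate_protein_table,
    train_regressor,
)

rep = external_validate()  # fixture self-check
print("published-prediction self-check:")
print(f"  MAE {rep.mae:.2f}  RMSE {rep.rmse:.2f}  "
      f"R2(pearson^2) {rep.r2_pearson_squared:.2f}  R2(determination) {rep.r2_determination:.2f}")
print("  per-row percentage errors:", [r[3] for r in rep.rows])

table = generate_protein_table(SyntheticConfig(seed=7))
dataset = augment_ensemble(table, AugmentationConfig(seed=7))
model = train_regressor(dataset, RegressorSpec.simplified(), TrainConfig(seed=7))
rep2 = external_validate(model=model)
print("\nfreshly trained simplified model on the literature rows:")
for source, measured, predicted, err in rep2.rows:
    print(f"  {source:24s} measured {measured:5.1f}%  predicted {predicted:5.1f}%  err {err:5.2f}%")
if rep2.extrapolated:
    print("  note: inputs extrapolate beyond the training range for:",
          ", ".join(rep2.extrapolated))
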