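"""End-to-end orchestration: generate → augment → train → explain → validate.

One master seed drives every stage.  Sub-seeds are spawned from it with
``numpy.random.SeedSequence`` at fixed stage positions (generate=0, augment=1,
train-full=2, train-simplified=3, explain=4, cv=5), so any stage can be rerun
in isolation and reproduce the full run's result exactly.

Each run writes plain CSV/JSON artifacts plus a manifest with the config, the
derived seeds, SHA-256 checksums of every artifact and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augmentation import AugmentationConfig, AugmentedDataset, augment_ensemble
from .exceptions import ConfigError, DigestnnError
from .feature_table import (
    CSV_COLUMNS,
    FEATURE_NAMES,
    TARGET_NAME,
    ProteinFeatureTable,
    ScalerParams,
    pearson_screen,
    write_feature_table,
)
from .fnn import RegressorSpec, TrainConfig, kfold_cv, train_honest, train_regressor
from .interpretability import compute_importance_report
from .synthetic import SyntheticConfig, generate_protein_table
from .validation import external_validate

STAGES = ("generate", "augment", "train_full", "train_simplified", "explain", "cv")


@dataclass(frozen=True)
class RunConfig:
    """Workflow configuration; round-trips through YAML/JSON unchanged."""

    seed: int = 42
    n_samples: int = 23
    expansion_factor: int = 21
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 5e-4
    early_stopping_patience: int = 15
    cv_folds: int = 5
    importance_repeats: int = 20
    shap_samples: int = 256
    honest_split: bool = False
    run_cv: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ConfigError("n_samples must be at least 5")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be at least 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data or {})


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31)) for name, c in zip(STAGES, children)}


def augmentation_config_for(n: int, expansion_factor: int, seed: int) -> AugmentationConfig:
    """Default counts when they fit exactly (the 23-row study layout),
    proportionally scaled counts otherwise."""
    base = AugmentationConfig(seed=seed, expansion_factor=expansion_factor)
    if base.generated_count == n * (expansion_factor - 1):
        return base
    return AugmentationConfig.scaled(n, expansion_factor, seed=seed)


def dataset_to_csv(dataset: AugmentedDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def dataset_from_csv(path) -> AugmentedDataset:
    """Rebuild an augmented dataset from its CSV.

    The scaler is re-fit on the original-tagged rows, which reproduces the
    standardization of the run that wrote the file.
    """
    df = pd.read_csv(path)
    if "provenance" not in df.columns:
        raise ConfigError("augmented CSV must carry a 'provenance' column")
    cols = [CSV_COLUMNS[f] for f in FEATURE_NAMES]
    X = df[cols].to_numpy(float)
    y = df[TARGET_NAME].to_numpy(float) / 100.0
    joint = np.column_stack([X, y])
    orig = df["provenance"].to_numpy() == "original"
    if orig.sum() < 2:
        raise ConfigError("augmented CSV must contain at least 2 original rows")
    scaler = ScalerParams.fit(joint[orig], (*FEATURE_NAMES, TARGET_NAME))
    return AugmentedDataset(scaler.transform(joint), df["provenance"].to_numpy(), scaler)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig | None = None, out_dir="run") -> Path:
    """Execute the full workflow and write all artifacts to ``out_dir``.

    Idempotent for a fixed config: re-running reproduces byte-identical
    metrics.  Stage failures are re-raised with the stage name; artifacts of
    completed stages remain on disk.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    tc = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                     learning_rate=config.learning_rate,
                     early_stopping_patience=config.early_stopping_patience)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise DigestnnError(f"stage '{name}' failed: {exc}") from exc

    table = _stage("generate", lambda: generate_protein_table(
        SyntheticConfig(n_samples=config.n_samples, seed=seeds["generate"])))
    write_feature_table(table, out / "table.csv")
    screen = pearson_screen(table)
    _write_json(out / "pearson_screen.json",
                {"r": screen.r, "band": screen.band, "warnings": list(screen.warnings)})

    aug_cfg = augmentation_config_for(len(table), config.expansion_factor, seeds["augment"])
    dataset = _stage("augment", lambda: augment_ensemble(table, aug_cfg))
    dataset_to_csv(dataset, out / "augmented.csv")
    _write_json(out / "augment_report.json",
                {"tag_counts": dataset.tag_counts(), **dataset.distribution_report})

    metrics: dict[str, dict] = {}
    models = {}
    for variant, spec in (("full", RegressorSpec.full()),
                          ("simplified", RegressorSpec.simplified())):
        seed = seeds[f"train_{variant}"]
        cfg = dataclasses.replace(tc, seed=seed)
        if config.honest_split:
            trained = _stage(f"train_{variant}", lambda s=spec, c=cfg: train_honest(table, aug_cfg, s, c))
        else:
            trained = _stage(f"train_{variant}", lambda s=spec, c=cfg: train_regressor(dataset, s, c))
        trained.save(out / f"model_{variant}.json")
        metrics[variant] = {**trained.test_metrics.to_dict(),
                            "stopped_epoch": trained.stopped_epoch}
        models[variant] = trained
    _write_json(out / "metrics.json", metrics)

    importance = _stage("explain", lambda: compute_importance_report(
        models["full"], table.X, table.y,
        n_repeats=config.importance_repeats, n_shap_samples=config.shap_samples,
        seed=seeds["explain"]))
    _write_json(out / "importance.json", importance.to_dict())

    validation = {
        "fixture_self_check": external_validate().to_dict(),
        "simplified_model": external_validate(model=models["simplified"]).to_dict(),
    }
    _write_json(out / "validation.json", validation)

    if config.run_cv:
        cv = _stage("cv", lambda: kfold_cv(
            dataset, k=config.cv_folds,
            cfg=dataclasses.replace(tc, seed=seeds["cv"]),
            spec=RegressorSpec.full()))
        _write_json(out / "cv.json", cv.to_dict())

    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "checksums": {name: _sha256(out / name) for name in artifacts},
        "versions": {"digestnn": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    _write_json(out / "manifest.json", manifest)
    return out
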