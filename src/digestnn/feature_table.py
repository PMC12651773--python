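"""Physicochemical feature tables for plant-protein digestibility work.

The central container is :class:`ProteinFeatureTable`: one row per protein
isolate, eleven numeric physicochemical features in a frozen order, a
digestibility target stored internally as a fraction in [0, 1], and light
provenance metadata (sample id, botanical source, drying technique).

The frozen feature order matters: weight-based importance indexes the first
network layer by column, so the order is part of the data contract.  All
importance reports nevertheless key results by feature *name* so that a
re-ordered table cannot silently mislabel attributions.

Also here: z-score standardization with an explicit, invertible parameter
record (population standard deviation by default, switchable to the sample
form), Pearson screening of each feature against digestibility with the
conventional |r| bands, and the two wet-lab utility formulas used to turn
Kjeldahl titration volumes into protein content and digestibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateFeatureError,
    DomainError,
    InsufficientDataError,
    ParseError,
    SchemaError,
    ShapeError,
)

#: Frozen canonical order of the 11 physicochemical features.
FEATURE_NAMES: tuple[str, ...] = (
    "particle_size",
    "zeta_potential",
    "solubility",
    "ionic_bond",
    "hydrogen_bond",
    "hydrophobic_interaction",
    "disulfide_bond",
    "alpha_helix",
    "beta_sheet",
    "beta_turn",
    "random_coil",
)

#: The three inputs of the simplified model, in canonical order.
SIMPLIFIED_FEATURES: tuple[str, ...] = ("solubility", "alpha_helix", "random_coil")

#: Secondary-structure columns; their percentages must sum to 100 +- 0.5.
STRUCTURE_FEATURES: tuple[str, ...] = (
    "alpha_helix",
    "beta_sheet",
    "beta_turn",
    "random_coil",
)

TARGET_NAME = "digestibility"

#: Mapping from internal feature names to the on-disk CSV column names.
CSV_COLUMNS: dict[str, str] = {
    "particle_size": "particle_size_nm",
    "zeta_potential": "zeta_potential_mV",
    "solubility": "solubility_pct",
    "ionic_bond": "ionic_bond_mgL",
    "hydrogen_bond": "hydrogen_bond_mgL",
    "hydrophobic_interaction": "hydrophobic_mgL",
    "disulfide_bond": "disulfide_mgL",
    "alpha_helix": "alpha_helix_pct",
    "beta_sheet": "beta_sheet_pct",
    "beta_turn": "beta_turn_pct",
    "random_coil": "random_coil_pct",
}

META_COLUMNS = ("sample_id", "source", "drying")
DRYING_LEVELS = ("spray", "freeze", "unknown")

STRUCTURE_SUM_TOL = 0.5

#: |r| band thresholds (inclusive lower bounds).
BAND_HIGH = 0.8
BAND_MODERATE = 0.5
BAND_LOW = 0.3


@dataclass(frozen=True)
class ProteinFeatureTable:
    """A validated table of protein isolates.

    Parameters
    ----------
    data
        DataFrame holding the metadata columns ``sample_id``, ``source``,
        ``drying``, the eleven feature columns named as in
        :data:`FEATURE_NAMES`, and ``digestibility`` as a fraction in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in (*META_COLUMNS, *FEATURE_NAMES, TARGET_NAME) if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        numeric = df[list(FEATURE_NAMES) + [TARGET_NAME]]
        if numeric.isna().any().any():
            bad = numeric.columns[numeric.isna().any()].tolist()
            raise SchemaError(f"missing values in column(s): {', '.join(bad)}")
        y = df[TARGET_NAME].to_numpy(float)
        if ((y < 0) | (y > 1)).any():
            raise SchemaError("digestibility must lie in [0, 1] (fraction scale)")
        if (df["particle_size"].to_numpy(float) <= 0).any():
            raise SchemaError("particle_size must be positive")
        sol = df["solubility"].to_numpy(float)
        if ((sol < 0) | (sol > 100)).any():
            raise SchemaError("solubility must lie in [0, 100] percent")
        for col in ("ionic_bond", "hydrogen_bond", "hydrophobic_interaction", "disulfide_bond"):
            if (df[col].to_numpy(float) < 0).any():
                raise SchemaError(f"{col} must be non-negative")
        ss = df[list(STRUCTURE_FEATURES)].to_numpy(float).sum(axis=1)
        off = np.abs(ss - 100.0)
        if (off > STRUCTURE_SUM_TOL).any():
            i = int(np.argmax(off))
            raise SchemaError(
                f"secondary-structure percentages must sum to 100 +- {STRUCTURE_SUM_TOL}; "
                f"row {i} sums to {ss[i]:.3f}"
            )
        bad_drying = set(df["drying"].astype(str)) - set(DRYING_LEVELS)
        if bad_drying:
            raise SchemaError(f"unknown drying level(s): {sorted(bad_drying)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        """The 11 feature columns in canonical order."""
        return self.data[list(FEATURE_NAMES)]

    @property
    def X(self) -> np.ndarray:
        """Feature matrix, shape (n, 11), canonical column order."""
        return self.features.to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        """Digestibility target as fractions, shape (n,)."""
        return self.data[TARGET_NAME].to_numpy(float)

    @property
    def Xy(self) -> np.ndarray:
        """Joint matrix of features and target, shape (n, 12)."""
        return np.column_stack([self.X, self.y])


def read_feature_table(path) -> ProteinFeatureTable:
    """Read a feature-table CSV and validate it.

    The CSV must carry the full schema (``sample_id``, ``source``, ``drying``,
    the eleven feature columns with unit-suffixed names, ``digestibility``).
    Digestibility on disk may be percent or fraction; any value above 1.5 makes
    the whole column percent, which is converted to fractions on load.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ParseError
        if a numeric cell fails to parse, with the offending row index.
    """
    raw = pd.read_csv(path)
    expected = {**{m: m for m in META_COLUMNS}, **{CSV_COLUMNS[f]: f for f in FEATURE_NAMES},
                TARGET_NAME: TARGET_NAME}
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = raw[list(expected)].rename(columns=expected)
    for col in (*FEATURE_NAMES, TARGET_NAME):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value in column '{col}' at row {row}")
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise ParseError(f"missing value in column '{col}' at row {row}")
        df[col] = parsed.astype(float)
    if (df[TARGET_NAME] > 1.5).any():
        df[TARGET_NAME] = df[TARGET_NAME] / 100.0
    return ProteinFeatureTable(df.reset_index(drop=True))


def write_feature_table(table: ProteinFeatureTable, path, *, extra: pd.DataFrame | None = None) -> None:
    """Write a table to CSV using the on-disk schema (digestibility as percent).

    ``extra`` optionally appends provenance columns (e.g. generator tags).
    """
    df = table.data.copy()
    df[TARGET_NAME] = df[TARGET_NAME] * 100.0
    df = df.rename(columns=CSV_COLUMNS)
    cols = [*META_COLUMNS, *(CSV_COLUMNS[f] for f in FEATURE_NAMES), TARGET_NAME]
    out = df[cols]
    if extra is not None:
        out = pd.concat([out.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Standardization (z-score with invertible parameters)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerParams:
    """Per-column mean/std for z-score standardization and its inverse.

    ``ddof=0`` (population standard deviation) is the default, matching the
    convention of the usual machine-learning standardizer; ``ddof=1`` gives the
    sample form.
    """

    mean: np.ndarray
    std: np.ndarray
    columns: tuple[str, ...]
    ddof: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "std", np.asarray(self.std, float))
        if self.mean.shape != self.std.shape or self.mean.ndim != 1:
            raise ShapeError("mean and std must be 1-D arrays of equal length")
        if len(self.columns) != self.mean.size:
            raise ShapeError("column names must match parameter length")
        if (self.std <= 0).any():
            bad = self.columns[int(np.argmax(self.std <= 0))]
            raise DegenerateFeatureError(f"non-positive std for column '{bad}'")

    @classmethod
    def fit(cls, matrix: np.ndarray, columns: tuple[str, ...], ddof: int = 0) -> "ScalerParams":
        matrix = np.asarray(matrix, float)
        if matrix.ndim != 2 or matrix.shape[1] != len(columns):
            raise ShapeError(f"expected a 2-D matrix with {len(columns)} columns")
        if matrix.shape[0] < 2:
            raise InsufficientDataError("standardization needs at least 2 rows")
        std = matrix.std(axis=0, ddof=ddof)
        if (std == 0).any():
            bad = columns[int(np.argmax(std == 0))]
            raise DegenerateFeatureError(f"zero-variance column '{bad}'")
        return cls(mean=matrix.mean(axis=0), std=std, columns=tuple(columns), ddof=ddof)

    def _check(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, float)
        if matrix.ndim != 2 or matrix.shape[1] != self.mean.size:
            raise ShapeError(
                f"matrix has {matrix.shape[-1] if matrix.ndim else 0} columns, "
                f"scaler expects {self.mean.size}"
            )
        return matrix

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """(x - mean) / std per column."""
        return (self._check(matrix) - self.mean) / self.std

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        """z * std + mean per column."""
        return self._check(matrix) * self.std + self.mean

    def subset(self, columns: tuple[str, ...]) -> "ScalerParams":
        """Restrict the scaler to a subset of its columns, preserving order given."""
        idx = [self.columns.index(c) for c in columns]
        return ScalerParams(self.mean[idx], self.std[idx], tuple(columns), self.ddof)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "columns": list(self.columns),
            "ddof": self.ddof,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalerParams":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]), tuple(d["columns"]),
                   int(d.get("ddof", 0)))


def standardize(table: ProteinFeatureTable, ddof: int = 0) -> tuple[np.ndarray, ScalerParams]:
    """Standardize the joint (features, digestibility) matrix of a table.

    Returns the z-scored (n, 12) matrix and the fitted :class:`ScalerParams`
    (11 feature columns plus the target).
    """
    columns = (*FEATURE_NAMES, TARGET_NAME)
    params = ScalerParams.fit(table.Xy, columns, ddof=ddof)
    return params.transform(table.Xy), params


def inverse_standardize(matrix: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Undo :func:`standardize`: ``x = z * std + mean`` per column."""
    return params.inverse_transform(matrix)


# ---------------------------------------------------------------------------
# Pearson screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationReport:
    """Per-feature Pearson correlation with digestibility, with |r| bands.

    Bands use inclusive lower bounds: high |r| >= 0.8, moderate 0.8 > |r| >= 0.5,
    low 0.5 > |r| >= 0.3, negligible below. Constant features get r = 0 with a
    warning flag (the coefficient is undefined there).
    """

    r: dict[str, float]
    band: dict[str, str]
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": pd.Series(self.r), "band": pd.Series(self.band)}
        ).loc[list(FEATURE_NAMES)]


def assign_band(r: float) -> str:
    """Map a Pearson coefficient to its conventional strength band."""
    a = abs(r)
    if a >= BAND_HIGH:
        return "high"
    if a >= BAND_MODERATE:
        return "moderate"
    if a >= BAND_LOW:
        return "low"
    return "negligible"


def pearson_screen(table: ProteinFeatureTable) -> CorrelationReport:
    """Correlate every feature with digestibility and band the coefficients."""
    if len(table) < 3:
        raise InsufficientDataError("Pearson screening needs at least 3 rows")
    y = table.y
    rs: dict[str, float] = {}
    bands: dict[str, str] = {}
    warns: list[str] = []
    y_ctr = y - y.mean()
    sy = math.sqrt(float(y_ctr @ y_ctr))
    for name in FEATURE_NAMES:
        x = table.data[name].to_numpy(float)
        x_ctr = x - x.mean()
        sx = math.sqrt(float(x_ctr @ x_ctr))
        if sx == 0.0 or sy == 0.0:
            rs[name] = 0.0
            bands[name] = "negligible"
            warns.append(name)
            continue
        r = float(x_ctr @ y_ctr) / (sx * sy)
        rs[name] = r
        bands[name] = assign_band(r)
    return CorrelationReport(rs, bands, tuple(warns))


# ---------------------------------------------------------------------------
# Wet-lab utility formulas
# ---------------------------------------------------------------------------

def protein_content(V: float, c: float, m: float) -> float:
    """Protein content (%) from a Kjeldahl titration.

    ``PC = V * c * 0.014 / m * 6.25 * 100`` with V the titrant volume (mL),
    c its molar concentration (mol/L), m the sample mass (g); 0.014 g/mmol is
    the molar mass of nitrogen and 6.25 the nitrogen-to-protein factor.
    """
    if m <= 0:
        raise DomainError("sample mass m must be positive")
    if V < 0 or c < 0:
        raise DomainError("titrant volume and concentration must be non-negative")
    return V * c * 0.014 / m * 6.25 * 100.0


def digestibility_from_contents(PC1: float, PC0: float) -> float:
    """Digestibility (%) from protein content after (PC1) and before (PC0) digestion.

    ``(1 - PC1/PC0) * 100``; requires 0 <= PC1 <= PC0 and PC0 > 0.
    """
    if PC0 <= 0:
        raise DomainError("initial protein content PC0 must be positive")
    if PC1 < 0 or PC1 > PC0:
        raise DomainError("residual protein content must satisfy 0 <= PC1 <= PC0")
    return (1.0 - PC1 / PC0) * 100.0
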