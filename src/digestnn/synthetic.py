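"""Synthetic protein feature tables and the packaged literature fixture.

The measured physicochemical table behind this pipeline (23 plant-protein
isolates) was published only as figures, so development and testing run on a
synthetic emulation: a Gaussian copula draws a latent 12-dimensional normal
with a target correlation structure (eleven features plus digestibility), each
margin is pushed through a monotone map onto its published range, the four
secondary-structure percentages are renormalized to sum to 100, and the
disulfide-bond margin is split by drying technique (freeze-dried isolates in
the high range, spray-dried below 6025 mg/L).

Because monotone maps preserve rank correlations, the realized Pearson
correlations stay close to their latent targets.  For n above the latent
dimension the latent draw is re-colored so its *sample* correlation matrix
equals the target exactly; the residual discrepancy after the margin maps is
then only the (small) copula distortion, which keeps the realized
feature-digestibility correlations within a tight tolerance of their targets
even at n = 23.

The external-validation fixture — nine literature rows of solubility,
α-helix, random-coil, measured digestibility, model prediction and percentage
error — is shipped both as an in-code constant and as a packaged CSV; a test
asserts the two agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigError
from .feature_table import (
    FEATURE_NAMES,
    STRUCTURE_FEATURES,
    ProteinFeatureTable,
)

#: Target Pearson correlation of each feature with digestibility.
DEFAULT_TARGET_CORRELATIONS: dict[str, float] = {
    "particle_size": -0.40,
    "zeta_potential": -0.30,
    "solubility": 0.60,
    "ionic_bond": 0.25,
    "hydrogen_bond": 0.40,
    "hydrophobic_interaction": 0.35,
    "disulfide_bond": -0.50,
    "alpha_helix": 0.87,
    "beta_sheet": -0.60,
    "beta_turn": 0.674,
    "random_coil": 0.30,
}

#: Published measurement ranges; the disulfide entry is the spray-dried range,
#: freeze-dried isolates use DEFAULT_DISULFIDE_FREEZE_RANGE.
DEFAULT_FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "particle_size": (150.0, 9000.0),
    "zeta_potential": (-25.61, -2.05),
    "solubility": (8.41, 85.94),
    "ionic_bond": (500.0, 8000.0),
    "hydrogen_bond": (1000.0, 20000.0),
    "hydrophobic_interaction": (1000.0, 25000.0),
    "disulfide_bond": (300.0, 6025.0),
    "alpha_helix": (15.0, 25.0),
    "beta_sheet": (12.0, 42.0),
    "beta_turn": (17.0, 27.0),
    "random_coil": (26.0, 36.0),
}

DEFAULT_DISULFIDE_FREEZE_RANGE: tuple[float, float] = (29525.2, 64736.9)

#: Observed digestibility extremes (fraction scale) anchoring the target margin.
DEFAULT_DIGESTIBILITY_RANGE: tuple[float, float] = (0.3334, 0.8851)

#: Feature-feature correlation overrides reflecting the bond/structure
#: groupings (hydrogen and hydrophobic forces track each other; the four
#: structure fractions compete for the same 100%).
DEFAULT_GROUP_CORRELATIONS: dict[tuple[str, str], float] = {
    ("hydrogen_bond", "hydrophobic_interaction"): 0.70,
    ("ionic_bond", "hydrogen_bond"): 0.40,
    ("ionic_bond", "disulfide_bond"): 0.30,
    ("alpha_helix", "beta_sheet"): -0.76,
    ("alpha_helix", "beta_turn"): 0.70,
    ("alpha_helix", "random_coil"): 0.35,
    ("beta_sheet", "beta_turn"): -0.76,
    ("beta_sheet", "random_coil"): -0.70,
    ("beta_turn", "random_coil"): 0.30,
    ("solubility", "particle_size"): -0.45,
    ("solubility", "beta_sheet"): -0.40,
}

_SOURCES = (
    "soybean", "pea", "fava_bean", "kidney_bean", "chickpea", "lupin", "rice",
    "brown_rice", "wheat", "barley", "oat", "corn", "potato", "walnut", "sesame",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for generating a synthetic isolate table."""

    n_samples: int = 23
    seed: int = 0
    target_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS))
    feature_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_RANGES))
    disulfide_freeze_range: tuple[float, float] = DEFAULT_DISULFIDE_FREEZE_RANGE
    digestibility_range: tuple[float, float] = DEFAULT_DIGESTIBILITY_RANGE
    group_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_CORRELATIONS))
    fraction_freeze_dried: float = 8.0 / 23.0

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ConfigError("n_samples must be at least 5")
        for name, r in self.target_correlations.items():
            if name not in FEATURE_NAMES:
                raise ConfigError(f"unknown feature in target_correlations: {name}")
            if not abs(r) < 1:
                raise ConfigError(f"|target correlation| must be < 1 (got {r} for {name})")
        for name in FEATURE_NAMES:
            if name not in self.feature_ranges:
                raise ConfigError(f"feature_ranges missing '{name}'")
        ranges = {**self.feature_ranges,
                  "digestibility": self.digestibility_range,
                  "_disulfide_freeze": self.disulfide_freeze_range}
        for name, (lo, hi) in ranges.items():
            if not lo < hi:
                raise ConfigError(f"range for {name} must satisfy lo < hi (got {lo}, {hi})")
        if not 0.0 <= self.fraction_freeze_dried <= 1.0:
            raise ConfigError("fraction_freeze_dried must lie in [0, 1]")


@dataclass(frozen=True)
class GenerationReport:
    """Diagnostics for one generated table."""

    realized_correlations: dict[str, float]
    clip_rate: dict[str, float]
    correlation_matrix: np.ndarray


def _nearest_psd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite repair with unit diagonal."""
    A = (R + R.T) / 2.0
    for _ in range(10):
        w, V = np.linalg.eigh(A)
        if w.min() >= floor / 2:
            break
        w = np.clip(w, floor, None)
        A = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        np.fill_diagonal(A, 1.0)
    return A


def build_correlation_matrix(config: SyntheticConfig) -> np.ndarray:
    """Assemble the 12x12 latent correlation matrix (11 features + target).

    Unspecified feature-feature entries default to the single-factor value
    r_i * r_j implied by the per-feature digestibility targets (which is
    positive semidefinite by construction); the group overrides are applied on
    top and the result repaired to the nearest PSD correlation matrix.
    """
    names = list(FEATURE_NAMES)
    r = np.array([config.target_correlations.get(n, 0.0) for n in names])
    k = len(names)
    # invert the Gaussian-copula distortion for uniform margins
    # (realized r_u = (6/pi) asin(rho/2)  =>  rho = 2 sin(pi r_u / 6))
    r_latent = 2.0 * np.sin(np.pi * r / 6.0)
    R = np.empty((k + 1, k + 1))
    R[:k, :k] = np.outer(r_latent, r_latent)
    R[:k, k] = R[k, :k] = r_latent
    np.fill_diagonal(R, 1.0)
    for (a, b), v in config.group_correlations.items():
        if a not in names or b not in names:
            raise ConfigError(f"unknown feature pair in group_correlations: ({a}, {b})")
        if not abs(v) < 1:
            raise ConfigError(f"|group correlation| must be < 1 (got {v})")
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = v
    repaired = _nearest_psd(R)
    drift = np.abs(repaired[:k, k] - r_latent).max()
    if drift > 0.1:
        suggestion = {n: round(float(v), 3) for n, v in zip(names, repaired[:k, k])}
        raise ConfigError(
            "target correlations are jointly infeasible (not positive semidefinite); "
            f"nearest feasible digestibility correlations: {suggestion}"
        )
    return repaired


def _renormalize_structure(S: np.ndarray, ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    """Adjust the four structure columns to sum to 100.

    The residual 100 - sum is distributed additively in proportion to the
    squared range width of each column (so the wide β-sheet margin absorbs
    most of it), then values are clipped to range and any remainder is
    redistributed proportionally to the remaining slack (exact).  The additive
    scheme perturbs the narrow columns far less than multiplicative rescaling
    would, preserving their copula correlations.
    """
    lo = np.array([ranges[c][0] for c in STRUCTURE_FEATURES])
    hi = np.array([ranges[c][1] for c in STRUCTURE_FEATURES])
    w = hi - lo
    lam = w / w.sum()
    resid = 100.0 - S.sum(axis=1, keepdims=True)
    out = np.clip(S + resid * lam, lo, hi)
    for _ in range(8):
        resid = 100.0 - out.sum(axis=1)
        if np.abs(resid).max() < 1e-9:
            break
        slack = np.where(resid[:, None] > 0, hi - out, out - lo)
        total = slack.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        out = np.clip(out + resid[:, None] * slack / total, lo, hi)
    return out


def _realize_margins(config: SyntheticConfig, U: np.ndarray):
    """Map copula uniforms onto the physical margins.

    Returns feature columns, the digestibility vector, the freeze-dried mask
    and per-feature clip rates.
    """
    n = U.shape[0]
    names = list(FEATURE_NAMES)
    cols: dict[str, np.ndarray] = {}
    clip_rate: dict[str, float] = {}
    for j, name in enumerate(names):
        lo, hi = config.feature_ranges[name]
        u = U[:, j]
        if name == "particle_size":
            # squared margin skews mass toward small particles, as measured
            x = lo + (hi - lo) * u ** 2
        elif name == "disulfide_bond":
            continue  # handled with drying assignment below
        else:
            x = lo + (hi - lo) * u
        cols[name] = x

    # drying: freeze-dried isolates are the ones with the highest latent
    # disulfide signal, so the piecewise margin map stays globally monotone
    j_ds = names.index("disulfide_bond")
    u_ds = U[:, j_ds]
    n_freeze = int(round(config.fraction_freeze_dried * n))
    order = np.argsort(u_ds)
    freeze_mask = np.zeros(n, bool)
    if n_freeze > 0:
        freeze_mask[order[-n_freeze:]] = True
    slo, shi = config.feature_ranges["disulfide_bond"]
    flo, fhi = config.disulfide_freeze_range
    x_ds = np.empty(n)
    if freeze_mask.any():
        u_star = u_ds[freeze_mask].min()
    else:
        u_star = 1.0
    spray = ~freeze_mask
    x_ds[spray] = slo + (shi - slo) * (u_ds[spray] / max(u_star, 1e-12))
    if freeze_mask.any():
        span = max(1.0 - u_star, 1e-12)
        x_ds[freeze_mask] = flo + (fhi - flo) * (u_ds[freeze_mask] - u_star) / span
    cols["disulfide_bond"] = x_ds

    S = np.column_stack([cols[c] for c in STRUCTURE_FEATURES])
    S = _renormalize_structure(S, config.feature_ranges)
    for i, c in enumerate(STRUCTURE_FEATURES):
        cols[c] = S[:, i]

    for name in names:
        if name == "disulfide_bond":
            continue
        lo, hi = config.feature_ranges[name]
        clipped = np.clip(cols[name], lo, hi)
        clip_rate[name] = float(np.mean(clipped != cols[name]))
        cols[name] = clipped
    lo_all = np.where(freeze_mask, flo, slo)
    hi_all = np.where(freeze_mask, fhi, shi)
    clipped = np.clip(cols["disulfide_bond"], lo_all, hi_all)
    clip_rate["disulfide_bond"] = float(np.mean(clipped != cols["disulfide_bond"]))
    cols["disulfide_bond"] = clipped

    dlo, dhi = config.digestibility_range
    y = dlo + (dhi - dlo) * U[:, -1]
    return cols, y, freeze_mask, clip_rate


def generate_protein_table(
    config: SyntheticConfig | None = None, *, return_report: bool = False
):
    """Generate a synthetic isolate table emulating the measured study table.

    The latent Gaussian draw is fixed once from ``config.seed``; the latent
    feature-digestibility correlation column is then calibrated iteratively
    (regenerate from the same draw, measure, adjust) so the *realized* Pearson
    correlations land on their targets despite the non-linear margins, the
    structure renormalization and the drying-conditional disulfide split.
    Deterministic for a fixed seed.  With ``return_report=True`` also returns
    a :class:`GenerationReport` with realized correlations and clip rates.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    R = build_correlation_matrix(config)
    n = config.n_samples
    names = list(FEATURE_NAMES)
    k = R.shape[0]
    E = rng.standard_normal((n, k))
    if n > k + 1:  # whiten so the latent sample correlation matches exactly
        E = E - E.mean(axis=0)
        S = (E.T @ E) / n
        Ls = np.linalg.cholesky(S + 1e-12 * np.eye(k))
        E = np.linalg.solve(Ls, E.T).T

    target = np.array([config.target_correlations.get(nm, 0.0) for nm in names])
    Rk = R.copy()
    best = None
    since_best = 0
    for _ in range(20):
        Z = E @ np.linalg.cholesky(Rk + 1e-10 * np.eye(k)).T
        cols, y, freeze_mask, clip_rate = _realize_margins(config, norm.cdf(Z))
        realized = np.array([np.corrcoef(cols[nm], y)[0, 1] for nm in names])
        err = target - realized
        score = np.abs(err).max()
        if best is None or score < best[0]:
            best = (score, cols, y, freeze_mask, clip_rate, Rk.copy())
            since_best = 0
        else:
            since_best += 1
        if score < 0.015 or since_best >= 4:
            break
        # only move entries that are materially off, to limit interference
        step = np.where(np.abs(err) > 0.015, 0.6 * err, 0.0)
        latent_col = np.clip(Rk[:-1, -1] + step, -0.985, 0.985)
        Rk[:-1, -1] = Rk[-1, :-1] = latent_col
        Rk = _nearest_psd(Rk)
    _, cols, y, freeze_mask, clip_rate, Rk = best

    df = pd.DataFrame({
        "sample_id": [f"syn{i + 1:02d}" for i in range(n)],
        "source": [_SOURCES[i % len(_SOURCES)] for i in range(n)],
        "drying": np.where(freeze_mask, "freeze", "spray"),
        **{name: cols[name] for name in names},
        "digestibility": y,
    })
    table = ProteinFeatureTable(df)
    if not return_report:
        return table
    realized = {name: float(np.corrcoef(cols[name], y)[0, 1]) for name in names}
    return table, GenerationReport(realized, clip_rate, Rk)


# ---------------------------------------------------------------------------
# External-validation literature fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiteratureRow:
    """One published external-validation row (all values percent)."""

    plant_source: str
    solubility: float
    alpha_helix: float
    random_coil: float
    digestibility: float
    prediction: float
    percentage_error: float


#: The nine published validation rows, verbatim.  Continuation rows of the
#: printed table inherit the plant source of the row above.
TABLE3_ROWS: tuple[LiteratureRow, ...] = (
    LiteratureRow("Lentil protein", 92.7, 10.44, 17.43, 84.9, 93.5, 10.13),
    LiteratureRow("Quinoa protein", 82.94, 19.99, 16.91, 81.07, 83.58, 3.1),
    LiteratureRow("Quinoa protein", 87.0, 17.49, 18.24, 84.06, 82.39, 1.99),
    LiteratureRow("Quinoa protein", 88.53, 16.74, 18.44, 85.15, 92.07, 8.13),
    LiteratureRow("Pearl millet protein", 60.0, 30.19, 25.79, 71.73, 65.92, 8.1),
    LiteratureRow("Pearl millet protein", 62.35, 21.48, 32.8, 75.89, 69.16, 8.87),
    LiteratureRow("Kiwifruit protein", 16.51, 15.0, 33.0, 35.0, 35.28, 0.8),
    LiteratureRow("Kiwifruit protein", 14.54, 10.0, 32.0, 44.0, 43.56, 1.0),
    LiteratureRow("Sunflower meal protein", 64.48, 15.54, 17.69, 93.67, 83.97, 10.36),
)


def table3_fixture() -> list[LiteratureRow]:
    """The packaged external-validation rows (in-code constant)."""
    return list(TABLE3_ROWS)


def load_table3_csv() -> pd.DataFrame:
    """Load the packaged CSV copy of the literature fixture."""
    with resources.files("digestnn").joinpath("data/table3_literature.csv").open() as fh:
        return pd.read_csv(fh)
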