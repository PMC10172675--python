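"""Synthetic survey data with the statistical structure the pipeline assumes.

Real data for the five screeners are not bundled, so this module generates
them: stratified demographic covariates, per-instrument latent traits with
configurable subgroup effects, and graded-response-model item responses
drawn from frozen default item banks.

The default banks were chosen by a documented calibration procedure (see
``scripts/calibrate_banks.py``): the threshold locations and spacings of the
AUDIT-like bank were solved so that the model-implied total-score
distribution has 34% of respondents at the minimum score of 0 and 90% at 6
or below — the zero-inflated, strongly right-skewed shape clinical
screeners show in general-population samples.  The other banks emulate the
qualitative marginals of their instruments (floor-heavy mean scores for the
agoraphobic-cognition scales, right-skewed totals for depression/anxiety).

Subgroup effects act on the latent trait only ("impact"); item-level
differences between groups enter exclusively through :func:`inject_dif`,
which keeps true group differences and differential item functioning
separable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .grm import GRMParams, QuadratureGrid, default_grid, sumscore_likelihoods
from .scales import COVARIATE_LEVELS, MISSING, ResponseMatrix, ScaleSpec, builtin_spec

__all__ = [
    "PopulationConfig",
    "ItemBank",
    "default_item_bank",
    "default_trait_effects",
    "simulate_population",
    "simulate_traits",
    "simulate_responses",
    "simulate_dataset",
    "inject_dif",
    "add_missing",
    "save_responses",
    "score_distribution",
]

#: Stratum proportions of the study sample (general population, two districts).
DEFAULT_STRATA: dict[str, dict[str, float]] = {
    "gender": {"female": 0.579, "male": 0.421},
    "age_group": {
        "16-19": 0.082, "20-29": 0.206, "30-39": 0.198,
        "40-49": 0.213, "50-59": 0.202, "60-69": 0.099,
    },
    "region": {"urban": 0.642, "rural": 0.358},
    "education": {"primary": 0.420, "secondary": 0.413, "higher": 0.167},
}

#: Age bands counted as "younger than 45" when an age effect is configured.
_YOUNG_BANDS = ("16-19", "20-29", "30-39", "40-49")


def default_trait_effects(instrument_id: str) -> dict[str, dict[str, float]]:
    """Standardized subgroup shifts (Cohen's d) on the latent trait.

    Defaults follow the gender, age and urbanicity contrasts observed for
    each instrument: men drink more (AUDIT d = 0.84), women report more
    depression and anxiety, younger respondents score slightly higher.
    """
    def aged(d: float) -> dict[str, float]:
        return {b: d for b in _YOUNG_BANDS}

    effects = {
        "AUDIT": {"gender": {"male": 0.84}, "age_group": aged(0.14), "region": {"urban": 0.03}},
        "CESD": {"gender": {"female": 0.35}, "region": {"rural": 0.08}},
        "GAD7": {"gender": {"female": 0.40}, "age_group": aged(0.09)},
        "ACQ": {"gender": {"female": 0.50}, "region": {"rural": 0.07}},
        "BSQ": {"gender": {"female": 0.49}, "age_group": aged(0.15), "region": {"rural": 0.07}},
    }
    try:
        return copy.deepcopy(effects[instrument_id.upper()])
    except KeyError:
        raise KeyError(f"no default trait effects for {instrument_id!r}") from None


@dataclass
class PopulationConfig:
    """Sampling design for a synthetic survey."""

    n_persons: int
    strata_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_STRATA)
    )
    trait_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for cov, probs in self.strata_proportions.items():
            if cov not in COVARIATE_LEVELS:
                raise ValueError(f"unknown covariate {cov!r}")
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"proportions for {cov!r} must sum to 1")
            unknown = set(probs) - set(COVARIATE_LEVELS[cov])
            if unknown:
                raise ValueError(f"unknown levels {sorted(unknown)} for {cov!r}")


@dataclass
class ItemBank:
    """A scale spec plus the generating GRM parameters (the simulation truth).

    ``group_params``, when present, holds the focal group's alternative
    parameters used for DIF injection; all non-manipulated items are shared.
    """

    spec: ScaleSpec
    params: GRMParams
    group_params: GRMParams | None = None

    def __post_init__(self) -> None:
        if list(self.params.item_ids) != list(self.spec.items):
            raise ValueError("bank parameters must cover exactly the spec's items")
        if self.group_params is not None and list(self.group_params.item_ids) != list(self.spec.items):
            raise ValueError("group parameters must cover exactly the spec's items")
        for k, bi in zip(self.spec.n_categories, self.params.b):
            if bi.size != k - 1:
                raise ValueError("threshold counts must match category counts")


# ---------------------------------------------------------------------------
# frozen default banks
#
# Thresholds are expressed as (first threshold + calibrated shift) followed
# by calibrated-scale gaps; the AUDIT shift/scale solve the 34%-zeros /
# 90%-at-or-below-6 marginals exactly on the quadrature grid (see
# scripts/calibrate_banks.py, which re-derives them).


def _bank_from_layout(
    spec: ScaleSpec,
    a: list[float],
    b1: list[float],
    gaps: list[list[float]],
    shift: float = 0.0,
    gap_scale: float = 1.0,
) -> ItemBank:
    b = []
    for first, g in zip(b1, gaps):
        cum = np.concatenate([[0.0], np.cumsum(np.asarray(g) * gap_scale)])
        b.append(first + shift + cum)
    return ItemBank(spec, GRMParams(list(spec.items), np.asarray(a), b))


_BANK_LAYOUTS: dict[str, dict] = {
    "AUDIT": {
        # consumption items (1-3) are endorsed far more often than the
        # dependence/problem items (4-10), which drives the zero inflation
        "a": [1.7, 2.0, 1.8, 1.9, 2.2, 2.0, 1.8, 2.1, 1.7, 1.9],
        "b1": [0.10, 0.45, 0.90, 1.45, 1.60, 1.50, 1.80, 1.70, 1.35, 1.65],
        "gaps": [[0.90, 0.85, 1.00]] * 3 + [[0.70, 0.65, 0.80]] * 7,
        "shift": 0.0317482914,
        "gap_scale": 1.6042086540,
    },
    "CESD": {
        "a": [1.6, 1.9, 2.1, 1.3, 1.8, 2.2, 1.7, 1.4, 2.0, 1.8,
              1.6, 1.5, 1.9, 2.1, 1.7, 1.4, 2.0, 2.2, 1.8, 1.6],
        "b1": [0.35, 0.55, 0.75, 1.05, 0.45, 0.65, 0.90, 1.15, 0.50, 0.70,
               0.95, 1.20, 0.40, 0.60, 0.85, 1.10, 0.55, 0.80, 1.00, 0.30],
        "gaps": [[1.00, 1.10]] * 20,
    },
    "GAD7": {
        "a": [2.2, 2.5, 2.3, 2.0, 2.4, 2.1, 1.9],
        "b1": [0.45, 0.60, 0.75, 0.95, 0.55, 0.85, 1.05],
        "gaps": [[1.00, 1.05]] * 7,
    },
    "ACQ": {
        # thoughts about catastrophic consequences of panic: rare in the
        # general population, hence hard first thresholds (floor-heavy)
        "a": [1.8, 2.0, 1.9, 1.7, 2.1, 1.8, 1.6, 1.9, 2.2, 1.8, 1.7, 2.0, 1.9, 1.8],
        "b1": [1.30, 1.55, 1.75, 2.00, 1.45, 1.65, 1.90, 1.40, 1.60, 1.85, 2.05, 1.50, 1.70, 1.95],
        "gaps": [[0.75, 0.70, 0.70]] * 14,
    },
    "BSQ": {
        "a": [2.0, 2.2, 1.9, 2.1, 2.3, 1.8, 2.0, 2.2, 1.9, 2.1, 1.8, 2.0, 2.3, 1.9, 2.1, 2.0, 1.8],
        "b1": [0.30, 0.50, 0.70, 0.95, 0.40, 0.60, 0.85, 0.35, 0.55, 0.80, 1.00, 0.45, 0.65, 0.90, 0.25, 0.75, 1.05],
        "gaps": [[0.85, 0.80, 0.90]] * 17,
    },
}


def default_item_bank(instrument_id: str) -> ItemBank:
    """The frozen generating item bank for one of the five instruments."""
    key = instrument_id.upper()
    if key not in _BANK_LAYOUTS:
        raise KeyError(f"unknown instrument {instrument_id!r}")
    layout = _BANK_LAYOUTS[key]
    return _bank_from_layout(
        builtin_spec(key),
        layout["a"],
        layout["b1"],
        layout["gaps"],
        layout.get("shift", 0.0),
        layout.get("gap_scale", 1.0),
    )


def score_distribution(params: GRMParams, grid: QuadratureGrid | None = None) -> np.ndarray:
    """Model-implied marginal distribution of the 0-based sum score."""
    grid = grid or default_grid(201, 8.0)
    L = sumscore_likelihoods(params, grid)
    return L @ grid.weights


# ---------------------------------------------------------------------------
# generation


def simulate_population(config: PopulationConfig) -> pd.DataFrame:
    """Independent draws of demographic covariates from the strata design."""
    rng = np.random.default_rng(config.seed)
    out = {}
    for cov, probs in config.strata_proportions.items():
        levels = [l for l in COVARIATE_LEVELS[cov] if l in probs]
        p = np.array([probs[l] for l in levels])
        out[cov] = pd.Categorical.from_codes(
            rng.choice(len(levels), size=config.n_persons, p=p / p.sum()),
            categories=levels,
        )
    return pd.DataFrame(out)


def simulate_traits(
    covariates: pd.DataFrame,
    effects: dict[str, dict[str, float]],
    seed: int,
) -> np.ndarray:
    """Latent trait: standard-normal noise plus subgroup shifts, re-standardized.

    Shifts are in SD units of the noise; because every group keeps unit
    within-group variance, the realized pooled-SD standardized difference
    between levels matches the configured shift (up to sampling error and
    small cross-covariate contamination).  The returned vector has overall
    mean 0 and SD 1 exactly.
    """
    n = len(covariates)
    rng = np.random.default_rng(seed)
    trait = rng.standard_normal(n)
    for cov, shifts in effects.items():
        if cov not in covariates.columns:
            raise KeyError(f"covariate {cov!r} not present in the population table")
        col = covariates[cov].astype(str)
        known = set(col.unique())
        unknown = set(shifts) - known
        if unknown:
            raise KeyError(f"effect levels {sorted(unknown)} absent from covariate {cov!r}")
        for level, d in shifts.items():
            trait = trait + d * (col == level).to_numpy()
    trait = trait - trait.mean()
    sd = trait.std()
    return trait / sd if sd > 0 else trait


def simulate_responses(
    bank: ItemBank,
    traits: np.ndarray,
    group: np.ndarray | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> ResponseMatrix:
    """Draw GRM responses at each person's trait value.

    ``group`` (boolean, focal = True) must be given exactly when the bank
    carries focal-group parameters.  A single uniform per response is
    compared against the item's cumulative curves, so the path is
    bit-reproducible under a fixed seed.
    """
    traits = np.asarray(traits, dtype=float)
    if (group is not None) != (bank.group_params is not None):
        raise ValueError("supply `group` exactly when the bank has group_params")
    rng = np.random.default_rng(seed)
    n = traits.size
    m = len(bank.spec.items)
    u = rng.random((n, m))
    resp = np.zeros((n, m), dtype=int)

    def fill(params: GRMParams, rows: np.ndarray) -> None:
        th = traits[rows]
        for j in range(m):
            cum = expit(params.a[j] * (th[:, None] - params.b[j]))  # P(X >= k)
            resp[rows, j] = (u[rows, j][:, None] < cum).sum(axis=1)

    if group is None:
        fill(bank.params, np.arange(n))
    else:
        group = np.asarray(group, dtype=bool)
        if group.size != n:
            raise ValueError("group indicator length must match traits")
        fill(bank.params, np.flatnonzero(~group))
        fill(bank.group_params, np.flatnonzero(group))

    cov = covariates if covariates is not None else pd.DataFrame(index=range(n))
    return ResponseMatrix(resp, list(bank.spec.items), cov.reset_index(drop=True))


def inject_dif(
    bank: ItemBank,
    item: str,
    kind: str,
    magnitude: float,
) -> ItemBank:
    """Return a bank whose focal group sees one item behave differently.

    ``uniform`` shifts all thresholds of ``item`` by ``+magnitude`` for the
    focal group (harder item at equal trait); ``nonuniform`` multiplies the
    focal discrimination by ``magnitude``.  Every other item is shared.
    """
    if item not in bank.spec.items:
        raise KeyError(f"item {item!r} not in bank")
    base = bank.group_params or bank.params
    a = base.a.copy()
    b = [bi.copy() for bi in base.b]
    j = bank.spec.items.index(item)
    if kind == "uniform":
        b[j] = b[j] + magnitude
    elif kind == "nonuniform":
        if magnitude <= 0:
            raise ValueError("discrimination ratio must be positive")
        a[j] = a[j] * magnitude
    else:
        raise ValueError("kind must be 'uniform' or 'nonuniform'")
    return ItemBank(bank.spec, bank.params, GRMParams(list(base.item_ids), a, b))


def add_missing(matrix: ResponseMatrix, rate: float, seed: int) -> ResponseMatrix:
    """Knock out responses completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    resp = matrix.responses.copy()
    resp[rng.random(resp.shape) < rate] = MISSING
    return ResponseMatrix(resp, list(matrix.item_ids), matrix.covariates)


def simulate_dataset(
    instrument_id: str,
    n_persons: int,
    seed: int,
    trait_effects: dict | None = None,
    missing_rate: float = 0.0,
) -> tuple[ResponseMatrix, dict]:
    """Population + traits + responses for one instrument, plus the truth.

    Returns the response matrix (with covariates attached) and a dictionary
    with the generating bank, traits and seeds, for recovery tests.
    """
    bank = default_item_bank(instrument_id)
    effects = trait_effects if trait_effects is not None else default_trait_effects(instrument_id)
    config = PopulationConfig(n_persons, trait_effects=effects, seed=seed)
    cov = simulate_population(config)
    traits = simulate_traits(cov, effects, seed + 1)
    matrix = simulate_responses(bank, traits, seed=seed + 2, covariates=cov)
    if missing_rate > 0:
        matrix = add_missing(matrix, missing_rate, seed + 3)
    truth = {
        "instrument": bank.spec.instrument_id,
        "bank": bank.params.to_dict(),
        "traits": traits,
        "effects": effects,
        "seed": seed,
    }
    return matrix, truth


def save_responses(matrix: ResponseMatrix, spec: ScaleSpec, path) -> None:
    """Write responses + covariates as CSV with offset-restored codes."""
    cols = {}
    for j, item in enumerate(spec.items):
        col = matrix.responses[:, j].astype(float) + spec.response_offset
        col[matrix.responses[:, j] == MISSING] = np.nan
        cols[item] = pd.array(col).astype("Int64")
    df = pd.DataFrame(cols)
    for c in matrix.covariates.columns:
        df[c] = matrix.covariates[c].astype(str)
    df.to_csv(path, index=False, na_rep="NA")
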