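"""Instrument definitions, response matrices and raw-score computation.

The pipeline norms five mental-health screeners: the AUDIT (alcohol use,
10 items, 0-4), the CES-D (depression, 20 items, 0-3), the GAD-7 (anxiety,
7 items, 0-3), and the ACQ and BSQ (fear of fear, 14 and 17 items, 1-5,
mean-scored).  A :class:`ScaleSpec` captures an instrument's items,
response-category counts, the printed value of the lowest category
(``response_offset``) and whether raw scores are sums or item means.

Responses are held 0-based internally (observed code minus the offset);
the offset is restored only when presenting mean scores.  The delimited
dialect everywhere is comma-separated UTF-8 with ``NA`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleSpec",
    "ResponseMatrix",
    "COVARIATE_LEVELS",
    "builtin_spec",
    "BUILTIN_INSTRUMENTS",
    "load_scale_spec",
    "save_scale_spec",
    "load_responses",
    "raw_scores",
    "write_table",
]

MISSING = -1

#: Declared level sets for the demographic covariates carried with responses.
COVARIATE_LEVELS = {
    "gender": ["female", "male"],
    "age_group": ["16-19", "20-29", "30-39", "40-49", "50-59", "60-69"],
    "region": ["urban", "rural"],
    "education": ["primary", "secondary", "higher"],
}


@dataclass
class ScaleSpec:
    """Definition of one instrument: items, categories, scoring, subscales."""

    instrument_id: str
    items: list[str]
    n_categories: list[int]
    response_offset: int = 0
    score_type: str = "sum"
    subscales: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("items must be non-empty")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item ids")
        if isinstance(self.n_categories, int):
            self.n_categories = [self.n_categories] * len(self.items)
        if len(self.n_categories) != len(self.items):
            raise ValueError("n_categories must match items")
        if any(k < 2 for k in self.n_categories):
            raise ValueError("every item needs at least 2 response categories")
        if self.score_type not in ("sum", "mean"):
            raise ValueError("score_type must be 'sum' or 'mean'")
        for name, sub in self.subscales.items():
            unknown = set(sub) - set(self.items)
            if unknown:
                raise ValueError(f"subscale {name!r} references unknown items {sorted(unknown)}")
            if not sub:
                raise ValueError(f"subscale {name!r} is empty")

    def categories_of(self, item: str) -> int:
        return self.n_categories[self.items.index(item)]

    def subscale_spec(self, name: str | None) -> "ScaleSpec":
        """The spec restricted to one subscale (or itself when name is None)."""
        if name is None:
            return self
        if name not in self.subscales:
            raise KeyError(f"unknown subscale {name!r} of {self.instrument_id}")
        sub = self.subscales[name]
        return ScaleSpec(
            f"{self.instrument_id}_{name}" if not name.startswith(self.instrument_id) else name,
            list(sub),
            [self.categories_of(i) for i in sub],
            self.response_offset,
            self.score_type,
        )

    @property
    def max_sum(self) -> int:
        """Maximum achievable 0-based sum score."""
        return sum(k - 1 for k in self.n_categories)

    def to_dict(self) -> dict:
        return {
            "instrument_id": self.instrument_id,
            "items": list(self.items),
            "n_categories": list(self.n_categories),
            "response_offset": self.response_offset,
            "score_type": self.score_type,
            "subscales": {k: list(v) for k, v in self.subscales.items()},
        }


def _make_items(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, n + 1)]


def _builtin() -> dict[str, ScaleSpec]:
    audit = _make_items("audit", 10)
    acq = _make_items("acq", 14)
    return {
        "AUDIT": ScaleSpec(
            "AUDIT", audit, [5] * 10, 0, "sum",
            {"USE": audit[:3], "PRO": audit[3:]},
        ),
        "CESD": ScaleSpec("CESD", _make_items("cesd", 20), [4] * 20, 0, "sum"),
        "GAD7": ScaleSpec("GAD7", _make_items("gad", 7), [4] * 7, 0, "sum"),
        # Default factor layout: social/behavioral concerns first, physical
        # concerns second; override via a custom spec file if needed.
        "ACQ": ScaleSpec(
            "ACQ", acq, [5] * 14, 1, "mean",
            {"SC": acq[:7], "PHY": acq[7:]},
        ),
        "BSQ": ScaleSpec("BSQ", _make_items("bsq", 17), [5] * 17, 1, "mean"),
    }


BUILTIN_INSTRUMENTS = _builtin()


def builtin_spec(instrument_id: str) -> ScaleSpec:
    """Bundled definition of one of the five study instruments."""
    try:
        spec = BUILTIN_INSTRUMENTS[instrument_id.upper()]
    except KeyError:
        raise KeyError(
            f"unknown instrument {instrument_id!r}; bundled: {sorted(BUILTIN_INSTRUMENTS)}"
        ) from None
    return ScaleSpec(**spec.to_dict())


# ---------------------------------------------------------------------------
# response container


@dataclass
class ResponseMatrix:
    """Persons x items 0-based integer codes plus demographic covariates.

    ``responses[p, i] == -1`` marks a missing answer.  ``covariates`` is a
    per-person DataFrame whose columns are restricted to declared level sets.
    """

    responses: np.ndarray
    item_ids: list[str]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2 or self.responses.shape[1] != len(self.item_ids):
            raise ValueError("responses must be persons x items matching item_ids")
        if len(self.covariates) not in (0, self.responses.shape[0]):
            raise ValueError("covariates must have one row per person (or be empty)")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    def columns(self, items: list[str]) -> np.ndarray:
        idx = [self.item_ids.index(i) for i in items]
        return self.responses[:, idx]

    def complete_mask(self, items: list[str] | None = None) -> np.ndarray:
        cols = self.columns(items) if items is not None else self.responses
        return np.all(cols != MISSING, axis=1)

    def all_missing_mask(self) -> np.ndarray:
        return np.all(self.responses == MISSING, axis=1)

    def subset(self, mask: np.ndarray) -> "ResponseMatrix":
        cov = self.covariates.loc[mask].reset_index(drop=True) if len(self.covariates) else self.covariates
        return ResponseMatrix(self.responses[mask], list(self.item_ids), cov)


# ---------------------------------------------------------------------------
# file IO


def load_scale_spec(path) -> ScaleSpec:
    """Read a YAML scale definition; invariant violations are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ScaleSpec(
        instrument_id=raw["instrument_id"],
        items=list(raw["items"]),
        n_categories=raw["n_categories"],
        response_offset=int(raw.get("response_offset", 0)),
        score_type=raw.get("score_type", "sum"),
        subscales={k: list(v) for k, v in (raw.get("subscales") or {}).items()},
    )


def save_scale_spec(spec: ScaleSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_responses(path, spec: ScaleSpec, covariate_cols: list[str] | None = None) -> ResponseMatrix:
    """Read a persons x items CSV, shift codes to 0-base and validate.

    Item columns are matched by item id; covariate columns default to every
    declared covariate present in the file.  Out-of-range codes are reported
    with their row and column.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing_cols = [i for i in spec.items if i not in df.columns]
    if missing_cols:
        raise ValueError(f"response file lacks item columns {missing_cols}")
    if covariate_cols is None:
        covariate_cols = [c for c in COVARIATE_LEVELS if c in df.columns]

    n = len(df)
    resp = np.full((n, len(spec.items)), MISSING, dtype=int)
    for j, item in enumerate(spec.items):
        col = df[item]
        obs = col.notna()
        vals = col[obs].astype(float)
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integer response codes in column {item!r}")
        codes = vals.round().astype(int) - spec.response_offset
        bad = (codes < 0) | (codes >= spec.n_categories[j])
        if bad.any():
            row = codes.index[bad][0]
            raise ValueError(
                f"response {df.loc[row, item]!r} out of range for item {item!r} (row {row})"
            )
        resp[obs.to_numpy(), j] = codes.to_numpy()

    cov = pd.DataFrame(index=range(n))
    for c in covariate_cols:
        levels = COVARIATE_LEVELS.get(c)
        vals = df[c].astype("string").str.strip().str.lower()
        if levels is not None:
            bad = vals.notna() & ~vals.isin(levels)
            if bad.any():
                raise ValueError(
                    f"unparseable level {vals[bad].iloc[0]!r} in covariate {c!r}; "
                    f"expected one of {levels}"
                )
            cov[c] = pd.Categorical(vals, categories=levels)
        else:
            cov[c] = vals
    return ResponseMatrix(resp, list(spec.items), cov)


# ---------------------------------------------------------------------------
# scoring


def raw_scores(
    matrix: ResponseMatrix,
    spec: ScaleSpec,
    subscale: str | None = None,
    prorate: bool = False,
) -> pd.DataFrame:
    """Per-person raw scores for a scale or one of its subscales.

    Sum-scored scales return the integer sum of 0-based codes; mean-scored
    scales return the mean of offset-restored codes (carried as an exact
    rational and rendered at presentation).  By default a person is scored
    only when every item is answered (``complete``); with ``prorate=True``
    partially answered persons get the scaled mean of their answered items.
    """
    sub = spec.subscale_spec(subscale)
    if not sub.items:
        raise ValueError("empty item set")
    cols = matrix.columns(sub.items)
    answered = cols != MISSING
    n_ans = answered.sum(axis=1)
    complete = n_ans == len(sub.items)
    sums = np.where(answered, cols, 0).sum(axis=1)

    score = np.full(matrix.n_persons, np.nan)
    if sub.score_type == "sum":
        score[complete] = sums[complete]
        if prorate:
            part = (n_ans > 0) & ~complete
            score[part] = sums[part] / n_ans[part] * len(sub.items)
    else:
        scored = complete | (prorate & (n_ans > 0))
        with np.errstate(invalid="ignore"):
            score[scored] = sums[scored] / n_ans[scored] + sub.response_offset
    return pd.DataFrame({"score": score, "complete": complete, "n_answered": n_ans})


def mean_score_value(sum_code: int, n_items: int, offset: int) -> Fraction:
    """Exact rational presented value of a mean score from its 0-based sum."""
    return Fraction(sum_code, n_items) + offset


# ---------------------------------------------------------------------------
# table output

#: fixed presentation precision by column name
_DECIMALS = {"T": 1, "T_equation": 1, "theta": 2, "se": 2, "percentile": 4, "raw": 2}


def write_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as CSV with a deterministic layout.

    Columns keep their existing order; floats are rendered at fixed
    precision (1 decimal for T, 2 for theta/SE, 4 for percentiles).
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty table")
    out = rows.copy()
    for col in out.columns:
        nd = _DECIMALS.get(col)
        if nd is not None and pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v, nd=nd: "" if pd.isna(v) else f"{v:.{nd}f}")
    out.to_csv(path, index=False, na_rep="NA")
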