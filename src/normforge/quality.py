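"""Scale-quality diagnostics: Mokken scalability, monotonicity, local dependence.

Three checks complement the parametric IRT machinery:

* **Mokken's H** — the ratio of observed inter-item covariance to the
  maximum attainable given the item marginals (the comonotonic coupling).
  H = 1 for a perfect Guttman scale; interpretation bands follow common
  practice (0.3 <= H < 0.4 low, 0.4 <= H < 0.5 moderate, >= 0.5 high
  quality).  The polytomous generalization is used throughout; the
  dichotomous formula is its special case.

* **Monotonicity** — item mean scores as a function of the rest score
  (total minus the item), with rest-score groups merged to a minimum size;
  any decrease across ordered groups is a violation.

* **Yen's Q3** — the correlation, across persons, of residuals
  (observed code minus model-expected code at the person's EAP trait) for
  each item pair.  Values in [0.24, 0.37) indicate moderate and >= 0.37
  large local dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRMParams, QuadratureGrid, category_probs, default_grid, eap_pattern

__all__ = [
    "MokkenResult",
    "mokken_h",
    "monotonicity_check",
    "yen_q3",
    "QualityReport",
    "quality_report",
    "H_BANDS",
    "Q3_MODERATE",
    "Q3_LARGE",
]

H_BANDS = ((0.30, "low"), (0.40, "moderate"), (0.50, "high"))
Q3_MODERATE = 0.24
Q3_LARGE = 0.37


def interpret_h(h: float) -> str:
    if h < 0.30:
        return "unscalable"
    if h < 0.40:
        return "low"
    if h < 0.50:
        return "moderate"
    return "high"


@dataclass
class MokkenResult:
    scale_h: float
    item_h: pd.Series
    pair_h: pd.DataFrame
    interpretation: str


def _max_cov(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum covariance attainable given the two marginals (sort coupling)."""
    xs = np.sort(x)
    ys = np.sort(y)
    return float(np.mean(xs * ys) - xs.mean() * ys.mean())


def mokken_h(responses: np.ndarray, item_ids: list[str] | None = None) -> MokkenResult:
    """Scalability coefficients H_ij, H_i and scale H (complete cases)."""
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a persons x items array with at least 3 items")
    if np.any(X < 0):
        raise ValueError("Mokken H requires complete cases")
    m = X.shape[1]
    ids = item_ids or [f"item_{j + 1}" for j in range(m)]
    if np.any(X.std(axis=0) == 0):
        bad = [ids[j] for j in range(m) if X[:, j].std() == 0]
        raise ValueError(f"zero-variance items {bad}")

    cov = np.cov(X.T, ddof=0)
    cmax = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            cmax[i, j] = cmax[j, i] = _max_cov(X[:, i], X[:, j])

    with np.errstate(divide="ignore", invalid="ignore"):
        pair = np.where(cmax != 0, cov / np.where(cmax == 0, 1, cmax), np.nan)
    np.fill_diagonal(pair, np.nan)
    off = ~np.eye(m, dtype=bool)
    item_h = np.array(
        [cov[j, off[j]].sum() / cmax[j, off[j]].sum() for j in range(m)]
    )
    iu = np.triu_indices(m, 1)
    scale_h = float(cov[iu].sum() / cmax[iu].sum())
    return MokkenResult(
        scale_h,
        pd.Series(item_h, index=ids),
        pd.DataFrame(pair, index=ids, columns=ids),
        interpret_h(scale_h),
    )


def monotonicity_check(
    responses: np.ndarray,
    item_ids: list[str] | None = None,
    min_group_size: int = 50,
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Decreases of item mean scores across ordered rest-score groups.

    Rest scores are grouped by value and adjacent groups merged (bottom-up)
    until each holds at least ``min_group_size`` persons; a trailing
    undersized group is merged backwards.  Returns per item the number of
    adjacent decreases exceeding ``tolerance`` and the largest decrease.
    """
    X = np.asarray(responses)
    if np.any(X < 0):
        raise ValueError("monotonicity check requires complete cases")
    n, m = X.shape
    if n < 2 * min_group_size:
        raise ValueError("too few persons to form two rest-score groups")
    ids = item_ids or [f"item_{j + 1}" for j in range(m)]
    total = X.sum(axis=1)

    rows = []
    for j in range(m):
        rest = total - X[:, j]
        order = np.unique(rest)
        # merge adjacent rest-score values until groups reach the minimum size
        groups: list[np.ndarray] = []
        current = np.zeros(n, dtype=bool)
        for v in order:
            current |= rest == v
            if current.sum() >= min_group_size:
                groups.append(current.copy())
                current[:] = False
        if current.any():
            if groups:
                groups[-1] |= current
            else:
                groups.append(current.copy())
        means = np.array([X[g, j].mean() for g in groups])
        if means.size < 2:
            rows.append({"item": ids[j], "n_groups": means.size, "violations": 0,
                         "max_violation": 0.0})
            continue
        drops = -np.diff(means)
        rows.append({
            "item": ids[j],
            "n_groups": means.size,
            "violations": int(np.sum(drops > tolerance)),
            "max_violation": float(max(drops.max(), 0.0)),
        })
    return pd.DataFrame(rows).set_index("item")


def yen_q3(
    responses: np.ndarray,
    params: GRMParams,
    grid: QuadratureGrid | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Q3 local-dependence matrix and its summary.

    Residuals are observed codes minus model-expected codes at each
    person's full-pattern EAP trait; Q3 of a pair is the Pearson
    correlation of those residuals.  The summary reports the largest
    absolute off-diagonal pair and the counts of pairs in the moderate
    ([0.24, 0.37)) and large (>= 0.37) bands.
    """
    X = np.asarray(responses)
    if np.any(X < 0):
        raise ValueError("Q3 requires complete cases")
    grid = grid or default_grid()
    m = X.shape[1]
    if m < 2:
        raise ValueError("need at least 2 items")
    theta, _ = eap_pattern(X, params, grid)
    resid = np.empty(X.shape, dtype=float)
    for j in range(m):
        p = category_probs(params.a[j], params.b[j], theta)  # n x K
        expected = p @ np.arange(p.shape[1])
        resid[:, j] = X[:, j] - expected
    sds = resid.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("degenerate residual variance")
    q3 = np.corrcoef(resid.T)
    np.fill_diagonal(q3, np.nan)
    ids = list(params.item_ids)
    frame = pd.DataFrame(q3, index=ids, columns=ids)

    iu = np.triu_indices(m, 1)
    vals = q3[iu]
    k = int(np.nanargmax(np.abs(vals)))
    summary = {
        "max_pair": (ids[iu[0][k]], ids[iu[1][k]]),
        "max_abs_q3": float(abs(vals[k])),
        "max_q3_signed": float(vals[k]),
        "n_moderate": int(np.sum((np.abs(vals) >= Q3_MODERATE) & (np.abs(vals) < Q3_LARGE))),
        "n_large": int(np.sum(np.abs(vals) >= Q3_LARGE)),
        "n_pairs": int(vals.size),
    }
    return frame, summary


@dataclass
class QualityReport:
    scale_h: float
    h_interpretation: str
    item_h: dict
    monotonicity: dict
    q3_summary: dict


def quality_report(
    responses: np.ndarray,
    params: GRMParams,
    item_ids: list[str] | None = None,
    grid: QuadratureGrid | None = None,
    min_group_size: int = 50,
) -> QualityReport:
    """Bundle the three diagnostics for one calibrated scale."""
    ids = item_ids or list(params.item_ids)
    mok = mokken_h(responses, ids)
    mono = monotonicity_check(responses, ids, min_group_size)
    _, q3s = yen_q3(responses, params, grid)
    return QualityReport(
        mok.scale_h,
        mok.interpretation,
        mok.item_h.round(4).to_dict(),
        mono.to_dict(orient="index"),
        q3s,
    )
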