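"""Raw-score -> theta -> normalized-T crosswalk tables and conversion equations.

A crosswalk table assigns every achievable raw score its EAP trait estimate
(from the summed-score posterior), its mid-rank percentile in the norming
sample, and a *normalized* T-score::

    percentile(s) = (count below s + count at s / 2) / total
    T(s)          = 50 + 10 * Phi^-1(percentile(s))

The normalization is rank-based, so T depends on the score distribution
only through ranks — any strictly monotone rescaling of the raw metric
yields the same person-level T.  Raw scores unobserved in the sample get T
by monotone interpolation on the theta scale between flanking observed
scores, so the T column stays strictly increasing.

Closed-form conversion equations (twelve families, from linear through
sigmoid) are fitted to the table by least squares and compared by BIC;
agreement between table-based and equation-based person-level T is
summarized with the two-way absolute-agreement single-measures ICC and
Bland-Altman limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtri

from .grm import GRMParams, QuadratureGrid, default_grid, eap_sum_table
from .scales import ResponseMatrix, ScaleSpec, raw_scores

__all__ = [
    "normalized_t",
    "build_crosswalk",
    "CrosswalkEquation",
    "EQUATION_FAMILIES",
    "fit_conversion_equation",
    "evaluate_equation",
    "validate_conversion",
    "icc_agreement",
    "person_t_scores",
]


def normalized_t(score_frequencies: pd.Series) -> pd.DataFrame:
    """Mid-rank percentile and normalized T for each observed raw score.

    ``score_frequencies`` maps score -> count (index = score).  Scores with
    zero frequency are dropped: their percentile is undefined and their T is
    later interpolated on the theta scale by :func:`build_crosswalk`.
    """
    freq = score_frequencies[score_frequencies > 0].sort_index()
    if len(freq) == 0:
        raise ValueError("empty frequency table")
    total = freq.sum()
    below = freq.cumsum() - freq
    pct = (below + freq / 2) / total
    t = 50 + 10 * ndtri(pct.to_numpy(dtype=float))
    return pd.DataFrame({"percentile": pct, "T": t}, index=freq.index)


def person_t_scores(scores: np.ndarray) -> np.ndarray:
    """Normalized T per person from their own sample's score distribution."""
    s = pd.Series(scores).dropna()
    table = normalized_t(s.value_counts())
    return pd.Series(scores).map(table["T"]).to_numpy()


def build_crosswalk(
    matrix: ResponseMatrix,
    spec: ScaleSpec,
    params: GRMParams,
    subscale: str | None = None,
    group_mask: np.ndarray | None = None,
    grid: QuadratureGrid | None = None,
    min_group_size: int = 50,
    t_metric: str = "normalized",
) -> pd.DataFrame:
    """One row per achievable raw score: frequency, EAP theta, SE, percentile, T.

    Mean-scored scales enumerate achievable 0-based sums and present
    ``sum / n_items + offset`` in the ``raw`` column.  When ``group_mask``
    is given the score frequencies (hence percentiles and T) come from that
    subgroup while the item parameters stay pooled.

    ``t_metric`` selects the T definition: ``"normalized"`` (default) is the
    rank-based mid-rank/inverse-normal conversion; ``"linear"`` instead sets
    T = 50 + 10 * standardized EAP theta (standardized over the scored
    sample), which preserves the shape of the theta distribution.
    """
    if t_metric not in ("normalized", "linear"):
        raise ValueError("t_metric must be 'normalized' or 'linear'")
    sub = spec.subscale_spec(subscale)
    if list(params.item_ids) != list(sub.items):
        raise ValueError("params do not match the scale's items")
    grid = grid or default_grid()

    scored = raw_scores(matrix, spec, subscale)
    complete = matrix.complete_mask(sub.items)
    if group_mask is not None:
        group_mask = np.asarray(group_mask, dtype=bool)
        n_scored = int((complete & group_mask).sum())
        if n_scored < min_group_size:
            raise ValueError(f"subgroup has {n_scored} scored persons (< {min_group_size})")
        complete = complete & group_mask

    sums = matrix.columns(sub.items)[complete].sum(axis=1)
    eap = eap_sum_table(params, grid)
    n_scores = params.max_score + 1
    freq = pd.Series(np.bincount(sums, minlength=n_scores), index=np.arange(n_scores))

    nt = normalized_t(freq)
    theta = eap.theta
    T = np.full(n_scores, np.nan)
    pct = np.full(n_scores, np.nan)
    obs = nt.index.to_numpy()
    pct[obs] = nt["percentile"].to_numpy()
    if t_metric == "linear":
        person_theta = theta[sums]
        T[:] = 50 + 10 * (theta - person_theta.mean()) / person_theta.std()
    else:
        T[obs] = nt["T"].to_numpy()
    # unobserved scores: interpolate T monotonically on the theta scale
    gaps = np.flatnonzero(np.isnan(T))
    if gaps.size:
        T[gaps] = np.interp(theta[gaps], theta[obs], T[obs])
        # beyond the observed extremes np.interp clamps; extrapolate linearly
        # in theta from the two flanking observed scores to keep T strictly
        # increasing over the whole table
        if obs.size >= 2:
            lo, lo2 = obs[0], obs[1]
            hi2, hi = obs[-2], obs[-1]
            slope_lo = (T[lo2] - T[lo]) / (theta[lo2] - theta[lo])
            slope_hi = (T[hi] - T[hi2]) / (theta[hi] - theta[hi2])
            below = gaps[gaps < lo]
            above = gaps[gaps > hi]
            T[below] = T[lo] + slope_lo * (theta[below] - theta[lo])
            T[above] = T[hi] + slope_hi * (theta[above] - theta[hi])

    if sub.score_type == "mean":
        raw = np.arange(n_scores) / len(sub.items) + sub.response_offset
    else:
        raw = np.arange(n_scores).astype(float)
    return pd.DataFrame(
        {
            "raw": raw,
            "sum": np.arange(n_scores),
            "freq": freq.to_numpy(),
            "theta": theta,
            "se": eap.se,
            "percentile": pct,
            "T": T,
            "observed": freq.to_numpy() > 0,
        }
    )


# ---------------------------------------------------------------------------
# conversion equations


@dataclass
class CrosswalkEquation:
    """A fitted closed-form raw -> T conversion."""

    family: str
    coef: np.ndarray
    rss: float
    bic: float
    n_points: int
    x_range: tuple[float, float]
    x_shift: float = 0.0  # families needing positive x evaluate at (x - x_shift)
    icc: float | None = None
    bias: float | None = None
    loa: tuple[float, float] | None = None


def _poly(degree):
    def f(x, c):
        return np.polyval(c, x)

    return f


# Each family: (#coefficients, evaluator(x, coef), start generator(x, y)).
# Families with a positive-argument requirement (log, power, hyperbolic,
# rational pole) receive x already shifted so min(x) = 1.
def _starts_generic(n_coef: int) -> list[np.ndarray]:
    base = [
        np.full(n_coef, 0.1),
        np.full(n_coef, 1.0),
        np.linspace(0.5, 2.0, n_coef),
        np.full(n_coef, -0.5),
        np.linspace(-1.0, 1.0, n_coef) + 0.3,
    ]
    return base


def _eval_family(family: str, x: np.ndarray, c: np.ndarray) -> np.ndarray:
    if family == "linear":
        return c[0] + c[1] * x
    if family == "poly2":
        return c[0] + c[1] * x + c[2] * x**2
    if family == "poly3":
        return c[0] + c[1] * x + c[2] * x**2 + c[3] * x**3
    if family == "exponential":
        return c[0] + c[1] * np.exp(np.clip(c[2] * x, -500, 500))
    if family == "logarithmic":
        return c[0] + c[1] * np.log(x)
    if family == "power":
        return c[0] + c[1] * np.sign(x) * np.abs(x) ** c[2]
    if family == "rational":
        return (c[0] + c[1] * x) / (1.0 + np.abs(c[2]) * x)
    if family == "sigmoid":
        return c[0] + c[1] / (1.0 + np.exp(np.clip(-(x - c[2]) / np.abs(c[3]), -500, 500)))
    if family == "hyperbolic":
        return c[0] + c[1] / x
    if family == "exp_linear":
        return c[0] + c[1] * np.exp(np.clip(c[2] * x, -500, 500)) + c[3] * x
    if family == "log_linear":
        return c[0] + c[1] * np.log(x) + c[2] * x
    if family == "power_linear":
        return c[0] + c[1] * np.sign(x) * np.abs(x) ** c[2] + c[3] * x
    raise KeyError(f"unknown equation family {family!r}")


#: family -> (coefficient count, requires x shifted to min 1)
EQUATION_FAMILIES: dict[str, tuple[int, bool]] = {
    "linear": (2, False),
    "poly2": (3, False),
    "poly3": (4, False),
    "exponential": (3, False),
    "logarithmic": (2, True),
    "power": (3, True),
    "rational": (3, True),
    "sigmoid": (4, False),
    "hyperbolic": (2, True),
    "exp_linear": (4, False),
    "log_linear": (3, True),
    "power_linear": (4, True),
}


def _family_starts(family: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Five deterministic starts per family, anchored at simple fits."""
    ybar, yspan = float(np.mean(y)), float(np.ptp(y)) or 1.0
    xmid = float(np.median(x))
    lin = np.polyfit(x, y, 1)
    starts: list[np.ndarray] = []
    if family == "linear":
        return [lin[::-1]]
    if family in ("poly2", "poly3"):
        deg = 2 if family == "poly2" else 3
        return [np.polyfit(x, y, deg)[::-1]]
    if family == "exponential":
        for c2 in (0.05, 0.2, -0.2, 0.5, -0.05):
            starts.append(np.array([ybar, yspan / 4 * np.sign(c2), c2]))
    elif family == "logarithmic":
        c1 = yspan / (np.log(x.max()) - np.log(x.min()) or 1.0)
        for m in (1.0, 0.5, 2.0, -1.0, 0.25):
            starts.append(np.array([y[0], c1 * m]))
    elif family == "power":
        for c2 in (0.5, 1.0, 2.0, 0.25, 1.5):
            starts.append(np.array([y[0], yspan / (x.max() ** c2), c2]))
    elif family == "rational":
        for c2 in (0.01, 0.1, 0.5, 1.0, 0.05):
            starts.append(np.array([y[0], lin[0], c2]))
    elif family == "sigmoid":
        for c3 in (1.0, 2.0, 5.0, 0.5, np.ptp(x) / 4 or 1.0):
            starts.append(np.array([y.min(), yspan, xmid, c3]))
    elif family == "hyperbolic":
        for m in (1.0, -1.0, 0.5, -0.5, 2.0):
            starts.append(np.array([ybar, m * yspan]))
    elif family == "exp_linear":
        for c2 in (0.05, 0.2, -0.2, 0.5, -0.05):
            starts.append(np.array([ybar, yspan / 4 * np.sign(c2), c2, lin[0]]))
    elif family == "log_linear":
        c1 = yspan / (np.log(x.max()) - np.log(x.min()) or 1.0)
        for m in (1.0, 0.5, 2.0, -1.0, 0.25):
            starts.append(np.array([y[0], c1 * m, lin[0] / 2]))
    elif family == "power_linear":
        for c2 in (0.5, 1.0, 2.0, 0.25, 1.5):
            starts.append(np.array([y[0], yspan / (x.max() ** c2), c2, lin[0] / 2]))
    else:
        starts = _starts_generic(EQUATION_FAMILIES[family][0])
    return starts


def _bic(rss: float, n: int, n_coef: int) -> float:
    # Gaussian profile likelihood; the error variance counts as a parameter
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + (n_coef + 1) * np.log(n)


def fit_conversion_equation(
    table: pd.DataFrame,
    families: list[str] | None = None,
    weight_by_freq: bool = False,
) -> tuple[CrosswalkEquation, list[CrosswalkEquation]]:
    """Fit T on raw score for each family; the lowest BIC wins.

    Only observed scores enter the fit.  A family that fails to converge is
    recorded with infinite BIC and skipped.  Ties in BIC break toward fewer
    coefficients.
    """
    obs = table[table["observed"]] if "observed" in table else table
    x = obs["raw"].to_numpy(dtype=float)
    y = obs["T"].to_numpy(dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observed scores to fit conversion equations")
    w = np.sqrt(obs["freq"].to_numpy(dtype=float)) if weight_by_freq else np.ones_like(x)
    families = families or list(EQUATION_FAMILIES)

    candidates: list[CrosswalkEquation] = []
    for fam in families:
        n_coef, needs_pos = EQUATION_FAMILIES[fam]
        shift = float(x.min() - 1.0) if needs_pos else 0.0
        xs = x - shift
        best = None
        for c0 in _family_starts(fam, xs, y):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = least_squares(
                        lambda c: w * (_eval_family(fam, xs, c) - y),
                        c0,
                        method="lm",
                        max_nfev=2000,
                    )
                rss = float(np.sum((_eval_family(fam, xs, res.x) - y) ** 2))
                if np.isfinite(rss) and (best is None or rss < best[0]):
                    best = (rss, res.x)
            except Exception:
                continue
        if best is None:
            candidates.append(
                CrosswalkEquation(fam, np.full(n_coef, np.nan), np.inf, np.inf, x.size,
                                  (float(x.min()), float(x.max())), shift)
            )
            continue
        rss, coef = best
        candidates.append(
            CrosswalkEquation(
                fam, coef, rss, _bic(rss, x.size, n_coef), x.size,
                (float(x.min()), float(x.max())), shift,
            )
        )

    ranked = sorted(candidates, key=lambda e: (round(e.bic, 6), len(e.coef)))
    return ranked[0], candidates


def evaluate_equation(eq: CrosswalkEquation, raw, warn_extrapolation: bool = True) -> np.ndarray:
    """Deterministic evaluation of a fitted family at its stored coefficients."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = eq.x_range
    if warn_extrapolation and (np.any(raw < lo) or np.any(raw > hi)):
        warnings.warn(
            f"evaluating {eq.family} equation outside the fitted range [{lo}, {hi}]",
            stacklevel=2,
        )
    return _eval_family(eq.family, raw - eq.x_shift, eq.coef)


# ---------------------------------------------------------------------------
# agreement validation


def icc_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute agreement, single measures (two raters)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 observations")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    return float((msr - mse) / denom) if denom != 0 else 1.0


def validate_conversion(
    table: pd.DataFrame,
    eq: CrosswalkEquation,
    matrix: ResponseMatrix,
    spec: ScaleSpec,
    subscale: str | None = None,
) -> dict:
    """Person-level agreement between table-based and equation-based T.

    Each scored person receives the crosswalk T of their raw score and the
    equation's prediction at the same score; agreement is summarized with
    ICC(A,1), the Bland-Altman mean difference (equation minus table) and
    its 95% limits of agreement.
    """
    sub = spec.subscale_spec(subscale)
    complete = matrix.complete_mask(sub.items)
    sums = matrix.columns(sub.items)[complete].sum(axis=1)
    if sums.size < 3:
        raise ValueError("fewer than 3 scored persons")
    t_table = table.set_index("sum").loc[sums, "T"].to_numpy()
    raw = table.set_index("sum").loc[sums, "raw"].to_numpy()
    t_eq = evaluate_equation(eq, raw, warn_extrapolation=False)
    diff = t_eq - t_table
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    icc = icc_agreement(t_table, t_eq)
    return {
        "icc": icc,
        "bias": bias,
        "loa": (bias - 1.96 * sd, bias + 1.96 * sd),
        "n": int(sums.size),
    }
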