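"""Distribution summaries, subgroup comparisons and representativeness checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptiveStats",
    "GroupComparison",
    "moments",
    "compare_groups",
    "gof_chi2",
    "reference_means",
]


@dataclass
class DescriptiveStats:
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    skewness: float
    kurtosis: float  # excess kurtosis: 0 for a normal distribution
    defined: bool = True


def moments(values: np.ndarray, sample_adjusted: bool = False) -> DescriptiveStats:
    """Mean, SD, range, skewness g1 = m3/m2^1.5 and excess kurtosis g2 = m4/m2^2 - 3.

    ``sample_adjusted=True`` applies the small-sample bias corrections
    (the G1/G2 estimators); the plain moment versions are the default.
    A constant vector has undefined shape moments, reported via ``defined``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    sd = float(np.sqrt(m2 * n / (n - 1)))
    if m2 == 0:
        return DescriptiveStats(n, m, 0.0, float(v.min()), float(v.max()),
                                np.nan, np.nan, defined=False)
    g1 = float(stats.skew(v, bias=not sample_adjusted))
    g2 = float(stats.kurtosis(v, fisher=True, bias=not sample_adjusted))
    return DescriptiveStats(n, float(m), sd, float(v.min()), float(v.max()), g1, g2)


@dataclass
class GroupComparison:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    df: float
    p_t: float
    u: float
    p_u: float
    cohen_d: float


def compare_groups(
    values: np.ndarray,
    group: np.ndarray,
    welch: bool = False,
) -> GroupComparison:
    """Two-sample comparison: pooled-variance t, Mann-Whitney U, Cohen's d.

    ``group`` is binary; group 1 is the *higher-sorted* label so signs are
    deterministic.  U counts pairs where group-1 values exceed group-2
    values plus half of the ties; its p-value is the tie-corrected normal
    approximation.  Cohen's d divides the mean difference by the pooled SD.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    ok = ~np.isnan(values)
    values, group = values[ok], group[ok]
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels")
    x = values[group == levels[0]]
    y = values[group == levels[1]]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")

    tt = stats.ttest_ind(x, y, equal_var=not welch)
    mw = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    d = float((x.mean() - y.mean()) / np.sqrt(sp2)) if sp2 > 0 else 0.0
    df = float(tt.df) if hasattr(tt, "df") else float(n1 + n2 - 2)
    return GroupComparison(
        n1, n2, float(x.mean()), float(y.mean()), float(x.std(ddof=1)), float(y.std(ddof=1)),
        float(tt.statistic), df, float(tt.pvalue),
        float(mw.statistic), float(mw.pvalue), d,
    )


def gof_chi2(observed_counts, expected_proportions) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test of observed counts against population shares."""
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("counts and proportions must align")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("expected proportions must sum to 1")
    exp = obs.sum() * props
    if np.any(exp == 0):
        raise ValueError("expected count of zero")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# Published community means (M, SD) for side-by-side report rendering only;
# regions: world/US/Dutch/German comparison samples.  Never computed from.
_REFERENCE_MEANS = [
    ("AUDIT_TOT", "world", None, None, 5.09, 3.51, 3.30, 2.58),
    ("AUDIT_USE", "world", None, None, 3.44, 1.36, 2.46, 1.27),
    ("AUDIT_PRO", "world", None, None, 1.58, 2.79, 0.72, 1.82),
    ("CESD", "usa", 10.60, 11.20, None, None, None, None),
    ("CESD", "dutch", 7.38, 7.55, 6.25, 6.76, 8.41, 8.05),
    ("GAD7", "german", 2.97, 3.38, 2.66, 3.24, 3.20, 3.52),
    ("GAD7", "usa", 3.76, 3.96, None, None, None, None),
    ("ACQ_TOT", "usa", 1.55, 0.42, None, None, None, None),
    ("ACQ_TOT", "dutch", 1.23, 0.34, 1.21, 0.34, 1.24, 0.35),
    ("BSQ", "usa", 1.80, 0.59, None, None, None, None),
    ("BSQ", "dutch", 1.47, 0.54, 1.52, 0.51, 1.51, 0.52),
]


def reference_means() -> pd.DataFrame:
    """Static comparison-sample means for report rendering."""
    return pd.DataFrame(
        _REFERENCE_MEANS,
        columns=["scale", "region", "m_all", "sd_all", "m_male", "sd_male", "m_female", "sd_female"],
    )
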