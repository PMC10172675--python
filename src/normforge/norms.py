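"""Seven-level percentile norm tables.

Raw scores are binned into seven levels by their cumulative percentile in
the norming sample: very low (lowest 5%), low (next 15%), below average
(20%), average (20%), above average (20%), high (15%), very high (top 5%).

On zero-inflated screeners a single score can swallow several boundaries;
the convention here is that a score whose tied mass contains a boundary
belongs to the *lower* level, so e.g. a bulk minimum score stays "very low"
and the intermediate levels collapse (rendered absent).  "Very high"
therefore starts strictly above the 95th-percentile score.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LEVELS", "BOUNDARIES", "NormTable", "norm_levels", "assign_level"]

LEVELS = ["very low", "low", "below average", "average", "above average", "high", "very high"]
BOUNDARIES = (0.05, 0.20, 0.40, 0.60, 0.80, 0.95)


@dataclass
class NormTable:
    """Raw-score ranges per norm level for one subgroup.

    ``cuts[j]`` is the lowest score belonging to level ``j``; ``cuts[0]`` is
    the achievable minimum and a cut above the achievable maximum marks an
    absent level.  A level is also absent when the next level starts at the
    same score (collapsed under heavy ties).
    """

    group: str
    cuts: list[float]
    score_range: tuple[float, float]
    boundaries: tuple[float, ...] = BOUNDARIES

    def level_ranges(self) -> dict[str, tuple[float, float]]:
        """Present levels mapped to [lower, upper) score ranges."""
        lo, hi = self.score_range
        ext = list(self.cuts) + [np.nextafter(hi, np.inf)]
        out = {}
        for j, level in enumerate(LEVELS):
            if ext[j] <= hi and ext[j + 1] > ext[j]:
                out[level] = (ext[j], ext[j + 1])
        return out

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Presentation table with closed upper bounds (x.99-style ends)."""
        lo, hi = self.score_range
        step = 10.0 ** (-decimals)
        ranges = self.level_ranges()
        rows = []
        for level in LEVELS:
            if level in ranges:
                lower, upper = ranges[level]
                closed = hi if upper > hi else upper - step
                rows.append({"group": self.group, "level": level,
                             "lower": round(lower, decimals), "upper": round(closed, decimals)})
            else:
                rows.append({"group": self.group, "level": level,
                             "lower": np.nan, "upper": np.nan})
        return pd.DataFrame(rows)


def norm_levels(
    score_frequencies: pd.Series,
    score_range: tuple[float, float],
    group: str = "all",
    boundaries: tuple[float, ...] = BOUNDARIES,
) -> NormTable:
    """Build the seven-level table from a raw-score frequency distribution.

    The cut opening level ``j`` is the smallest observed score whose
    cumulative proportion *below* it reaches the level's lower boundary —
    i.e. the smallest score lying strictly above that percentile of the
    sample.  Consecutive boundaries landing inside one score's tied mass
    leave the intermediate levels empty, reproducing the sparse rows that
    zero-inflated screeners produce.
    """
    freq = score_frequencies[score_frequencies > 0].sort_index()
    total = float(freq.sum())
    if total == 0:
        raise ValueError("empty score distribution")
    if total < 20:
        raise ValueError("need at least 20 scored persons to build norms")
    lo, hi = float(score_range[0]), float(score_range[1])
    scores = freq.index.to_numpy(dtype=float)
    if scores.min() < lo or scores.max() > hi:
        raise ValueError("observed scores fall outside the achievable range")
    cum_below = (freq.cumsum() - freq).to_numpy() / total

    cuts: list[float] = [lo]
    sentinel = np.nextafter(hi, np.inf)
    for q in boundaries:
        idx = np.flatnonzero(cum_below >= q - 1e-12)
        cuts.append(float(scores[idx[0]]) if idx.size else sentinel)
    return NormTable(group, cuts, (lo, hi), tuple(boundaries))


def assign_level(score: float, table: NormTable) -> str:
    """The unique norm level whose range contains ``score``.

    With tied cuts the highest level starting at that score wins, which is
    exactly the collapsed-level convention of :func:`norm_levels`.
    """
    lo, hi = table.score_range
    if not (lo <= score <= hi):
        raise ValueError(f"score {score} outside achievable range [{lo}, {hi}]")
    return LEVELS[bisect_right(table.cuts, score) - 1]
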