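"""Delphi expert-consultation statistics.

Experts score each candidate indicator's importance and feasibility on a
1-10 scale.  Indicators are retained when the panel mean is strictly above
a threshold (default 7) and the coefficient of variation is at most a
threshold (default 0.25), on *both* dimensions.  Panel quality is
summarized by the positive coefficient (effective response rate), the
authority coefficient Cr = (Ca + Cs)/2, and Kendall's coefficient of
concordance W across experts' implied rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DIMENSIONS",
    "DelphiScoreTable",
    "ExpertProfile",
    "KendallWResult",
    "screen_indicators",
    "positive_coefficient",
    "authority_coefficient",
    "kendall_w",
]

logger = logging.getLogger(__name__)

DIMENSIONS = ("importance", "feasibility")


@dataclass
class DelphiScoreTable:
    """Expert x (indicator, dimension) score block.

    ``scores`` has one row per expert and a two-level column index
    ``(indicator, dimension)`` with dimension in ``DIMENSIONS``; entries are
    1-10 scores, NaN for missing.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.scores.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("scores must have (indicator, dimension) column MultiIndex")
        bad_dims = set(cols.get_level_values(1)) - set(DIMENSIONS)
        if bad_dims:
            raise ValueError(f"unknown score dimensions: {sorted(bad_dims)}")
        vals = self.scores.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 1 or finite.max() > 10):
            raise ValueError("scores must lie in [1, 10]")
        if len(self.scores) < 2 or len(self.indicators) < 2:
            raise ValueError("need at least 2 experts and 2 indicators")

    @property
    def experts(self) -> list:
        return list(self.scores.index)

    @property
    def indicators(self) -> list:
        return list(dict.fromkeys(self.scores.columns.get_level_values(0)))

    def dimension(self, dimension: str) -> pd.DataFrame:
        """Expert x indicator block for one dimension."""
        if dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}")
        return self.scores.xs(dimension, axis=1, level=1)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DelphiScoreTable":
        """Read a table whose header rows give indicator then dimension."""
        df = pd.read_csv(path, header=[0, 1], index_col=0)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path)


@dataclass(frozen=True)
class ExpertProfile:
    """Authority inputs for one expert (or a panel average)."""

    ca: float  # judgment-basis coefficient
    cs: float  # familiarity coefficient

    def __post_init__(self) -> None:
        for name, v in (("ca", self.ca), ("cs", self.cs)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def screen_indicators(
    table: DelphiScoreTable,
    mean_threshold: float = 7.0,
    cv_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-indicator screening report.

    An indicator is kept iff mean > ``mean_threshold`` (strict) and
    CV <= ``cv_threshold`` on both importance and feasibility.  CV uses the
    sample standard deviation (n-1 denominator).  Statistics use each
    indicator's non-missing scores; fewer than 2 non-missing scores on a
    dimension is an error.
    """
    out: dict[str, list[float]] = {f"{d}_{s}": [] for d in DIMENSIONS for s in ("mean", "cv")}
    indicators = table.indicators
    for dim in DIMENSIONS:
        block = table.dimension(dim)
        for ind in indicators:
            col = block[ind].dropna()
            if len(col) < 2:
                raise ValueError(f"indicator {ind!r} has <2 non-missing {dim} scores")
            mean = float(col.mean())
            out[f"{dim}_mean"].append(mean)
            out[f"{dim}_cv"].append(float(col.std(ddof=1) / mean))
    report = pd.DataFrame(out, index=pd.Index(indicators, name="indicator"))
    report["keep"] = True
    for dim in DIMENSIONS:
        report["keep"] &= (report[f"{dim}_mean"] > mean_threshold) & (
            report[f"{dim}_cv"] <= cv_threshold
        )
    return report


def positive_coefficient(distributed: int, returned: int) -> float:
    """Experts' positive coefficient: the effective response rate in %."""
    if distributed <= 0 or returned <= 0:
        raise ValueError("questionnaire counts must be positive")
    if returned > distributed:
        raise ValueError(f"returned ({returned}) exceeds distributed ({distributed})")
    return 100.0 * returned / distributed


def authority_coefficient(profile: ExpertProfile) -> float:
    """Expert authority coefficient Cr = (Ca + Cs) / 2."""
    return (profile.ca + profile.cs) / 2.0


class KendallWResult(NamedTuple):
    w: float
    chi2: float
    df: int
    p: float


def kendall_w(table: DelphiScoreTable, dimension: str) -> KendallWResult:
    """Tie-corrected Kendall coefficient of concordance for one dimension.

    Scores are converted to within-expert mid-ranks.  With m experts and n
    indicators, W = 12 S / (m^2 (n^3 - n) - m sum_i T_i) where S is the sum
    of squared deviations of rank sums and T_i the tie correction of expert
    i; significance uses chi^2 = m (n - 1) W on n - 1 degrees of freedom.
    Experts with missing entries are dropped (logged) so the block is
    complete.
    """
    block = table.dimension(dimension)
    complete = block.dropna(axis=0, how="any")
    dropped = len(block) - len(complete)
    if dropped:
        logger.info("kendall_w: dropped %d expert(s) with missing %s scores", dropped, dimension)
    m, n = complete.shape
    if m < 2 or n < 3:
        raise ValueError(f"Kendall's W needs >=2 complete experts and >=3 indicators, got {m}x{n}")
    ranks = complete.rank(axis=1, method="average").to_numpy()
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        raise ValueError("tie correction removed all variation (every expert scored constant)")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return KendallWResult(w=float(w), chi2=float(chi2), df=df, p=p)
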