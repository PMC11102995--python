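"""Score aggregation and cohort summaries.

An institution's composite score is 100 * sum_j W_j y_ij over its
applicable leaf indicators (weights renormalized to sum to 1), so perfect
compliance scores 100 and domain subscores sum to the composite.  Cohort
reporting mirrors the stratified layout used for field deployments:
mean +/- SD per administrative level, ownership and institution type, with
a one-way fixed-effects F test per stratifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index_model import IndicatorTree

__all__ = [
    "ADMIN_LEVELS",
    "OWNERSHIPS",
    "INSTITUTION_TYPES",
    "InstitutionRecord",
    "ScoreReport",
    "institution_score",
    "score_table",
    "cohort_summary",
    "qualification_line",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

ADMIN_LEVELS = ("first_and_below", "second", "third")
OWNERSHIPS = ("public", "social_run")
INSTITUTION_TYPES = ("comprehensive", "specialized")

STRATIFIERS = ("level", "ownership", "type")


@dataclass(frozen=True)
class InstitutionRecord:
    """Covariates of one assessed institution."""

    id: str
    level: str
    ownership: str
    type: str
    outpatient_visits: float = 0.0
    inpatient_visits: float = 0.0
    outpatient_revenue: float = 0.0
    inpatient_revenue: float = 0.0
    penalty_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.level not in ADMIN_LEVELS:
            raise ValueError(f"administrative level must be one of {ADMIN_LEVELS}, got {self.level!r}")
        if self.ownership not in OWNERSHIPS:
            raise ValueError(f"ownership must be one of {OWNERSHIPS}, got {self.ownership!r}")
        if self.type not in INSTITUTION_TYPES:
            raise ValueError(f"type must be one of {INSTITUTION_TYPES}, got {self.type!r}")
        for name in ("outpatient_visits", "inpatient_visits", "outpatient_revenue",
                     "inpatient_revenue", "penalty_amount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def records_to_frame(records: Sequence[InstitutionRecord]) -> pd.DataFrame:
    """Covariate table (one row per institution, indexed by id)."""
    return pd.DataFrame([vars(r) for r in records]).set_index("id")


def institution_score(y: Mapping[str, float] | pd.Series, w: Mapping[str, float] | pd.Series) -> float:
    """100-point weighted sum of standardized values.

    Leaves with a missing (NaN) standardized value are dropped and the
    remaining weights renormalized (logged), keeping the score on the
    100-point scale.
    """
    y_s = pd.Series(dict(y), dtype=float)
    w_s = pd.Series(dict(w), dtype=float)
    if not y_s.index.sort_values().equals(w_s.index.sort_values()):
        raise ValueError("standardized values and weights cover different leaves")
    w_s = w_s.reindex(y_s.index)
    keep = y_s.notna()
    if not keep.all():
        dropped = list(y_s.index[~keep])
        logger.info("institution_score: dropping leaves with missing values: %s", dropped)
        y_s, w_s = y_s[keep], w_s[keep]
    if y_s.empty or w_s.sum() <= 0:
        raise ValueError("no scorable leaves after dropping missing values")
    if (y_s < -1e-12).any() or (y_s > 1 + 1e-12).any():
        raise ValueError("standardized values must lie in [0, 1]")
    w_s = w_s / w_s.sum()
    return float(100.0 * (w_s * y_s).sum())


def score_table(tree: IndicatorTree, y: pd.DataFrame, w: Mapping[str, float]) -> pd.DataFrame:
    """Composite and per-domain subscores for every institution.

    ``y`` is the institution x leaf standardized matrix.  Weights are
    renormalized over ``y``'s columns; the ``composite`` column equals the
    sum of the ``domain_*`` columns by construction.
    """
    codes = [str(c) for c in y.columns]
    w_s = pd.Series({c: float(w[c]) for c in codes})
    if w_s.sum() <= 0:
        raise ValueError("leaf weights sum to zero")
    w_s = w_s / w_s.sum()
    contrib = 100.0 * y.to_numpy(dtype=float) * w_s.to_numpy()
    out = pd.DataFrame(index=y.index)
    domains = sorted({tree.domain_of(c) for c in codes})
    for dom in domains:
        cols = [j for j, c in enumerate(codes) if tree.domain_of(c) == dom]
        out[f"domain_{dom}"] = contrib[:, cols].sum(axis=1)
    out["composite"] = contrib.sum(axis=1)
    return out


@dataclass
class ScoreReport:
    """Cohort score summary: overall stats, per-stratum stats, F tests."""

    overall: dict[str, float]
    strata: pd.DataFrame           # rows (stratifier, stratum): n, mean, sd, median, min, max
    f_tests: pd.DataFrame          # rows stratifier: F, p, df_between, df_within
    excluded_strata: list[tuple[str, str]] = field(default_factory=list)


def _describe(scores: pd.Series) -> dict[str, float]:
    return {
        "n": int(scores.size),
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if scores.size > 1 else float("nan"),
        "median": float(scores.median()),
        "min": float(scores.min()),
        "max": float(scores.max()),
    }


def cohort_summary(scores: pd.Series, institutions: pd.DataFrame) -> ScoreReport:
    """Stratified score summaries with one-way F tests.

    ``institutions`` is the covariate table from :func:`records_to_frame`
    aligned to ``scores``.  Strata with fewer than 2 members are described
    but excluded from the F test for their stratifier.
    """
    institutions = institutions.loc[scores.index]
    strata_rows = []
    f_rows = []
    excluded: list[tuple[str, str]] = []
    for strat in STRATIFIERS:
        groups = []
        for name, idx in scores.groupby(institutions[strat]).groups.items():
            sub = scores.loc[idx]
            strata_rows.append({"stratifier": strat, "stratum": name, **_describe(sub)})
            if len(sub) >= 2:
                groups.append(sub.to_numpy())
            else:
                excluded.append((strat, str(name)))
        if len(groups) >= 2:
            f, p = stats.f_oneway(*groups)
            f_rows.append({
                "stratifier": strat, "F": float(f), "p": float(p),
                "df_between": len(groups) - 1,
                "df_within": int(sum(len(g) for g in groups) - len(groups)),
            })
    strata = pd.DataFrame(strata_rows).set_index(["stratifier", "stratum"])
    f_tests = pd.DataFrame(f_rows).set_index("stratifier") if f_rows else pd.DataFrame(
        columns=["F", "p", "df_between", "df_within"]
    )
    return ScoreReport(
        overall=_describe(scores), strata=strata, f_tests=f_tests, excluded_strata=excluded
    )


def qualification_line(scores: pd.Series, threshold: float) -> pd.Series:
    """Contract-renewal rule: qualified iff score >= threshold."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"qualification line must lie in [0, 100], got {threshold}")
    return scores >= threshold
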