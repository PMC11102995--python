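"""Reliability and criterion validity of assessment scores.

Reliability is test-retest: the correlation between scores obtained
online and re-scored on site for the same institutions.  Criterion
validity checks that scores track an external reference - the regulatory
penalty amount - via Spearman rank correlation and a covariate-adjusted
linear regression (standardized coefficients), overall and within each
administrative level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import ADMIN_LEVELS

__all__ = [
    "PairedScores",
    "RegressionTable",
    "ValidityResult",
    "test_retest",
    "criterion_correlation",
    "criterion_regression",
]

logger = logging.getLogger(__name__)

#: covariates entering the adjusted regression besides the criterion
_COVARIATES = (
    "type_code",
    "outpatient_visits",
    "inpatient_visits",
    "outpatient_revenue",
    "inpatient_revenue",
)
_CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class PairedScores:
    """Online and on-site scores for the same institutions."""

    online: pd.Series
    onsite: pd.Series

    def __post_init__(self) -> None:
        if not self.online.index.sort_values().equals(self.onsite.index.sort_values()):
            raise ValueError("online and on-site scores cover different institutions")
        if len(self.online) < 3:
            raise ValueError("test-retest needs at least 3 paired institutions")
        object.__setattr__(self, "onsite", self.onsite.reindex(self.online.index))


def test_retest(pairs: PairedScores, method: str = "pearson") -> tuple[float, float]:
    """Test-retest reliability coefficient with a two-sided p-value.

    Pearson by default; ``method='spearman'`` switches to rank correlation.
    """
    x = pairs.online.to_numpy(dtype=float)
    y = pairs.onsite.to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("test-retest requires nonzero variance in both score sets")
    if np.array_equal(x, y):  # identical measurements correlate exactly
        return 1.0, 0.0
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r.statistic), float(r.pvalue)


def criterion_correlation(scores: pd.Series, penalty: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation between scores and the criterion."""
    penalty = penalty.reindex(scores.index)
    if len(scores) < 3:
        raise ValueError("criterion correlation needs at least 3 institutions")
    if scores.nunique() < 2 or penalty.nunique() < 2:
        raise ValueError("criterion correlation requires non-constant inputs")
    r = stats.spearmanr(scores.to_numpy(dtype=float), penalty.to_numpy(dtype=float))
    return float(r.statistic), float(r.pvalue)


@dataclass
class RegressionTable:
    """Standardized OLS results for one (sub)cohort."""

    coef: pd.DataFrame  # rows per covariate: beta, t, p
    r2: float
    n: int
    flagged_collinear: list[str] = field(default_factory=list)


@dataclass
class ValidityResult:
    spearman_r: float
    spearman_p: float
    overall: RegressionTable
    by_level: dict[str, RegressionTable] = field(default_factory=dict)


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    keep = sd > 0
    dropped = list(df.columns[~keep])
    if dropped:
        logger.info("dropping constant regression columns: %s", dropped)
    z = (df.loc[:, keep] - df.loc[:, keep].mean()) / sd[keep]
    return z


def _fit_standardized(scores: pd.Series, design: pd.DataFrame) -> RegressionTable:
    n, k = design.shape
    if n <= k + 2:
        raise ValueError(f"need n > covariates + 2 (n={n}, covariates={k})")
    z_y = (scores - scores.mean()) / scores.std(ddof=1)
    z_x = _zscore(design)
    x = sm.add_constant(z_x, has_constant="add")
    fit = sm.OLS(z_y.to_numpy(), x.to_numpy()).fit()
    flagged: list[str] = []
    if np.linalg.cond(x.to_numpy()) > _CONDITION_LIMIT:
        corr = z_x.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        flagged = sorted(set(corr.index[(corr > 0.999).any(axis=1)]))
        logger.warning("near-collinear regression design; flagged columns: %s", flagged)
    names = list(x.columns)
    coef = pd.DataFrame(
        {"beta": fit.params, "t": fit.tvalues, "p": fit.pvalues}, index=names
    ).drop(index="const")
    return RegressionTable(coef=coef, r2=float(fit.rsquared), n=n, flagged_collinear=flagged)


def criterion_regression(
    scores: pd.Series,
    institutions: pd.DataFrame,
    stratify: bool = True,
) -> ValidityResult:
    """Adjusted criterion-validity analysis.

    Regresses the composite score on the penalty amount plus institution
    covariates (administrative level coded ordinally, institution type,
    visit counts, revenue), all variables z-scored so coefficients are
    standardized betas.  With ``stratify=True`` the model is refit within
    each administrative level, omitting the level covariate.
    """
    institutions = institutions.loc[scores.index]
    rho, rho_p = criterion_correlation(scores, institutions["penalty_amount"])
    design = pd.DataFrame(index=scores.index)
    design["level_code"] = institutions["level"].map(
        {lvl: i + 1 for i, lvl in enumerate(ADMIN_LEVELS)}
    )
    design["type_code"] = (institutions["type"] == "specialized").astype(float)
    for col in _COVARIATES[1:]:
        design[col] = institutions[col].astype(float)
    design["penalty_amount"] = institutions["penalty_amount"].astype(float)
    overall = _fit_standardized(scores, design)
    by_level: dict[str, RegressionTable] = {}
    if stratify:
        for lvl in ADMIN_LEVELS:
            mask = institutions["level"] == lvl
            if mask.sum() < 3:
                continue
            sub_design = design.loc[mask].drop(columns=["level_code"])
            try:
                by_level[lvl] = _fit_standardized(scores[mask], sub_design)
            except ValueError as exc:
                logger.info("skipping level %s regression: %s", lvl, exc)
    return ValidityResult(spearman_r=rho, spearman_p=rho_p, overall=overall, by_level=by_level)
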