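"""Synthetic inputs with known ground truth.

Three generators emulate everything the toolkit consumes, so the full
pipeline is testable without any external data:

* :func:`gen_expert_scores` - a Delphi panel scoring indicators around
  planted means, with a planted "weak" subset (means <= 7) that screening
  should delete;
* :func:`gen_judgment_matrices` - expert pairwise-comparison matrices
  perturbed around a consistent matrix built from planted true weights;
* :func:`gen_institution_data` - an institution cohort whose raw
  indicator values derive from a latent compliance level c_i in (0, 1)
  (logit-normal), with covariates and a regulatory penalty amount coupled
  to compliance at a configurable target rank correlation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .delphi import DIMENSIONS, DelphiScoreTable
from .index_model import IndicatorTree
from .scoring import ADMIN_LEVELS, INSTITUTION_TYPES, OWNERSHIPS, InstitutionRecord
from .weighting import JudgmentMatrix

__all__ = [
    "PanelSpec",
    "CohortSpec",
    "gen_expert_scores",
    "gen_judgment_matrices",
    "gen_institution_data",
]

#: lognormal scale parameters for the penalty amount (currency units)
_PENALTY_LOG_MEAN = 8.0
_PENALTY_LOG_SD = 1.2


@dataclass(frozen=True)
class PanelSpec:
    """Delphi panel simulation settings."""

    n_experts: int = 20
    n_indicators: int = 66
    n_weak: int = 10
    score_sd: float = 1.0       # consensus strength: SD of scores around planted means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("need at least 2 experts")
        if not 0 <= self.n_weak <= self.n_indicators:
            raise ValueError("weak-indicator count outside [0, n_indicators]")
        if self.score_sd < 0:
            raise ValueError("score SD must be >= 0")


def gen_expert_scores(spec: PanelSpec) -> tuple[DelphiScoreTable, list[str]]:
    """Panel score table plus the planted weak-indicator codes.

    Strong indicators get planted means in (7.5, 9.3), weak ones in
    (5.5, 6.8); expert scores are normal around the planted mean (same
    mean for importance and feasibility), clamped to [1, 10].
    """
    rng = np.random.default_rng(spec.seed)
    codes = [f"cand_{i + 1}" for i in range(spec.n_indicators)]
    weak = sorted(rng.choice(spec.n_indicators, size=spec.n_weak, replace=False).tolist())
    means = rng.uniform(7.5, 9.3, size=spec.n_indicators)
    means[weak] = rng.uniform(5.5, 6.8, size=spec.n_weak)
    cols = {}
    for j, code in enumerate(codes):
        for dim in DIMENSIONS:
            draws = means[j] + spec.score_sd * rng.standard_normal(spec.n_experts)
            cols[(code, dim)] = np.clip(draws, 1.0, 10.0)
    table = pd.DataFrame(cols, index=[f"expert_{i + 1}" for i in range(spec.n_experts)])
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["indicator", "dimension"])
    return DelphiScoreTable(table), [codes[j] for j in weak]


def gen_judgment_matrices(
    true_weights,
    sigma: float,
    n_experts: int,
    seed: int = 0,
) -> list[JudgmentMatrix]:
    """Expert judgment matrices a_ij = (w_i / w_j) * exp(eps_ij).

    ``eps`` is antisymmetric normal(0, sigma^2), so reciprocity holds
    exactly and sigma = 0 reproduces the consistent matrix of the planted
    weights.
    """
    w = np.asarray(true_weights, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("true_weights must be a vector of length >= 2")
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w <= 0):
        raise ValueError("true_weights must be positive and sum to 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = w.size
    base = np.log(w[:, None] / w[None, :])
    out = []
    for k in range(n_experts):
        eps = sigma * rng.standard_normal((n, n))
        eps = np.triu(eps, 1)
        eps = eps - eps.T
        out.append(JudgmentMatrix(a=np.exp(base + eps), expert=f"expert_{k + 1}"))
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Institution-cohort simulation settings.

    Latent compliance is logit-normal: the defaults (logit mean 3, logit
    SD 1) give a left-skewed, high-compliance cohort like field deployments
    of contract assessments (most institutions near full compliance).
    ``target_corr`` is the planted latent correlation between compliance
    and the log penalty amount (negative: better compliance, lower
    penalties).
    """

    tree: IndicatorTree
    n_institutions: int = 760
    logit_mean: float = 3.0
    logit_sd: float = 1.0
    noise_sd: float = 0.05
    target_corr: float = -0.15
    level_mix: dict[str, float] = field(
        default_factory=lambda: {"first_and_below": 0.7, "second": 0.2, "third": 0.1}
    )
    ownership_mix: dict[str, float] = field(
        default_factory=lambda: {"public": 0.5, "social_run": 0.5}
    )
    type_mix: dict[str, float] = field(
        default_factory=lambda: {"comprehensive": 0.6, "specialized": 0.4}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_institutions < 10:
            raise ValueError("need at least 10 institutions")
        if not -1.0 <= self.target_corr <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")
        if abs(self.target_corr) == 1.0 and self.noise_sd > 0:
            raise ValueError(
                "target correlation of +/-1 is unattainable with noise_sd > 0; "
                "the attainable magnitude is strictly below 1"
            )
        if self.noise_sd < 0 or self.logit_sd <= 0:
            raise ValueError("noise_sd must be >= 0 and logit_sd > 0")
        for name, mix, allowed in (
            ("level_mix", self.level_mix, ADMIN_LEVELS),
            ("ownership_mix", self.ownership_mix, OWNERSHIPS),
            ("type_mix", self.type_mix, INSTITUTION_TYPES),
        ):
            if set(mix) - set(allowed) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must cover only {allowed} and sum to 1")


def _leaf_raw(rule_kind: str, params, direction: str, c: np.ndarray, noise: np.ndarray, rng):
    """Raw values for one leaf given compliance c and additive noise.

    ``noise`` is zero in the noiseless limit, where discrete rules use
    their median outcome so raw values are a deterministic monotone
    function of compliance.
    """
    goodness = np.clip((c if direction == "positive" else 1.0 - c) + noise, 0.0, 1.0)
    deterministic = not noise.any()
    if rule_kind == "binary":
        p = c if direction == "positive" else 1.0 - c
        if deterministic:
            return p >= 0.5
        return rng.random(c.size) < p
    if rule_kind == "multi_condition":
        total = params["total"]
        if deterministic:
            return np.rint(total * c).astype(int)
        return rng.binomial(total, c)
    if rule_kind == "proportional":
        return 100.0 * goodness
    if rule_kind == "segment":
        low, high = params["low"], params["high"]
        return low + (high - low) * goodness
    if rule_kind == "min_max":
        return goodness
    if rule_kind == "horizontal":
        return 100.0 * np.maximum(goodness, 1e-6)
    raise ValueError(f"unknown rule kind {rule_kind!r}")  # pragma: no cover


def gen_institution_data(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, list[InstitutionRecord], np.ndarray]:
    """Raw-value table, institution records, and true compliance vector.

    Every leaf's raw values are driven by the latent compliance c_i through
    its declared rule and direction, so the downstream pipeline score is a
    noisy monotone transform of c_i.  The penalty amount is lognormal with
    its log coupled to standardized logit-compliance at ``target_corr``
    (a Gaussian-copula construction: Spearman correlations survive the
    monotone exp transform).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_institutions
    tree = spec.tree
    z = rng.standard_normal(n)
    c = expit(spec.logit_mean + spec.logit_sd * z)
    raw = {}
    for code in tree.leaves:
        ind = tree[code]
        noise = (
            spec.noise_sd * rng.standard_normal(n) if spec.noise_sd > 0 else np.zeros(n)
        )
        raw[code] = _leaf_raw(ind.rule.kind, ind.rule.params, ind.direction, c, noise, rng)
    ids = [f"inst_{i + 1:04d}" for i in range(n)]
    raw_df = pd.DataFrame(raw, index=pd.Index(ids, name="id"))

    # penalty: log amount correlated with standardized logit-compliance
    t = spec.target_corr
    z_std = (logit(c) - spec.logit_mean) / spec.logit_sd
    eta = rng.standard_normal(n)
    latent = t * z_std + np.sqrt(max(0.0, 1.0 - t * t)) * eta
    penalty = np.exp(_PENALTY_LOG_MEAN + _PENALTY_LOG_SD * latent)

    def draw_mix(mix: dict[str, float]) -> np.ndarray:
        cats = list(mix)
        return rng.choice(cats, size=n, p=[mix[k] for k in cats])

    levels = draw_mix(spec.level_mix)
    owners = draw_mix(spec.ownership_mix)
    types = draw_mix(spec.type_mix)
    # visit/revenue scales grow with administrative level, independent of compliance
    level_scale = {lvl: 10.0 ** (i + 1) for i, lvl in enumerate(ADMIN_LEVELS)}
    scales = np.array([level_scale[lvl] for lvl in levels])
    records = []
    for i in range(n):
        out_visits = scales[i] * rng.lognormal(3.0, 0.5)
        in_visits = scales[i] * rng.lognormal(1.0, 0.5)
        records.append(
            InstitutionRecord(
                id=ids[i],
                level=str(levels[i]),
                ownership=str(owners[i]),
                type=str(types[i]),
                outpatient_visits=float(out_visits),
                inpatient_visits=float(in_visits),
                outpatient_revenue=float(out_visits * rng.lognormal(5.0, 0.3)),
                inpatient_revenue=float(in_visits * rng.lognormal(8.0, 0.3)),
                penalty_amount=float(penalty[i]),
            )
        )
    return raw_df, records, c
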