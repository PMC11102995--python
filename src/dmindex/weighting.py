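"""Combination weighting: AHP (subjective) x entropy (objective).

Subjective weights come from pairwise judgment matrices on the 1-9 Saaty
scale: the principal right eigenvector of each sibling group's (expert-
aggregated) matrix gives local priorities, whose consistency is checked by
CR = CI/RI with CI = (lambda_max - n)/(n - 1).  Objective weights come
from the entropy method on the standardized institution x indicator
matrix: value shares P_ij, entropies e_j = -k sum_i P_ij ln P_ij with
k = 1/ln m, difference coefficients g_j = 1 - e_j, correction
coefficients mu_j = g_j / sum g, and AHP-adjusted weights
theta_j = mu_j w_j / sum(mu w).  The combined weight is the blend
W_j = rho * w_j + (1 - rho) * theta_j (rho = 0.5 by default), computed at
leaf level and summed up the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .index_model import IndicatorTree, WeightBundle

__all__ = [
    "SAATY_RI",
    "JudgmentMatrix",
    "PriorityVector",
    "EntropyResult",
    "ahp_priority",
    "aggregate_experts",
    "global_ahp_weights",
    "local_from_global",
    "entropy_weights",
    "combine_weights",
    "rollup_weights",
    "build_weight_bundle",
]

#: Saaty random consistency indices for matrix orders 1..10.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_RECIPROCITY_TOL = 1e-9
_POWER_TOL = 1e-10
_POWER_MAXITER = 10_000


@dataclass(frozen=True)
class JudgmentMatrix:
    """One expert's pairwise comparisons over a sibling group."""

    a: np.ndarray
    expert: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 2:
            raise ValueError(f"judgment matrix must be square with n >= 2, got shape {a.shape}")
        if np.any(a <= 0):
            raise ValueError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIPROCITY_TOL):
            raise ValueError("judgment matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-6):
            raise ValueError("judgment matrix must be reciprocal (a_ij = 1/a_ji)")

    @property
    def n(self) -> int:
        return self.a.shape[0]


@dataclass(frozen=True)
class PriorityVector:
    """Local AHP weights for one sibling group plus consistency diagnostics."""

    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float

    @property
    def consistent(self) -> bool:
        """CR below Saaty's 0.1 acceptance threshold."""
        return self.cr < 0.1


def ahp_priority(matrix: JudgmentMatrix) -> PriorityVector:
    """Principal-eigenvector priorities with consistency diagnostics.

    The principal right eigenvector is found by power iteration (tolerance
    1e-10); lambda_max is its Rayleigh quotient.  CI = (lambda_max - n)/(n - 1)
    and CR = CI/RI(n); for n <= 2 a reciprocal matrix is always consistent
    and CR is defined as 0.
    """
    a = matrix.a
    n = matrix.n
    v = np.full(n, 1.0 / n)
    for _ in range(_POWER_MAXITER):
        nxt = a @ v
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - v)) < _POWER_TOL:
            v = nxt
            break
        v = nxt
    lam = float((a @ v).sum())  # since v sums to 1, sum(Av) = lambda * sum(v)
    ci = (lam - n) / (n - 1) if n > 1 else 0.0
    ci = max(ci, 0.0)
    if n <= 2:
        cr = 0.0
    else:
        ri = SAATY_RI.get(n)
        if ri is None:
            raise ValueError(f"no random consistency index for matrix order {n}")
        cr = ci / ri
    return PriorityVector(weights=v, lambda_max=lam, ci=float(ci), cr=float(cr))


def aggregate_experts(matrices: Sequence[JudgmentMatrix]) -> JudgmentMatrix:
    """Element-wise geometric mean of expert matrices (reciprocity exact)."""
    if not matrices:
        raise ValueError("need at least one judgment matrix")
    n = matrices[0].n
    if any(m.n != n for m in matrices):
        raise ValueError("all judgment matrices must have the same size")
    log_mean = np.mean([np.log(m.a) for m in matrices], axis=0)
    g = np.exp((log_mean - log_mean.T) / 2.0)  # symmetrize logs: exact reciprocity
    np.fill_diagonal(g, 1.0)
    return JudgmentMatrix(a=g, expert="geometric_mean")


def global_ahp_weights(
    tree: IndicatorTree,
    local: Mapping[str | None, Mapping[str, float]],
) -> dict[str, float]:
    """Synthesize local sibling-group priorities into global leaf weights.

    ``local`` maps each parent code (``None`` for the domain level) to its
    children's local weights.  A leaf's global weight is the product of
    local weights along its root path; leaves sum to 1 when every local
    vector does.
    """
    globals_: dict[str, float] = {}

    def descend(code: str, acc: float) -> None:
        kids = tree.children(code)
        if not kids:
            globals_[code] = acc
            return
        group = local.get(code)
        if group is None:
            raise ValueError(f"no priority vector for sibling group under {code!r}")
        for kid in kids:
            if kid not in group:
                raise ValueError(f"priority vector under {code!r} lacks child {kid!r}")
            descend(kid, acc * group[kid])

    domain_group = local.get(None)
    if domain_group is None:
        raise ValueError("no priority vector for the domain (top) level")
    for dom in tree.domains:
        if dom not in domain_group:
            raise ValueError(f"domain-level priority vector lacks domain {dom!r}")
        descend(dom, domain_group[dom])
    return globals_


def local_from_global(
    tree: IndicatorTree,
    node_weights: Mapping[str, float],
) -> dict[str | None, dict[str, float]]:
    """Invert AHP synthesis: within-parent renormalized local weights.

    ``node_weights`` must cover every node (leaves plus roll-ups).  The
    result feeds :func:`global_ahp_weights`, which round-trips to the same
    global leaf weights.
    """
    local: dict[str | None, dict[str, float]] = {}
    for parent in [None, *tree.internal_nodes]:
        kids = tree.domains if parent is None else tree.children(parent)
        total = sum(node_weights[k] for k in kids)
        if total <= 0:
            raise ValueError(f"children of {parent!r} have non-positive weight sum")
        local[parent] = {k: node_weights[k] / total for k in kids}
    return local


@dataclass(frozen=True)
class EntropyResult:
    """Entropy-method outputs per leaf indicator (aligned to ``codes``)."""

    codes: list[str]
    p: np.ndarray          # m x n value shares
    e: np.ndarray          # entropies, in [0, 1]
    g: np.ndarray          # difference coefficients 1 - e
    mu: np.ndarray         # correction coefficients, sum to 1
    theta: np.ndarray      # AHP-adjusted entropy weights, sum to 1

    def theta_by_code(self) -> dict[str, float]:
        return dict(zip(self.codes, self.theta.tolist()))


def entropy_weights(x: pd.DataFrame | np.ndarray, w: Mapping[str, float] | Sequence[float]) -> EntropyResult:
    """Entropy weights adjusted by the AHP weights.

    ``x`` is the standardized m x n institution-by-indicator matrix
    (nonnegative, every column with a positive sum, m >= 2); ``w`` the leaf
    AHP weights in column order.  Uses k = 1/ln(m) so entropies lie in
    [0, 1], with the 0*ln(0) = 0 convention, which makes the
    constant-column limit exact (e = 1, theta = 0).
    """
    if isinstance(x, pd.DataFrame):
        codes = [str(c) for c in x.columns]
        mat = x.to_numpy(dtype=float)
    else:
        mat = np.asarray(x, dtype=float)
        codes = [str(j) for j in range(mat.shape[1])]
    if isinstance(w, Mapping):
        w_arr = np.array([float(w[c]) for c in codes])
    else:
        w_arr = np.asarray(w, dtype=float)
    m, n = mat.shape
    if m < 2:
        raise ValueError("entropy method needs at least 2 institutions")
    if w_arr.shape != (n,):
        raise ValueError(f"AHP weight vector length {w_arr.shape} does not match {n} columns")
    if np.any(mat < 0):
        raise ValueError("standardized matrix must be nonnegative")
    col_sums = mat.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = [codes[j] for j in np.flatnonzero(col_sums <= 0)]
        raise ValueError(f"columns with non-positive sums: {bad}")
    p = mat / col_sums
    k = 1.0 / np.log(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    e = -k * plogp.sum(axis=0)
    e = np.clip(e, 0.0, 1.0)
    g = 1.0 - e
    g_sum = g.sum()
    if g_sum <= 0:
        raise ValueError("no discriminating information: every indicator is constant")
    mu = g / g_sum
    mw = mu * w_arr
    theta = mw / mw.sum()
    return EntropyResult(codes=codes, p=p, e=e, g=g, mu=mu, theta=theta)


def combine_weights(
    w: Mapping[str, float],
    theta: Mapping[str, float],
    rho: float = 0.5,
) -> dict[str, float]:
    """Blend W_j = rho * w_j + (1 - rho) * theta_j over the leaf set."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if set(w) != set(theta):
        raise ValueError("AHP and entropy weight vectors cover different indicators")
    return {c: rho * w[c] + (1.0 - rho) * theta[c] for c in w}


def rollup_weights(tree: IndicatorTree, leaf_weights: Mapping[str, float]) -> dict[str, float]:
    """Sum leaf weights up the hierarchy; returns weights for every node."""
    orphans = set(leaf_weights) - set(tree.leaves)
    if orphans:
        raise ValueError(f"weights given for non-leaf codes: {sorted(orphans)}")
    missing = set(tree.leaves) - set(leaf_weights)
    if missing:
        raise ValueError(f"leaves without weights: {sorted(missing)}")
    out = dict(leaf_weights)

    def total(code: str) -> float:
        kids = tree.children(code)
        if not kids:
            return out[code]
        out[code] = sum(total(k) for k in kids)
        return out[code]

    for dom in tree.domains:
        total(dom)
    return out


def build_weight_bundle(
    tree: IndicatorTree,
    w_leaf: Mapping[str, float],
    theta_leaf: Mapping[str, float],
    rho: float = 0.5,
) -> WeightBundle:
    """Full per-node weight table: blend at leaf level, roll all columns up."""
    combined_leaf = combine_weights(w_leaf, theta_leaf, rho=rho)
    return WeightBundle(
        w_ahp=rollup_weights(tree, w_leaf),
        theta=rollup_weights(tree, theta_leaf),
        w_combined=rollup_weights(tree, combined_leaf),
    )
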