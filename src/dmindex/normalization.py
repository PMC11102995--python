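"""The six dimensionless assignment methods.

Each leaf indicator's raw value x_i is mapped to a standard value
y_i in [0, 1] by the rule declared in the index config:

1. ``binary`` - yes/no answers score 1/0 (reversed for negative direction).
2. ``multi_condition`` - fraction of required conditions met.
3. ``proportional`` - percentages score percent/100 (complemented when
   negative in direction).
4. ``segment`` - 0 outside an acceptable range [a, b], linear position
   inside it.
5. ``min_max`` - (x - min)/(max - min) over the assessed cohort, reversed
   for negative indicators.
6. ``horizontal`` - ratio to the cohort mean (or its reciprocal when
   negative), clipped to [0, 1] so downstream scores stay bounded by 100.

``normalize_leaf`` dispatches on the rule and records an audit entry;
``normalize_table`` applies the whole index to an institution x indicator
raw-value table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .index_model import Indicator, IndicatorTree

__all__ = [
    "NormalizationError",
    "AuditEntry",
    "normalize_binary",
    "normalize_multi_condition",
    "normalize_proportional",
    "normalize_segment",
    "normalize_min_max",
    "normalize_horizontal",
    "normalize_leaf",
    "normalize_table",
]

logger = logging.getLogger(__name__)

_TRUTHY = {"yes", "y", "true", "1"}
_FALSY = {"no", "n", "false", "0"}


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class AuditEntry:
    """One leaf's normalization provenance: rule applied and any flags."""

    code: str
    rule: str
    direction: str
    note: str = ""


def _check_direction(direction: str) -> None:
    if direction not in ("positive", "negative"):
        raise NormalizationError(f"direction must be 'positive' or 'negative', got {direction!r}")


def _as_bool(answer) -> bool:
    if isinstance(answer, (bool, np.bool_)):
        return bool(answer)
    if isinstance(answer, str):
        low = answer.strip().lower()
        if low in _TRUTHY:
            return True
        if low in _FALSY:
            return False
    if isinstance(answer, (int, np.integer, float, np.floating)) and answer in (0, 1):
        return bool(answer)
    raise NormalizationError(f"binary indicator expects a yes/no answer, got {answer!r}")


def normalize_binary(answer, direction: str = "positive") -> float:
    """0-1 assignment: yes scores 1 (0 for negative-direction indicators)."""
    _check_direction(direction)
    y = 1.0 if _as_bool(answer) else 0.0
    return y if direction == "positive" else 1.0 - y


def normalize_multi_condition(met: int, total: int) -> float:
    """Fraction of the required conditions met (equal sub-weights)."""
    if total < 2:
        raise NormalizationError(f"multi_condition requires total >= 2, got {total}")
    if not 0 <= met <= total:
        raise NormalizationError(f"met conditions {met} outside [0, {total}]")
    return met / total


def normalize_proportional(percent: float, direction: str = "positive") -> float:
    """Percentage indicators: percent/100, complemented when negative."""
    _check_direction(direction)
    if not 0.0 <= percent <= 100.0:
        raise NormalizationError(f"percentage {percent} outside [0, 100]")
    y = percent / 100.0
    return y if direction == "positive" else 1.0 - y


def normalize_segment(x: float, low: float, high: float, direction: str = "positive") -> float:
    """0 outside the acceptable range [low, high], linear position inside."""
    _check_direction(direction)
    if not low < high:
        raise NormalizationError(f"degenerate acceptable range [{low}, {high}]")
    if x < low or x > high:
        return 0.0
    frac = (x - low) / (high - low)
    return frac if direction == "positive" else 1.0 - frac


def normalize_min_max(values, direction: str = "positive") -> np.ndarray:
    """Cohort min-max scaling; a constant cohort scores 1 for everyone.

    A constant column carries no discriminating information, so no
    institution is penalized; the entropy weighting then independently
    drives such an indicator's weight toward 0.
    """
    _check_direction(direction)
    x = np.asarray(values, dtype=float)
    if x.size < 1 or not np.all(np.isfinite(x)):
        raise NormalizationError("min_max requires a nonempty finite value vector")
    lo, hi = x.min(), x.max()
    if lo == hi:
        logger.warning("min_max: constant raw vector, assigning 1.0 to all institutions")
        return np.ones_like(x)
    y = (x - lo) / (hi - lo)
    return y if direction == "positive" else 1.0 - y


def normalize_horizontal(x: float, cohort_mean: float, direction: str = "positive") -> float:
    """Ratio to the mean of comparable institutions, clipped to [0, 1]."""
    _check_direction(direction)
    if cohort_mean <= 0:
        raise NormalizationError(f"cohort mean must be positive, got {cohort_mean}")
    if x < 0:
        raise NormalizationError(f"horizontal rule requires x >= 0, got {x}")
    if direction == "positive":
        ratio = x / cohort_mean
    else:
        if x == 0:
            logger.info("horizontal: x=0 with negative direction, assigning 1.0")
            return 1.0
        ratio = cohort_mean / x
    return float(np.clip(ratio, 0.0, 1.0))


def normalize_leaf(
    indicator: Indicator,
    values,
    cohort_mean: float | None = None,
) -> tuple[np.ndarray, AuditEntry]:
    """Standardize one leaf's raw values across a cohort.

    ``values`` is the per-institution raw vector; ``cohort_mean`` feeds the
    horizontal rule (defaults to the mean of ``values``).
    """
    if indicator.rule is None:
        raise NormalizationError(f"indicator {indicator.code!r} is not a leaf with a rule")
    kind = indicator.rule.kind
    direction = indicator.direction
    params = indicator.rule.params
    note = ""
    try:
        if kind == "binary":
            y = np.array([normalize_binary(v, direction) for v in values])
        elif kind == "multi_condition":
            total = params["total"]
            y = np.array([normalize_multi_condition(int(v), total) for v in values])
        elif kind == "proportional":
            y = np.array([normalize_proportional(float(v), direction) for v in values])
        elif kind == "segment":
            y = np.array(
                [normalize_segment(float(v), params["low"], params["high"], direction) for v in values]
            )
        elif kind == "min_max":
            y = normalize_min_max(values, direction)
            if float(np.min(values)) == float(np.max(values)):
                note = "constant raw vector assigned 1.0"
        elif kind == "horizontal":
            x = np.asarray(values, dtype=float)
            mean = float(x.mean()) if cohort_mean is None else float(cohort_mean)
            y = np.array([normalize_horizontal(v, mean, direction) for v in x])
        else:  # pragma: no cover - kinds validated at config load
            raise NormalizationError(f"unknown rule kind {kind!r}")
    except (ValueError, TypeError) as exc:
        raise NormalizationError(f"indicator {indicator.code!r}: {exc}") from exc
    return y, AuditEntry(code=indicator.code, rule=kind, direction=direction, note=note)


def normalize_table(
    tree: IndicatorTree,
    raw: pd.DataFrame,
    cohort_means: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[AuditEntry]]:
    """Standardize an institution x leaf-indicator raw-value table.

    Columns of ``raw`` are leaf codes; the result has the same shape with
    all entries in [0, 1], plus the per-column audit trail.
    """
    missing = [c for c in raw.columns if c not in tree or tree[c].level != 3]
    if missing:
        raise NormalizationError(f"columns are not leaf indicators of the index: {missing}")
    out = {}
    audit: list[AuditEntry] = []
    for code in raw.columns:
        mean = None if cohort_means is None else cohort_means.get(code)
        y, entry = normalize_leaf(tree[code], raw[code].to_numpy(), cohort_mean=mean)
        out[code] = y
        audit.append(entry)
    return pd.DataFrame(out, index=raw.index), audit
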