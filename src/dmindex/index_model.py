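"""Hierarchical assessment-index model.

An assessment index is a rooted forest of indicators: level-1 *domains*,
level-2 groups, and level-3 *leaf* indicators.  Only leaves carry a
normalization rule and are scored directly; weights of internal nodes are
the sums of their children's weights.  The packaged index
(:func:`table5_fixture`) is the published 6-domain / 56-leaf
contract-compliance index for designated medical institutions, including
its three weight columns (AHP weight ``w_ahp``, entropy-adjusted weight
``theta``, combined weight ``w_combined``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "IndexConfigError",
    "NormalizationRule",
    "Indicator",
    "IndicatorTree",
    "WeightBundle",
    "load_index_config",
    "table5_fixture",
    "applicable_indicators",
]

DIRECTIONS = ("positive", "negative")
RULE_KINDS = ("binary", "multi_condition", "proportional", "segment", "min_max", "horizontal")
DATA_SOURCES = ("self_report", "admin_record")

#: tolerance for leaf combined weights summing to 1 over the whole index
LEAF_SUM_TOL = 5e-4
#: tolerance for an internal node's weight matching the sum of its children
ROLLUP_TOL = 2e-4


class IndexConfigError(ValueError):
    """Raised when an index configuration violates the schema.

    The message names the offending indicator code where one exists.
    """

    def __init__(self, message: str, code: str | None = None):
        self.code = code
        super().__init__(message if code is None else f"indicator {code!r}: {message}")


@dataclass(frozen=True)
class NormalizationRule:
    """Which of the six dimensionless assignment methods a leaf uses.

    ``params`` holds rule-specific settings: ``total`` (number of
    requirements) for ``multi_condition``; ``low``/``high`` (acceptable
    range) for ``segment``.
    """

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise IndexConfigError(f"unknown normalization rule kind {self.kind!r}")
        if self.kind == "multi_condition":
            total = self.params.get("total")
            if not isinstance(total, int) or total < 2:
                raise IndexConfigError("multi_condition rule requires integer total >= 2")
        elif self.kind == "segment":
            low, high = self.params.get("low"), self.params.get("high")
            if low is None or high is None or not low < high:
                raise IndexConfigError("segment rule requires an acceptable range low < high")
        elif self.params:
            raise IndexConfigError(f"rule {self.kind!r} takes no parameters, got {dict(self.params)}")


@dataclass(frozen=True)
class Indicator:
    """One node of the index: a domain, a group, or a leaf indicator."""

    code: str
    name: str
    direction: str = "positive"
    rule: NormalizationRule | None = None
    data_source: str = "self_report"
    #: declarative applicability: institutions whose ``level``/``type`` match
    #: (empty selector = applies to all institutions)
    applicability: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = self.code.split(".")
        if not all(p for p in parts) or len(parts) > 3:
            raise IndexConfigError("code must have 1-3 non-empty dot-separated parts", self.code)
        if self.direction not in DIRECTIONS:
            raise IndexConfigError(f"direction must be one of {DIRECTIONS}", self.code)
        if self.data_source not in DATA_SOURCES:
            raise IndexConfigError(f"data_source must be one of {DATA_SOURCES}", self.code)
        if self.level == 3 and self.rule is None:
            raise IndexConfigError("leaf (level-3) indicators must carry a normalization rule", self.code)
        if self.level < 3 and self.rule is not None:
            raise IndexConfigError("only leaf (level-3) indicators may carry a rule", self.code)

    @property
    def level(self) -> int:
        return self.code.count(".") + 1

    @property
    def parent_code(self) -> str | None:
        if self.level == 1:
            return None
        return self.code.rsplit(".", 1)[0]

    def applies_to(self, institution: Any) -> bool:
        """True if the institution's level/type match the selector."""
        for attr in ("level", "type"):
            if getattr(institution, attr, None) is None:
                raise IndexConfigError(f"institution record lacks required field {attr!r}")
        allowed_levels = self.applicability.get("levels")
        allowed_types = self.applicability.get("types")
        if allowed_levels and institution.level not in allowed_levels:
            return False
        if allowed_types and institution.type not in allowed_types:
            return False
        return True


class IndicatorTree:
    """A validated rooted forest of indicators (domains down to leaves)."""

    def __init__(self, indicators: Iterable[Indicator]):
        self._by_code: dict[str, Indicator] = {}
        for ind in indicators:
            if ind.code in self._by_code:
                raise IndexConfigError("duplicate indicator code", ind.code)
            self._by_code[ind.code] = ind
        self._children: dict[str, list[str]] = {c: [] for c in self._by_code}
        for ind in self._by_code.values():
            if ind.parent_code is not None:
                if ind.parent_code not in self._by_code:
                    raise IndexConfigError(f"parent {ind.parent_code!r} not defined", ind.code)
                self._children[ind.parent_code].append(ind.code)
        for code, kids in self._children.items():
            if self._by_code[code].level < 3 and not kids:
                raise IndexConfigError("internal node has no children", code)
        if not self._by_code:
            raise IndexConfigError("index contains no indicators")

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Indicator:
        return self._by_code[code]

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> list[str]:
        return list(self._by_code)

    @property
    def domains(self) -> list[str]:
        return [c for c, ind in self._by_code.items() if ind.level == 1]

    @property
    def leaves(self) -> list[str]:
        return [c for c, ind in self._by_code.items() if ind.level == 3]

    @property
    def internal_nodes(self) -> list[str]:
        return [c for c, ind in self._by_code.items() if ind.level < 3]

    def children(self, code: str) -> list[str]:
        return list(self._children[code])

    def domain_of(self, code: str) -> str:
        return code.split(".")[0]


@dataclass(frozen=True)
class WeightBundle:
    """Per-indicator weight triples (w_ahp, theta, w_combined), all nodes.

    Leaf ``w_combined`` values are global (sum to 1 over the index within
    ``LEAF_SUM_TOL``); internal-node weights equal their children's sums
    within ``ROLLUP_TOL``.
    """

    w_ahp: Mapping[str, float]
    theta: Mapping[str, float]
    w_combined: Mapping[str, float]

    def validate(self, tree: IndicatorTree) -> None:
        for col_name, col in (("w_ahp", self.w_ahp), ("theta", self.theta),
                              ("w_combined", self.w_combined)):
            for code, w in col.items():
                if w < 0:
                    raise IndexConfigError(f"negative weight in column {col_name}", code)
        leaf_sum = sum(self.w_combined[c] for c in tree.leaves)
        if abs(leaf_sum - 1.0) > LEAF_SUM_TOL:
            raise IndexConfigError(f"leaf combined weights sum to {leaf_sum:.6f}, expected 1")
        for node in tree.internal_nodes:
            kid_sum = sum(self.w_combined[k] for k in tree.children(node))
            if abs(kid_sum - self.w_combined[node]) > ROLLUP_TOL:
                raise IndexConfigError(
                    f"combined weight {self.w_combined[node]:.4f} != children sum {kid_sum:.4f}",
                    node,
                )


def _parse_indicator(rec: Mapping[str, Any]) -> Indicator:
    if not isinstance(rec, Mapping) or "code" not in rec:
        raise IndexConfigError(f"indicator record must be a mapping with a 'code': {rec!r}")
    rule_rec = rec.get("rule")
    rule = None
    if rule_rec is not None:
        params = {k: v for k, v in rule_rec.items() if k != "kind"}
        rule = NormalizationRule(rule_rec.get("kind"), params)
    return Indicator(
        code=str(rec["code"]),
        name=str(rec.get("name", rec["code"])),
        direction=rec.get("direction", "positive"),
        rule=rule,
        data_source=rec.get("data_source", "self_report"),
        applicability=rec.get("applicability", {}) or {},
    )


def _parse_config(doc: Mapping[str, Any]) -> tuple[IndicatorTree, WeightBundle | None]:
    if not isinstance(doc, Mapping) or "indicators" not in doc:
        raise IndexConfigError("config must be a mapping with an 'indicators' list")
    records = doc["indicators"]
    indicators = [_parse_indicator(rec) for rec in records]
    tree = IndicatorTree(indicators)
    weight_rows = {str(r["code"]): r.get("weights") for r in records}
    if all(w is not None for w in weight_rows.values()):
        bundle = WeightBundle(
            w_ahp={c: float(w["w_ahp"]) for c, w in weight_rows.items()},
            theta={c: float(w["theta"]) for c, w in weight_rows.items()},
            w_combined={c: float(w["w_combined"]) for c, w in weight_rows.items()},
        )
        bundle.validate(tree)
        return tree, bundle
    return tree, None


def load_index_config(path: str | Path) -> IndicatorTree:
    """Load and validate an indicator-tree YAML config.

    The schema is one record per indicator with fields ``code``, ``name``,
    ``direction``, ``rule`` (leaves only), ``data_source``, optional
    ``applicability`` selector and optional ``weights`` triple.  See the
    packaged ``data/dmi_index_2022.yaml`` for a complete example.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    tree, _ = _parse_config(doc)
    return tree


def table5_fixture() -> tuple[IndicatorTree, WeightBundle]:
    """The packaged 6-domain / 56-leaf DMI index with published weights."""
    ref = resources.files("dmindex").joinpath("data/dmi_index_2022.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    tree, bundle = _parse_config(doc)
    if bundle is None:  # pragma: no cover - packaged file always has weights
        raise IndexConfigError("packaged index is missing weight columns")
    return tree, bundle


def applicable_indicators(
    tree: IndicatorTree,
    institution: Any,
    weights: Mapping[str, float] | None = None,
) -> tuple[list[str], dict[str, float] | None]:
    """Leaves applicable to one institution, with weights renormalized.

    Applicability is declarative: each indicator may restrict the
    institution ``level``/``type`` strings it applies to.  When ``weights``
    are given, the retained leaves' weights are divided by their sum so the
    subset sums to 1 and scores stay on the 100-point scale.
    """
    kept = [c for c in tree.leaves if tree[c].applies_to(institution)]
    if not kept:
        raise IndexConfigError("no applicable indicators for this institution")
    if weights is None:
        return kept, None
    total = sum(weights[c] for c in kept)
    if total <= 0:
        raise IndexConfigError("applicable-leaf weights sum to zero; cannot renormalize")
    return kept, {c: weights[c] / total for c in kept}
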