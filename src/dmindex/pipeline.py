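"""End-to-end assessment pipeline.

Ties the stages together: Delphi screening (optional) -> normalization ->
AHP/entropy combination weighting -> 100-point scoring -> reliability/
validity reporting, writing a weight table, score report, validity report
and a reproducibility manifest to an output directory.  Any stage error
aborts the run, names the stage, and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .delphi import DelphiScoreTable, screen_indicators
from .index_model import IndicatorTree, WeightBundle, load_index_config, table5_fixture
from .normalization import normalize_table
from .scoring import (
    InstitutionRecord,
    cohort_summary,
    qualification_line,
    records_to_frame,
    score_table,
)
from .validation import criterion_regression
from .weighting import (
    JudgmentMatrix,
    aggregate_experts,
    ahp_priority,
    build_weight_bundle,
    entropy_weights,
    global_ahp_weights,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_institution_csv",
           "write_institution_csv"]

logger = logging.getLogger(__name__)

#: covariate columns of the institution CSV; all other columns are leaf codes
METADATA_COLUMNS = (
    "level", "ownership", "type",
    "outpatient_visits", "inpatient_visits",
    "outpatient_revenue", "inpatient_revenue", "penalty_amount",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Inputs, thresholds and reproducibility settings for one run."""

    institution_data: Path
    out_dir: Path
    index_config: Path | None = None        # None -> packaged index
    expert_scores: Path | None = None
    judgment_dir: Path | None = None        # None -> AHP weights from index config
    rho: float = 0.5
    mean_threshold: float = 7.0
    cv_threshold: float = 0.25
    cr_limit: float = 0.1
    qualification: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        for name in ("institution_data", "expert_scores", "judgment_dir", "index_config"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, Path(p))
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        self.out_dir = Path(self.out_dir)


def read_institution_csv(path: Path, tree: IndicatorTree) -> tuple[pd.DataFrame, list[InstitutionRecord]]:
    """Split an institution CSV into raw indicator values and covariates."""
    df = pd.read_csv(path, index_col="id")
    missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"institution CSV lacks covariate columns: {missing_meta}")
    leaf_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    unknown = [c for c in leaf_cols if c not in tree or tree[c].level != 3]
    if unknown:
        raise ValueError(f"institution CSV has non-leaf columns: {unknown}")
    records = [
        InstitutionRecord(id=str(i), **{c: row[c] for c in METADATA_COLUMNS})
        for i, row in df[list(METADATA_COLUMNS)].iterrows()
    ]
    return df[leaf_cols], records


def write_institution_csv(
    path: Path, raw: pd.DataFrame, records: list[InstitutionRecord]
) -> None:
    meta = records_to_frame(records)
    pd.concat([meta, raw], axis=1).to_csv(path, index_label="id")


def _ahp_from_judgments(
    tree: IndicatorTree, judgment_dir: Path, cr_limit: float
) -> tuple[dict[str, float], list[dict]]:
    """AHP leaf weights from per-expert judgment CSVs.

    Files are named ``<group>__<expert>.csv`` where the group is a parent
    indicator code (``root`` for the domain level); rows/columns are the
    sibling codes.  Experts are aggregated by element-wise geometric mean
    before the eigenvector solve; groups breaching the CR limit are logged.
    """
    raw_groups: dict[str | None, list] = {}
    paths = sorted(judgment_dir.glob("*.csv"))
    if not paths:
        raise ValueError(f"no judgment matrix CSVs in {judgment_dir}")
    for p in paths:
        stem = p.stem
        if "__" not in stem:
            raise ValueError(f"judgment file {p.name} not named <group>__<expert>.csv")
        group, expert = stem.split("__", 1)
        df = pd.read_csv(p, index_col=0)
        key = None if group == "root" else group
        raw_groups.setdefault(key, []).append(
            (JudgmentMatrix(a=df.to_numpy(dtype=float), expert=expert),
             [str(c) for c in df.columns])
        )
    local: dict[str | None, dict[str, float]] = {}
    diagnostics = []
    for key, items in raw_groups.items():
        codes = items[0][1]
        if any(c != codes for _, c in items):
            raise ValueError(f"inconsistent sibling codes across experts for group {key!r}")
        agg = aggregate_experts([m for m, _ in items])
        pv = ahp_priority(agg)
        if pv.cr >= cr_limit:
            logger.warning("sibling group %r: CR=%.3f >= %.2f", key, pv.cr, cr_limit)
        diagnostics.append(
            {"group": "root" if key is None else key, "lambda_max": pv.lambda_max,
             "ci": pv.ci, "cr": pv.cr, "consistent": bool(pv.cr < cr_limit)}
        )
        local[key] = dict(zip(codes, pv.weights.tolist()))
    return global_ahp_weights(tree, local), diagnostics


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _weight_frame(tree: IndicatorTree, bundle: WeightBundle) -> pd.DataFrame:
    rows = []
    for code in sorted(tree.codes, key=lambda c: [int(p) for p in c.split(".")]):
        rows.append({
            "code": code, "name": tree[code].name, "level": tree[code].level,
            "w_ahp": bundle.w_ahp[code], "theta": bundle.theta[code],
            "w_combined": bundle.w_combined[code],
        })
    return pd.DataFrame(rows).set_index("code")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full assessment pipeline; returns the run manifest."""
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    stage = "load_index"
    try:
        if config.index_config is None:
            tree, packaged = table5_fixture()
        else:
            tree = load_index_config(config.index_config)
            packaged = None

        if config.expert_scores is not None:
            stage = "screen"
            report = screen_indicators(
                DelphiScoreTable.from_csv(config.expert_scores),
                mean_threshold=config.mean_threshold,
                cv_threshold=config.cv_threshold,
            )
            report.to_csv(emit("screening_report.csv"))

        stage = "read_institutions"
        raw, records = read_institution_csv(config.institution_data, tree)

        stage = "normalize"
        standardized, audit = normalize_table(tree, raw)
        standardized.to_csv(emit("standardized.csv"), index_label="id")
        pd.DataFrame([vars(a) for a in audit]).to_csv(emit("normalization_audit.csv"), index=False)

        stage = "weight"
        ahp_diag: list[dict] = []
        if config.judgment_dir is not None:
            w_leaf, ahp_diag = _ahp_from_judgments(tree, config.judgment_dir, config.cr_limit)
        elif packaged is not None:
            w_leaf = {c: packaged.w_ahp[c] for c in tree.leaves}
        else:
            raise ValueError(
                "no AHP weights: provide judgment matrices or an index config with weights"
            )
        ent = entropy_weights(standardized, {c: w_leaf[c] for c in standardized.columns})
        bundle = build_weight_bundle(
            tree,
            {c: w_leaf[c] for c in standardized.columns},
            ent.theta_by_code(),
            rho=config.rho,
        )
        _weight_frame(tree, bundle).to_csv(emit("weight_table.csv"))
        if ahp_diag:
            pd.DataFrame(ahp_diag).to_csv(emit("ahp_consistency.csv"), index=False)

        stage = "score"
        leaf_w = {c: bundle.w_combined[c] for c in standardized.columns}
        scores = score_table(tree, standardized, leaf_w)
        scores["qualified"] = qualification_line(scores["composite"], config.qualification)
        scores.sort_values("composite", ascending=False).to_csv(emit("scores.csv"), index_label="id")
        inst_frame = records_to_frame(records)
        summary = cohort_summary(scores["composite"], inst_frame)
        emit("score_summary.json").write_text(json.dumps({
            "overall": summary.overall,
            "strata": summary.strata.reset_index().to_dict(orient="records"),
            "f_tests": summary.f_tests.reset_index().to_dict(orient="records"),
        }, indent=2, default=str))

        stage = "validate"
        validity = criterion_regression(scores["composite"], inst_frame, stratify=True)
        emit("validity_report.json").write_text(json.dumps({
            "spearman_r": validity.spearman_r,
            "spearman_p": validity.spearman_p,
            "overall": {"r2": validity.overall.r2, "n": validity.overall.n,
                        "coefficients": validity.overall.coef.to_dict(orient="index")},
            "by_level": {
                lvl: {"r2": t.r2, "n": t.n, "coefficients": t.coef.to_dict(orient="index")}
                for lvl, t in validity.by_level.items()
            },
        }, indent=2))

        stage = "manifest"
        manifest_path = emit("manifest.json")
        manifest = {
            "dmindex_version": __version__,
            "seed": config.seed,
            "rho": config.rho,
            "thresholds": {
                "screening_mean": config.mean_threshold,
                "screening_cv": config.cv_threshold,
                "cr_limit": config.cr_limit,
                "qualification_line": config.qualification,
            },
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in (
                    ("institution_data", config.institution_data),
                    ("index_config", config.index_config),
                    ("expert_scores", config.expert_scores),
                )
                if p is not None
            },
            "outputs": [p.name for p in written],
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
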