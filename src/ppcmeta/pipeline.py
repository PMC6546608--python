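"""Orchestration: validate -> effect sizes -> pooling -> bias -> moderators.

Emits the three pooled-effects tables (all trials, active-control trials only,
and trials disaggregated by control subtype), the publication-bias report and
funnel data, the moderator meta-regression report for the two suites, the
risk-of-bias domain summary, and a machine-readable manifest sufficient to
replay the run. No stage mutates its input files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .data_model import (
    ROB_DOMAINS,
    Dataset,
    Diagnostic,
    read_dataset,
    validate_dataset,
)
from .effect_sizes import ESConfig, compute_comparison_composites
from .meta_regression import run_moderator_suite
from .pooling import (
    PooledResult,
    pool_by_category,
    results_to_frame,
    subgroup_by_control,
)
from .publication_bias import bias_report_row, funnel_points

logger = logging.getLogger("ppcmeta")


class PipelineValidationError(Exception):
    """Raised when dataset validation produces error-level diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        lines = "; ".join(d.message for d in diagnostics)
        super().__init__(f"dataset validation failed: {lines}")


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    studies_path: Path
    arms_path: Path
    measures_path: Path
    out_dir: Path
    control_filter: str = "all"
    es: ESConfig = Field(default_factory=ESConfig)
    meta_regression_method: str = "mom"
    seed: int = 0
    log_level: str = "INFO"


def interpret_d(d: float) -> str:
    """Conventional verbal label for a standardized mean difference
    (0.2 small / 0.5 moderate / 0.8 large)."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    if a >= 0.2:
        return "small"
    return "negligible"


def rob_summary(dataset: Dataset) -> pd.DataFrame:
    """Per-domain counts and percentages of low/high/unclear ratings over
    studies (the data behind a risk-of-bias bar chart)."""
    rows = []
    n = len(dataset.studies)
    for dom in ROB_DOMAINS:
        ratings = [getattr(s.rob, dom) for s in dataset.studies]
        counts = {r: ratings.count(r) for r in ("low", "high", "unclear")}
        row = {"domain": dom, **{f"n_{r}": c for r, c in counts.items()}}
        for r, c in counts.items():
            row[f"pct_{r}"] = 100.0 * c / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_frame(rows: list[PooledResult]) -> pd.DataFrame:
    df = results_to_frame(rows)
    if not df.empty:
        df["magnitude"] = df["d_pooled"].map(interpret_d)
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of every emitted report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = read_dataset(cfg.studies_path, cfg.arms_path, cfg.measures_path)
    logger.info("loaded %d studies, %d measure rows",
                len(dataset.studies), len(dataset.measures))

    diagnostics = validate_dataset(dataset)
    errors = [d for d in diagnostics if d.severity == "error"]
    for d in diagnostics:
        logger.log(logging.ERROR if d.severity == "error" else logging.WARNING,
                   "[%s] %s", d.code, d.message)
    if errors:
        raise PipelineValidationError(errors)

    paths: dict[str, Path] = {}

    composites = compute_comparison_composites(dataset, cfg.es)
    eff_df = pd.DataFrame([{
        "study_id": e.study_id, "comparison_id": e.comparison_id,
        "category": e.category, "d": e.d, "variance": e.variance, "se": e.se,
        "n_total": e.n_total, "n_measures_averaged": e.n_measures_averaged,
    } for e in composites])
    paths["effects"] = out / "effect_sizes.tsv"
    eff_df.to_csv(paths["effects"], sep="\t", index=False)

    tables = {
        "table1_all": pool_by_category(dataset, cfg.es, "all"),
        "table2_active": pool_by_category(dataset, cfg.es, "active_only"),
        "table3_by_control": subgroup_by_control(dataset, cfg.es),
    }
    report_json: dict = {"tables": {}}
    for name, rows in tables.items():
        logger.info("%s: %d rows pooled", name, len(rows))
        paths[name] = out / f"{name}.tsv"
        _pooled_frame(rows).to_csv(paths[name], sep="\t", index=False)
        report_json["tables"][name] = [r.model_dump() for r in rows]

    bias_rows = []
    for suite, flt in (("all", "all"), ("active_only", "active_only")):
        pooled = tables["table1_all" if suite == "all" else "table2_active"]
        from .pooling import _filter_composites  # shared selection logic

        suite_composites = _filter_composites(dataset, cfg.es, flt)
        for row in pooled:
            if row.label == "all_measures":
                effs = suite_composites
            else:
                effs = [e for e in suite_composites if e.category == row.label]
            b = bias_report_row(row.label, effs)
            bias_rows.append({"suite": suite, **b.model_dump()})
        if suite_composites:
            funnel = funnel_points(suite_composites)
            fp = out / f"funnel_{suite}.tsv"
            funnel.to_csv(fp, sep="\t", index=False)
            paths[f"funnel_{suite}"] = fp
    paths["bias"] = out / "bias.tsv"
    pd.DataFrame(bias_rows).to_csv(paths["bias"], sep="\t", index=False)
    report_json["bias"] = bias_rows

    mod_rows = []
    for suite, flt in (("all", "all"), ("active_only", "active_only")):
        results, skips = run_moderator_suite(
            dataset, cfg.es, flt, method=cfg.meta_regression_method
        )
        logger.info("moderator suite %s: %d fits, %d skips", suite, len(results), len(skips))
        for r in results:
            mod_rows.append({
                "suite": suite, "category": r.category, "moderator": r.moderator_name,
                "n_used": r.n_used, "slope": r.slope, "se": r.slope_se,
                "Q_model": r.Q_model, "p": r.p, "tau2_residual": r.tau2_residual,
                "skip_reason": "",
            })
        for s in skips:
            mod_rows.append({
                "suite": suite, "category": s.category, "moderator": s.moderator_name,
                "n_used": None, "slope": None, "se": None, "Q_model": None,
                "p": None, "tau2_residual": None, "skip_reason": s.reason,
            })
    paths["moderators"] = out / "moderators.tsv"
    pd.DataFrame(mod_rows).to_csv(paths["moderators"], sep="\t", index=False)
    report_json["moderators"] = mod_rows

    paths["rob_summary"] = out / "rob_summary.tsv"
    rob_summary(dataset).to_csv(paths["rob_summary"], sep="\t", index=False)

    paths["report_json"] = out / "report.json"
    paths["report_json"].write_text(json.dumps(report_json, indent=2, default=str))

    manifest = {
        "package": "ppcmeta",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "inputs": {
            str(p): _sha256(p)
            for p in (cfg.studies_path, cfg.arms_path, cfg.measures_path)
        },
        "outputs": {k: str(v) for k, v in paths.items()},
        "diagnostics": [d.model_dump() for d in diagnostics],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
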