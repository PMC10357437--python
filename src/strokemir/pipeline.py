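"""Pipeline orchestration: catalog -> meta -> validation -> ROC -> tissue -> ORA.

Stages run independently on whatever inputs the configuration provides;
optional stages (ROC, tissue, enrichment) are skipped with a logged notice
when their inputs are absent.  Any stage failure aborts the run, removes
partial outputs, and names the failing stage.  A JSON manifest records the
run parameters and package version for reproducibility.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import catalog as cat
from . import meta, qpcr, roc, tissue, enrichment

log = logging.getLogger("strokemir")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    catalog_path: str | None = None
    aliases_path: str | None = None
    ct_path: str | None = None
    summaries_path: str | None = None
    expr_path: str | None = None          # wide sample x miRNA table for ROC
    panel: tuple[str, ...] = ()
    tissue_matrix_path: str | None = None
    tissue_map_path: str | None = None
    target_map_path: str | None = None
    gmt_path: str | None = None
    alpha: float = 0.05
    continuity: float = 0.5
    tau2_method: str = "dl"
    roc_mode: str = "in-sample"           # or "k-fold"
    roc_folds: int = 5
    seed: int = 0
    out_dir: str = "strokemir_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("meta")
def _run_meta(config: PipelineConfig, out: Path) -> dict:
    studies, reports = cat.read_catalog(config.catalog_path)
    aliases = cat.read_alias_map(config.aliases_path)
    reports = cat.standardize_names(reports, aliases)
    groups = cat.qualify_groups(studies, reports)
    results = meta.run_all(groups, continuity=config.continuity,
                           tau2_method=config.tau2_method, alpha=config.alpha)
    meta.results_frame(results).to_csv(out / "meta_results.tsv", sep="\t", index=False)
    meta.format_report(results).to_csv(out / "meta_table.tsv", sep="\t", index=False)
    forest = pd.concat(
        [meta.forest_frame(r).assign(mirna=r.canonical_name, specimen=r.specimen)
         for r in results],
        ignore_index=True) if results else pd.DataFrame()
    forest.to_csv(out / "forest_data.tsv", sep="\t", index=False)
    n_sig = sum(r.significant for r in results)
    log.info("meta: %d studies, %d qualified groups, %d significant",
             len(studies), len(groups), n_sig)
    return {"n_studies": len(studies), "n_groups": len(groups), "n_significant": n_sig}


@_stage("validate")
def _run_validate(config: PipelineConfig, out: Path) -> dict:
    if config.ct_path:
        ct = qpcr.read_ct(config.ct_path)
        summaries = qpcr.group_summary(qpcr.relative_expression(ct))
    else:
        summaries = qpcr.read_summaries(config.summaries_path)
    results = qpcr.validate_targets(summaries)
    qpcr.results_frame(results, summaries).to_csv(
        out / "validation_table.tsv", sep="\t", index=False)
    n_sig = sum(r.p < config.alpha for r in results)
    log.info("validate: %d targets, %d significant", len(results), n_sig)
    return {"n_targets": len(results), "n_significant": n_sig}


@_stage("roc")
def _run_roc(config: PipelineConfig, out: Path) -> dict:
    expr = pd.read_csv(config.expr_path)
    labels = (expr["group"] == "stroke").astype(int).to_numpy()
    markers = expr.drop(columns=[c for c in ("sample_id", "group") if c in expr])
    panel = list(config.panel) if config.panel else list(markers.columns)
    singles = roc.single_marker_aucs(markers, labels)
    if config.roc_mode == "k-fold":
        panel_result = roc.cross_validated_panel_auc(
            markers, labels, panel, k=config.roc_folds, seed=config.seed)
    else:
        panel_result = roc.panel_auc(markers, labels, panel)
    summary = {"single_marker_auc": singles, "panel": panel,
               "panel_auc": panel_result.auc, "mode": config.roc_mode}
    (out / "roc_summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame({"fpr": panel_result.fpr, "tpr": panel_result.tpr}).to_csv(
        out / "roc_curve.tsv", sep="\t", index=False)
    log.info("roc: panel AUC %.3f (%s)", panel_result.auc, config.roc_mode)
    return summary


@_stage("tissue")
def _run_tissue(config: PipelineConfig, out: Path) -> dict:
    matrix = tissue.read_matrix(config.tissue_matrix_path)
    mapping = tissue.read_tissue_map(config.tissue_map_path)
    z = tissue.tissue_zscores(matrix, mapping)
    z.to_csv(out / "tissue_zscores.tsv", sep="\t")
    log.info("tissue: %d tissues x %d miRNAs", *z.shape)
    return {"n_tissues": int(z.shape[0]), "n_mirnas": int(z.shape[1])}


@_stage("enrich")
def _run_enrich(config: PipelineConfig, out: Path, mirnas=None) -> dict:
    target_map = enrichment.read_target_map(config.target_map_path)
    collection = enrichment.read_gmt(config.gmt_path)
    mirnas = list(mirnas) if mirnas else sorted(target_map)
    query = enrichment.union_targets(target_map, mirnas)
    results = enrichment.run_ora(query, collection, alpha=config.alpha)
    results.to_csv(out / "enrichment_table.tsv", sep="\t", index=False)
    n_sig = int(results["significant"].sum())
    log.info("enrich: %d sets, %d significant, query %d genes",
             len(results), n_sig, len(query))
    return {"n_sets": len(results), "n_significant": n_sig, "query_size": len(query)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return the manifest."""
    out = Path(config.out_dir)
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(config), "stages": {}}
    try:
        if config.catalog_path and config.aliases_path:
            manifest["stages"]["meta"] = _run_meta(config, out)
        if config.ct_path or config.summaries_path:
            manifest["stages"]["validate"] = _run_validate(config, out)
        if config.expr_path:
            manifest["stages"]["roc"] = _run_roc(config, out)
        else:
            log.info("roc: no expression table supplied, stage skipped")
        if config.tissue_matrix_path and config.tissue_map_path:
            manifest["stages"]["tissue"] = _run_tissue(config, out)
        else:
            log.info("tissue: no matrix supplied, stage skipped")
        if config.target_map_path and config.gmt_path:
            manifest["stages"]["enrich"] = _run_enrich(config, out)
        else:
            log.info("enrich: no gene-set collection supplied, stage skipped")
    except StageError:
        if fresh:
            shutil.rmtree(out, ignore_errors=True)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
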