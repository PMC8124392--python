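"""End-to-end pipeline: filter -> log2 -> impute -> test -> call -> QC -> store.

Driven by a single configuration mapping (typically loaded from YAML by the
CLI); every stage logs row counts, all randomness flows from one seed, and
all artifacts are written under an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign, SampleInfo
from .differential import (
    DifferentialAnalyzer,
    DifferentialResult,
    Thresholds,
    volcano_dataset,
)
from .glygly import filter_glygly, glygly_summary, sites_per_protein
from .preprocess import ImputationParams, IntensityMatrix, filter_rows, impute, log2_transform
from .qc import QCPanel, QCReport, qc_report, replicate_correlation
from .store import SubstrateStore, records_from_results
from .tables_io import (
    ProteinGroupTable,
    read_glygly_sites,
    read_protein_groups,
    write_protein_groups,
    write_results_csv,
)

logger = logging.getLogger("dubscreen")

__all__ = ["PipelineResult", "run_pipeline", "design_from_config", "thresholds_from_config"]


@dataclass
class PipelineResult:
    """Objects and file paths produced by one pipeline run."""

    design: ExperimentDesign
    filtered_table: ProteinGroupTable
    removal_log: dict[str, int]
    matrix: IntensityMatrix
    results: list[DifferentialResult]
    initial_selection: list[DifferentialResult]
    putative_substrates: list[DifferentialResult]
    qc: QCReport
    glygly_sites: dict[str, list[int]]
    out_dir: Path
    artifacts: dict[str, Path]


def design_from_config(config: Mapping[str, Any]) -> ExperimentDesign:
    samples = tuple(
        SampleInfo(s["label"], s["condition"], int(s.get("replicate", i + 1)))
        for i, s in enumerate(config["design"]["samples"])
    )
    return ExperimentDesign(
        experiment_id=config.get("experiment_id", f"{config['dub_name']}_screen"),
        dub_name=config["dub_name"],
        samples=samples,
    )


def thresholds_from_config(config: Mapping[str, Any]) -> Thresholds:
    t = config.get("thresholds", {})
    return Thresholds(
        min_abs_log2_fc=float(t.get("min_abs_log2_fc", 1.0)),
        max_p=float(t.get("max_p", 0.05)),
        min_unique_peptides=int(t.get("min_unique_peptides", 2)),
        direction=t.get("direction", "up"),
    )


def _qc_panel_from_config(config: Mapping[str, Any]) -> QCPanel:
    p = config.get("qc_panel", {})
    kwargs = {}
    for key in ("carboxylase_genes", "ubiquitin_ids", "avidin_ids"):
        if key in p:
            kwargs[key] = frozenset(p[key])
    return QCPanel(**kwargs)


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(DifferentialResult)]
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=cols)


def run_synthetic_screen(config=None, imputation_seed: int | None = None):
    """Generate a synthetic screen and run the in-memory pipeline on it.

    Returns ``(analyzer, truth, design)`` where ``analyzer`` is the fitted
    :class:`~dubscreen.differential.DifferentialAnalyzer`.  Convenience used
    for recovery benchmarking; the imputation seed defaults to the
    generator's seed.
    """
    import warnings

    from .simulate import SyntheticConfig, generate_tables

    cfg = config or SyntheticConfig()
    table, _, truth, design = generate_tables(cfg)
    filtered, _ = filter_rows(table)
    matrix = impute(
        log2_transform(filtered, design),
        ImputationParams(seed=cfg.seed if imputation_seed is None else imputation_seed),
    )
    with warnings.catch_warnings():
        # the synthetic screen has no row for the silenced DUB itself
        warnings.filterwarnings("ignore", message=".*silenced DUB.*")
        analyzer = DifferentialAnalyzer().fit(matrix, filtered)
    return analyzer, truth, design


def results_from_frame(df: pd.DataFrame) -> list[DifferentialResult]:
    """Rebuild differential results from a differential.csv frame."""
    fields = {f.name: f for f in dataclasses.fields(DifferentialResult)}
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in fields:
            value = row[name]
            if name in ("n_imputed_control", "n_imputed_silenced", "unique_peptides"):
                value = int(value)
            elif name in ("log2_fc", "p_value", "t_statistic", "mean_control", "mean_silenced"):
                value = float(value)
            else:
                value = "" if pd.isna(value) else str(value)
            kwargs[name] = value
        out.append(DifferentialResult(**kwargs))
    return out


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on the inputs named by ``config``.

    Deterministic for a fixed ``seed``.  Raises ``RuntimeError`` naming the
    stage on any stage failure; if ``config["strict_qc"]`` is set, a failing
    QC report also raises.
    """
    out = Path(out_dir or config.get("output_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    design = design_from_config(config)
    thresholds = thresholds_from_config(config)
    seed = int(config.get("seed", 0))
    columns = config.get("columns") or None
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    table = stage(
        "read", read_protein_groups, config["inputs"]["protein_groups"], design, columns
    )
    logger.info("read: %d protein groups, %d samples", len(table), len(table.sample_labels))

    filtered, removal_log = stage("filter", filter_rows, table)
    logger.info("filter: %d -> %d rows (removed %s)", len(table), len(filtered), removal_log)
    artifacts["filtered_protein_groups"] = out / "filtered_protein_groups.tsv"
    write_protein_groups(filtered, artifacts["filtered_protein_groups"])

    matrix = stage("log2", log2_transform, filtered, design)
    imp_cfg = config.get("imputation", {})
    params = ImputationParams(
        width=float(imp_cfg.get("width", 0.3)),
        downshift=float(imp_cfg.get("downshift", 1.8)),
        mode=imp_cfg.get("mode", "per_column"),
        seed=seed,
    )
    matrix = stage("impute", impute, matrix, params)
    n_imputed = int(matrix.imputed_mask.sum())
    logger.info("impute: %d of %d cells imputed", n_imputed, matrix.values.size)
    artifacts["imputed_matrix"] = out / "imputed_matrix.csv"
    artifacts["imputation_mask"] = out / "imputation_mask.csv"
    matrix.to_frame().to_csv(artifacts["imputed_matrix"], index_label="protein_ids")
    matrix.mask_frame().to_csv(artifacts["imputation_mask"], index_label="protein_ids")

    panel = _qc_panel_from_config(config)
    analyzer = DifferentialAnalyzer(
        thresholds=thresholds,
        qc_genes=panel.all_ids,
        p_adjust=config.get("correction", {}).get("method", "none"),
    )
    stage("differential", analyzer.fit, matrix, filtered)
    results = analyzer.results_
    logger.info(
        "differential: %d tested, %d initial, %d putative",
        len(results),
        len(analyzer.initial_selection_),
        len(analyzer.putative_substrates_),
    )
    artifacts["differential"] = out / "differential.csv"
    write_results_csv(results_to_frame(results), artifacts["differential"])
    artifacts["initial_selection"] = out / "initial_selection.csv"
    write_results_csv(results_to_frame(analyzer.initial_selection_), artifacts["initial_selection"])
    artifacts["putative_substrates"] = out / "putative_substrates.csv"
    write_results_csv(
        results_to_frame(analyzer.putative_substrates_), artifacts["putative_substrates"]
    )

    volcano = volcano_dataset(results, thresholds)
    artifacts["volcano"] = out / "volcano.csv"
    write_results_csv(
        pd.DataFrame(volcano, columns=["gene_name", "description", "log2_fc", "neg_log10_p", "category"]),
        artifacts["volcano"],
    )

    report = stage("qc", qc_report, results, panel, thresholds)
    corr = replicate_correlation(matrix)
    artifacts["correlation"] = out / "replicate_correlation.csv"
    pd.DataFrame(corr, index=matrix.sample_labels, columns=matrix.sample_labels).to_csv(
        artifacts["correlation"]
    )
    artifacts["qc_report"] = out / "qc_report.json"
    artifacts["qc_report"].write_text(
        json.dumps(
            {
                "passed": report.passed,
                "warnings": list(report.warnings),
                "members": [dataclasses.asdict(m) for m in report.members],
                "removal_log": removal_log,
                "n_imputed_cells": n_imputed,
            },
            indent=2,
        )
    )
    logger.info("qc: %s", "pass" if report.passed else f"FAIL ({report.offenders()})")

    glygly_map: dict[str, list[int]] = {}
    gg_path = config.get("inputs", {}).get("glygly_sites")
    if gg_path:
        gg_rows = stage("glygly_read", read_glygly_sites, gg_path, design, columns)
        min_prob = float(config.get("glygly", {}).get("min_probability", 0.75))
        kept, gg_log = filter_glygly(gg_rows, min_prob)
        logger.info("glygly: %d -> %d sites (removed %s)", len(gg_rows), len(kept), gg_log)
        glygly_map = sites_per_protein(kept)
        artifacts["glygly_summary"] = out / "glygly_summary.json"
        artifacts["glygly_summary"].write_text(
            json.dumps(glygly_summary(gg_rows, min_prob), indent=2)
        )

    artifacts["store"] = out / "substrates.sqlite"
    if artifacts["store"].exists():
        artifacts["store"].unlink()
    with SubstrateStore(artifacts["store"]) as store:
        store.ingest(
            records_from_results(results, design.dub_name, glygly_map),
            experiment_id=design.experiment_id,
            experiment_meta=config.get("experiment_meta", {}),
        )
        store.set_thresholds(thresholds)

    if config.get("strict_qc") and not report.passed:
        raise RuntimeError(f"QC failed: significant shift in {report.offenders()}")

    return PipelineResult(
        design=design,
        filtered_table=filtered,
        removal_log=removal_log,
        matrix=matrix,
        results=results,
        initial_selection=analyzer.initial_selection_,
        putative_substrates=analyzer.putative_substrates_,
        qc=report,
        glygly_sites=glygly_map,
        out_dir=out,
        artifacts=artifacts,
    )
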