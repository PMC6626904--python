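"""End-to-end orchestration: cleanup -> clustering -> features -> classification.

``run_pipeline`` executes the full analysis on an in-memory cohort (or one
simulated from a config), returning a :class:`PipelineResult`; ``write_run``
persists every stage's exports (TSV tables, JSON reports, a parameter log
with every threshold actually applied) into a run directory.  Re-running
with the same config and inputs reproduces all numeric outputs
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import CvReport, double_loocv, pca_selected
from .cleanup import CleanupReport, clean_sample
from .cluster import (
    ClusterModel,
    MetaClusterModel,
    annotate_metaclusters,
    cluster_events,
    event_meta_ids,
    filter_small_clusters,
    metacluster,
)
from .features import FeatureTable, build_feature_table
from .panel import CohortManifest, EventTable, arcsinh_transform
from .simulate import GroundTruth, SimulationConfig, simulate_cohort
from .stats import abundance_table, cohort_summaries, compare_groups

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_run"]


@dataclass
class PipelineConfig:
    cofactor: float = 5.0
    k_clusters: int = 49
    n_meta: int = 15
    min_cluster_fraction: float = 1e-5
    min_meta_fraction: float = 0.005
    min_cells: int = 10
    lambda_grid_size: int = 50
    lambda_grid_ratio: float = 1e-3
    models: tuple[str, ...] = ("basal", "ratio", "combined")
    seed: int = 0
    cleanup: bool = True

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "cofactor": self.cofactor,
            "k_clusters": self.k_clusters,
            "n_meta": self.n_meta,
            "min_cluster_fraction": self.min_cluster_fraction,
            "min_meta_fraction": self.min_meta_fraction,
            "min_cells": self.min_cells,
            "lambda_grid_size": self.lambda_grid_size,
            "lambda_grid_ratio": self.lambda_grid_ratio,
            "models": list(self.models),
            "seed": self.seed,
            "cleanup": self.cleanup,
        }


@dataclass
class PipelineResult:
    manifest: CohortManifest
    cleanup_reports: list[CleanupReport]
    cluster_model: ClusterModel
    meta_model: MetaClusterModel
    meta_ids_per_table: list[np.ndarray]
    tables: list[EventTable]  # cleaned, arcsinh-transformed
    feature_tables: dict[str, FeatureTable]
    cv_reports: dict[str, CvReport]
    comparisons: pd.DataFrame
    abundances: pd.DataFrame
    pooled_abundance: pd.Series
    pca_scores: np.ndarray | None
    pca_explained: np.ndarray | None
    config: PipelineConfig
    truth: GroundTruth | None = None
    stage_counts: dict[str, int] = field(default_factory=dict)
    keep_masks: list[np.ndarray] = field(default_factory=list)  # cleanup mask per input table


def _stage(name: str):
    """Tag exceptions with the pipeline stage they came from."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(
    tables: list[EventTable],
    manifest: CohortManifest,
    config: PipelineConfig | None = None,
    truth: GroundTruth | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    stage_counts: dict[str, int] = {"input_events": int(sum(t.n_events for t in tables))}

    with _stage("cleanup"):
        cleanup_reports: list[CleanupReport] = []
        cleaned: list[EventTable] = []
        keep_masks: list[np.ndarray] = []
        for i, table in enumerate(tables):
            if config.cleanup:
                kept, report, _ = clean_sample(table, seed=config.seed + i)
                cleanup_reports.append(report)
                cleaned.append(kept)
                keep_masks.append(report.keep_mask)
            else:
                cleaned.append(table)
                keep_masks.append(np.ones(table.n_events, dtype=bool))
        stage_counts["after_cleanup"] = int(sum(t.n_events for t in cleaned))

    with _stage("transform"):
        transformed = [arcsinh_transform(t, cofactor=config.cofactor) for t in cleaned]

    with _stage("cluster"):
        pooled = np.vstack([t.phenotyping_matrix() for t in transformed])
        model = cluster_events(pooled, k=config.k_clusters, seed=config.seed)
        model = filter_small_clusters(model, config.min_cluster_fraction)
        meta = metacluster(model, config.n_meta, config.min_meta_fraction)
        meta_ids_all = event_meta_ids(model, meta)
        markers = transformed[0].panel.phenotyping_markers
        annotate_metaclusters(meta, pooled, meta_ids_all, markers)
        # split pooled meta ids back per table
        meta_ids_per_table = []
        offset = 0
        for t in transformed:
            meta_ids_per_table.append(meta_ids_all[offset : offset + t.n_events])
            offset += t.n_events
        stage_counts["after_meta_filter"] = int((meta_ids_all >= 0).sum())

    with _stage("features"):
        feature_tables = {
            m: build_feature_table(
                transformed, meta_ids_per_table, meta, manifest, model=m,
                min_cells=config.min_cells,
            )
            for m in config.models
        }

    with _stage("classify"):
        cv_reports = {
            m: double_loocv(
                ft,
                grid_size=config.lambda_grid_size,
                grid_ratio=config.lambda_grid_ratio,
            )
            for m, ft in feature_tables.items()
        }
        pca_scores = pca_explained = None
        if cv_reports:
            ref = "combined" if "combined" in cv_reports else list(cv_reports)[0]
            selected = [d for d, _ in cv_reports[ref].final_nonzero]
            if len(selected) >= 2:
                pca_scores, pca_explained = pca_selected(feature_tables[ref], selected)

    with _stage("compare"):
        summaries = cohort_summaries(transformed, meta_ids_per_table, meta)
        comparisons = compare_groups(summaries)
        abundances, pooled_abundance = abundance_table(
            transformed, meta_ids_per_table, meta
        )

    return PipelineResult(
        manifest=manifest,
        cleanup_reports=cleanup_reports,
        cluster_model=model,
        meta_model=meta,
        meta_ids_per_table=meta_ids_per_table,
        tables=transformed,
        feature_tables=feature_tables,
        cv_reports=cv_reports,
        comparisons=comparisons,
        abundances=abundances,
        pooled_abundance=pooled_abundance,
        pca_scores=pca_scores,
        pca_explained=pca_explained,
        config=config,
        truth=truth,
        stage_counts=stage_counts,
        keep_masks=keep_masks,
    )


def run_simulated(
    sim_config: SimulationConfig, config: PipelineConfig | None = None
) -> PipelineResult:
    manifest, tables, truth = simulate_cohort(sim_config)
    return run_pipeline(tables, manifest, config=config, truth=truth)


def write_run(result: PipelineResult, outdir) -> Path:
    """Persist all exports of a pipeline run into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "params.json").write_text(json.dumps(result.config.to_dict(), indent=2))
    (outdir / "stage_counts.json").write_text(json.dumps(result.stage_counts, indent=2))
    (outdir / "cleanup_report.json").write_text(
        json.dumps([r.to_dict() for r in result.cleanup_reports], indent=2)
    )

    meta = result.meta_model
    profile_rows = []
    for m in meta.kept_meta_ids():
        profile_rows.append(
            {
                "meta_id": int(m),
                "annotation": meta.annotations.get(int(m), "unassigned"),
                "events": int(meta.meta_sizes[m]),
                "fraction": float(meta.abundance[m]),
            }
        )
    pd.DataFrame(profile_rows).to_csv(outdir / "metaclusters.tsv", sep="\t", index=False)

    for name, ft in result.feature_tables.items():
        ft.to_frame().to_csv(outdir / f"features_{name}.tsv", sep="\t")
    for name, rep in result.cv_reports.items():
        (outdir / f"cv_report_{name}.json").write_text(json.dumps(rep.to_dict(), indent=2))
        coef = pd.DataFrame(
            [(d.column_name, c) for d, c in rep.final_nonzero],
            columns=["feature", "coefficient"],
        )
        coef.to_csv(outdir / f"coefficients_{name}.tsv", sep="\t", index=False)

    result.comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
    result.abundances.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    result.pooled_abundance.to_csv(outdir / "abundance_pooled.tsv", sep="\t")
    if result.pca_scores is not None:
        ref = "combined" if "combined" in result.cv_reports else list(result.cv_reports)[0]
        ft = result.feature_tables[ref]
        pca = pd.DataFrame(result.pca_scores, columns=["PC1", "PC2"], index=ft.individuals)
        pca.insert(0, "group", np.where(ft.labels == 1, "RA", "HD"))
        pca.to_csv(outdir / "pca_scores.tsv", sep="\t")
        np.savetxt(outdir / "pca_explained.tsv", result.pca_explained[None, :], delimiter="\t")
    return outdir
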