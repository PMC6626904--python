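"""Per-individual feature tables for classification.

For every kept meta-cluster and every functional marker, three summaries
of the arcsinh-scale single-cell values are available per individual:

``median_basal``
    Median over the individual's unstimulated events in that meta.
``q90_basal``
    90% quantile of the same values (linear interpolation between order
    statistics, ``h = (n-1) * 0.9``).
``arcsinh_ratio``
    Stimulation-induced change: median(stim) - median(basal) on the
    arcsinh scale.

The three model variants select columns: ``basal`` = medians + q90s,
``ratio`` = arcsinh ratios, ``combined`` = both.  Cells backed by fewer
than ``min_cells`` events are imputed with the cohort median of their
column and logged; the pre-imputation values (with NaNs) are retained so
cross-validation can re-impute strictly within training rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import MetaClusterModel
from .panel import CohortManifest, EventTable

__all__ = [
    "FeatureDescriptor",
    "FeatureTable",
    "subset_summary",
    "arcsinh_ratio",
    "build_feature_table",
    "MODELS",
    "STATISTICS",
]

MODELS = ("basal", "ratio", "combined")
BASAL_STATS = ("median_basal", "q90_basal")
RATIO_STATS = ("arcsinh_ratio",)
STATISTICS = BASAL_STATS + RATIO_STATS


@dataclass(frozen=True)
class FeatureDescriptor:
    meta_id: int
    annotation: str
    marker: str
    statistic: str

    @property
    def column_name(self) -> str:
        tag = self.annotation.replace(" ", "-")
        return f"meta{self.meta_id}_{tag}__{self.marker}__{self.statistic}"


@dataclass
class FeatureTable:
    matrix: np.ndarray  # individuals x features, imputed (no NaN)
    raw_matrix: np.ndarray  # same, with NaN where a cell was below min_cells
    descriptors: list[FeatureDescriptor]
    individuals: list[str]
    labels: np.ndarray  # 0 = HD, 1 = RA
    model: str
    imputation_log: list[tuple[str, str, str]] = field(default_factory=list)
    min_cells: int = 10

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.matrix,
            index=self.individuals,
            columns=[d.column_name for d in self.descriptors],
        )
        frame.insert(0, "group", np.where(self.labels == 1, "RA", "HD"))
        return frame


def subset_summary(values: np.ndarray, statistic: str) -> float:
    """Median or 90% quantile; empty input signals a missing cell (NaN)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan")
    if statistic in ("median", "median_basal"):
        return float(np.median(values))
    if statistic in ("q90", "q90_basal"):
        return float(np.quantile(values, 0.9))  # linear interpolation
    raise ValueError(f"unknown statistic {statistic!r}")


def arcsinh_ratio(stim_values: np.ndarray, basal_values: np.ndarray) -> float:
    """median(stim) - median(basal), both already on the arcsinh scale."""
    stim_values = np.asarray(stim_values, dtype=float)
    basal_values = np.asarray(basal_values, dtype=float)
    if stim_values.size == 0 or basal_values.size == 0:
        return float("nan")
    return float(np.median(stim_values) - np.median(basal_values))


def feature_descriptors(
    meta: MetaClusterModel, functional_markers: list[str], model: str
) -> list[FeatureDescriptor]:
    """Deterministic (meta, marker, statistic) column order."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    stats = {
        "basal": BASAL_STATS,
        "ratio": RATIO_STATS,
        "combined": BASAL_STATS + RATIO_STATS,
    }[model]
    out = []
    for m in meta.kept_meta_ids():
        annotation = meta.annotations.get(int(m), "unassigned")
        for marker in functional_markers:
            for stat in stats:
                out.append(FeatureDescriptor(int(m), annotation, marker, stat))
    return out


def build_feature_table(
    tables: list[EventTable],
    meta_ids_per_table: list[np.ndarray],
    meta: MetaClusterModel,
    manifest: CohortManifest,
    model: str = "combined",
    min_cells: int = 10,
) -> FeatureTable:
    """Assemble the individuals x features design matrix.

    ``tables`` must be arcsinh-transformed and aligned 1:1 with
    ``meta_ids_per_table`` (per-event kept-meta id, -1 = discarded).  Every
    individual needs basal events; stim events are required for the ratio
    and combined models.
    """
    need_stim = model in ("ratio", "combined")
    if need_stim:
        manifest.require_paired()

    markers = None
    by_sample: dict[tuple[str, str], tuple[EventTable, np.ndarray]] = {}
    for table, mids in zip(tables, meta_ids_per_table):
        if not table.transformed:
            raise ValueError("feature extraction expects arcsinh-transformed tables")
        by_sample[(table.individual_id, table.condition)] = (table, mids)
        markers = table.panel.functional_markers

    individuals = manifest.individuals
    for iid in individuals:
        if (iid, "basal") not in by_sample:
            raise ValueError(f"individual {iid} has no basal events")
        if need_stim and (iid, "stim") not in by_sample:
            raise ValueError(f"individual {iid} has no stim events")

    descriptors = feature_descriptors(meta, markers, model)
    n, p = len(individuals), len(descriptors)
    raw = np.full((n, p), np.nan)

    # cache per (individual, condition, meta): functional value matrix
    def functional_values(iid: str, condition: str, meta_id: int) -> np.ndarray:
        table, mids = by_sample[(iid, condition)]
        return table.functional_matrix()[mids == meta_id]

    marker_col = {m: j for j, m in enumerate(markers)}
    for i, iid in enumerate(individuals):
        for m in meta.kept_meta_ids():
            basal = functional_values(iid, "basal", int(m))
            stim = functional_values(iid, "stim", int(m)) if need_stim else None
            for j, desc in enumerate(descriptors):
                if desc.meta_id != int(m):
                    continue
                col = marker_col[desc.marker]
                if desc.statistic == "arcsinh_ratio":
                    if basal.shape[0] >= min_cells and stim.shape[0] >= min_cells:
                        raw[i, j] = arcsinh_ratio(stim[:, col], basal[:, col])
                else:
                    if basal.shape[0] >= min_cells:
                        raw[i, j] = subset_summary(basal[:, col], desc.statistic)

    matrix = raw.copy()
    log: list[tuple[str, str, str]] = []
    for j, desc in enumerate(descriptors):
        missing = np.isnan(raw[:, j])
        if missing.any():
            finite = raw[~missing, j]
            fill = float(np.median(finite)) if finite.size else 0.0
            matrix[missing, j] = fill
            for i in np.flatnonzero(missing):
                log.append((individuals[i], desc.column_name, "below min_cells"))

    labels = np.array([1 if manifest.group_of(i) == "RA" else 0 for i in individuals])
    return FeatureTable(
        matrix=matrix,
        raw_matrix=raw,
        descriptors=descriptors,
        individuals=list(individuals),
        labels=labels,
        model=model,
        imputation_log=log,
        min_cells=min_cells,
    )
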