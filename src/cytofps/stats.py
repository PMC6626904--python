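"""Group-comparison statistics and abundance tables.

Per (kept meta-cluster, functional marker, condition, summary statistic)
the two groups' per-individual summaries are compared with a two-sided
Mann-Whitney U test: exact by enumeration when n1*n2 <= 400 and there are
no ties, otherwise the normal approximation with tie and continuity
corrections.  P-values are reported raw — no multiplicity adjustment by
default (an optional Benjamini-Hochberg column can be switched on).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import MetaClusterModel
from .panel import EventTable

__all__ = [
    "mwu_test",
    "cohort_summaries",
    "compare_groups",
    "abundance_table",
]

SUMMARY_STATS = ("median", "q75")


def mwu_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    if has_ties and np.unique(pooled).size == 1:
        # all values identical: U at its null mean, no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def cohort_summaries(
    tables: list[EventTable],
    meta_ids_per_table: list[np.ndarray],
    meta: MetaClusterModel,
    min_cells: int = 1,
) -> pd.DataFrame:
    """Per-individual, per-condition, per-meta functional-marker medians and
    75th percentiles (arcsinh scale); one row per combination."""
    rows = []
    for table, mids in zip(tables, meta_ids_per_table):
        if not table.transformed:
            raise ValueError("summaries expect arcsinh-transformed tables")
        markers = table.panel.functional_markers
        func = table.functional_matrix()
        for m in meta.kept_meta_ids():
            sel = func[mids == m]
            if sel.shape[0] < min_cells:
                continue
            annotation = meta.annotations.get(int(m), "unassigned")
            med = np.median(sel, axis=0)
            q75 = np.quantile(sel, 0.75, axis=0)
            for j, marker in enumerate(markers):
                rows.append(
                    {
                        "individual_id": table.individual_id,
                        "group": table.group,
                        "condition": table.condition,
                        "meta_id": int(m),
                        "annotation": annotation,
                        "marker": marker,
                        "median": float(med[j]),
                        "q75": float(q75[j]),
                    }
                )
    return pd.DataFrame(rows)


def compare_groups(summaries: pd.DataFrame, adjust: bool = False) -> pd.DataFrame:
    """One Mann-Whitney test per (meta, marker, condition, statistic).

    Requires >= 3 individuals per group.  Rows are sorted by ascending
    p-value; ``direction`` is read off the group medians.  ``adjust=True``
    appends a Benjamini-Hochberg column (off by default: raw p-values only).
    """
    out = []
    grouped = summaries.groupby(["meta_id", "annotation", "marker", "condition"], sort=True)
    for (meta_id, annotation, marker, condition), chunk in grouped:
        hd = chunk[chunk["group"] == "HD"]
        ra = chunk[chunk["group"] == "RA"]
        if len(hd) < 3 or len(ra) < 3:
            raise ValueError("need summaries for at least 3 individuals per group")
        for stat in SUMMARY_STATS:
            a = hd[stat].to_numpy()
            b = ra[stat].to_numpy()
            u, p = mwu_test(a, b)
            direction = "HD>RA" if np.median(a) > np.median(b) else "RA>HD"
            out.append(
                {
                    "meta_id": meta_id,
                    "annotation": annotation,
                    "marker": marker,
                    "condition": condition,
                    "statistic": stat,
                    "U": u,
                    "p_two_sided": p,
                    "direction": direction,
                }
            )
    frame = pd.DataFrame(out).sort_values("p_two_sided", kind="mergesort").reset_index(drop=True)
    frame.attrs["multiplicity_adjusted"] = adjust
    if adjust:
        p = frame["p_two_sided"].to_numpy()
        m = p.size
        order = np.argsort(p)
        bh = np.empty(m)
        running = 1.0
        for rank_rev, idx in enumerate(order[::-1]):
            rank = m - rank_rev
            running = min(running, p[idx] * m / rank)
            bh[idx] = running
        frame["p_bh"] = bh
    return frame


def abundance_table(
    tables: list[EventTable],
    meta_ids_per_table: list[np.ndarray],
    meta: MetaClusterModel,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-individual, per-condition meta-cluster fractions (rows sum to 1
    over kept metas) plus the pooled fractions across all samples."""
    kept = meta.kept_meta_ids()
    rows = []
    pooled = np.zeros(kept.size)
    for table, mids in zip(tables, meta_ids_per_table):
        counts = np.array([(mids == m).sum() for m in kept], dtype=float)
        pooled += counts
        total = counts.sum()
        fracs = counts / total if total else counts
        row = {
            "individual_id": table.individual_id,
            "group": table.group,
            "condition": table.condition,
        }
        for m, f in zip(kept, fracs):
            label = meta.annotations.get(int(m), "unassigned")
            row[f"meta{m}_{label.replace(' ', '-')}"] = f
        rows.append(row)
    frame = pd.DataFrame(rows)
    pooled_fracs = pd.Series(
        pooled / pooled.sum() if pooled.sum() else pooled,
        index=[
            f"meta{m}_{meta.annotations.get(int(m), 'unassigned').replace(' ', '-')}"
            for m in kept
        ],
        name="pooled_fraction",
    )
    return frame, pooled_fracs
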