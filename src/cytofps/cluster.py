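"""Farthest-point-sampling clustering and complete-linkage meta-clustering.

Events (arcsinh-scale phenotyping markers, pooled over all individuals and
both conditions) are clustered by greedy farthest point sampling — the
classical 2-approximation to the k-center problem and a cheap k-means
surrogate for data too large for Lloyd iterations.  Clusters are induced
as Voronoi cells of the sampled representatives.  Tiny clusters (fraction
< 1e-5 of all events) are discarded; the surviving representatives are
agglomerated by complete linkage into ``n_meta`` meta-clusters; metas
holding < 0.5% of all events are discarded; the survivors are annotated as
immune subsets from their median phenotyping profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterModel",
    "MetaClusterModel",
    "farthest_point_sampling",
    "assign_events",
    "cluster_events",
    "filter_small_clusters",
    "metacluster",
    "metacluster_profiles",
    "annotate_metaclusters",
    "annotate_profile",
    "event_meta_ids",
    "covering_radius",
]

_BOUNDARY_EPS = 1e-9  # absolute slack on size-filter thresholds (float-exact boundaries)


def farthest_point_sampling(
    points: np.ndarray,
    k: int,
    seed: int | None = None,
    start: int | None = None,
) -> np.ndarray:
    """Greedy farthest point sampling; returns ``k`` row indices in pick order.

    The first index is chosen uniformly at random under ``seed`` (or fixed
    via ``start``); each subsequent pick maximizes the minimum Euclidean
    distance to all previous picks, ties broken by lowest index.  O(nk)
    time, O(n) memory (one running min-distance array).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points ({n})")
    if start is None:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(n))
    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    # squared distances preserve the argmax and its ties
    mind = ((points - points[start]) ** 2).sum(axis=1)
    for i in range(1, k):
        j = int(np.argmax(mind))  # first occurrence = lowest index
        if mind[j] <= 0.0:
            raise ValueError(f"fewer than k={k} distinct points")
        chosen[i] = j
        d = ((points - points[j]) ** 2).sum(axis=1)
        np.minimum(mind, d, out=mind)
    return chosen


def assign_events(
    points: np.ndarray, representatives: np.ndarray, chunk: int = 200_000
) -> np.ndarray:
    """Nearest-representative (Voronoi) assignment, ties to lowest index."""
    points = np.asarray(points, dtype=float)
    representatives = np.asarray(representatives, dtype=float)
    out = np.empty(points.shape[0], dtype=int)
    for lo in range(0, points.shape[0], chunk):
        hi = min(lo + chunk, points.shape[0])
        d = cdist(points[lo:hi], representatives, metric="sqeuclidean")
        out[lo:hi] = d.argmin(axis=1)  # argmin -> first occurrence on ties
    return out


def covering_radius(points: np.ndarray, representatives: np.ndarray) -> float:
    """Max over points of the distance to the nearest representative."""
    d = cdist(points, representatives)
    return float(d.min(axis=1).max())


@dataclass
class ClusterModel:
    representatives: np.ndarray  # (K, d), arcsinh scale
    representative_indices: np.ndarray  # event indices chosen by FPS
    assignments: np.ndarray  # per-event nearest representative in 0..K-1
    cluster_sizes: np.ndarray  # (K,)
    kept_clusters: np.ndarray  # bool (K,); all True before filtering
    min_cluster_fraction: float = 1e-5
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return self.representatives.shape[0]

    @property
    def n_total(self) -> int:
        return int(self.assignments.shape[0])

    def event_kept(self) -> np.ndarray:
        return self.kept_clusters[self.assignments]


@dataclass
class MetaClusterModel:
    linkage: np.ndarray  # scipy complete-linkage dendrogram over kept representatives
    n_meta: int
    meta_of_cluster: np.ndarray  # (K,), meta id in 0..n_meta-1, -1 for discarded clusters
    meta_sizes: np.ndarray  # (n_meta,) event counts
    kept_metas: np.ndarray  # bool (n_meta,)
    min_meta_fraction: float = 0.005
    n_total: int = 0
    annotations: dict[int, str] = field(default_factory=dict)

    @property
    def abundance(self) -> np.ndarray:
        return self.meta_sizes / max(self.n_total, 1)

    def kept_meta_ids(self) -> np.ndarray:
        return np.flatnonzero(self.kept_metas)


def cluster_events(
    points: np.ndarray, k: int = 49, seed: int | None = None, start: int | None = None
) -> ClusterModel:
    idx = farthest_point_sampling(points, k, seed=seed, start=start)
    reps = np.asarray(points, dtype=float)[idx].copy()
    assignments = assign_events(points, reps)
    sizes = np.bincount(assignments, minlength=k)
    return ClusterModel(
        representatives=reps,
        representative_indices=idx,
        assignments=assignments,
        cluster_sizes=sizes,
        kept_clusters=np.ones(k, dtype=bool),
        seed=seed,
    )


def filter_small_clusters(model: ClusterModel, min_fraction: float = 1e-5) -> ClusterModel:
    """Discard clusters with size strictly less than ``min_fraction`` of all
    events (boundary-inclusive keep)."""
    threshold = min_fraction * model.n_total
    kept = model.cluster_sizes >= threshold - _BOUNDARY_EPS * max(1.0, threshold)
    if not kept.any():
        raise ValueError("size filter discarded every cluster")
    return replace(model, kept_clusters=kept, min_cluster_fraction=min_fraction)


def metacluster(
    model: ClusterModel, n_meta: int = 15, min_meta_fraction: float = 0.005
) -> MetaClusterModel:
    """Complete-linkage agglomeration of kept representatives, cut at
    ``n_meta`` groups; metas holding < ``min_meta_fraction`` of all events
    (pre-filter denominator) are discarded."""
    kept_ids = np.flatnonzero(model.kept_clusters)
    if kept_ids.size < n_meta:
        raise ValueError(
            f"need at least n_meta={n_meta} kept clusters, have {kept_ids.size}"
        )
    reps = model.representatives[kept_ids]
    Z = linkage(reps, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_meta, criterion="maxclust") - 1  # 0-based

    meta_of_cluster = np.full(model.n_clusters, -1, dtype=int)
    meta_of_cluster[kept_ids] = labels
    meta_sizes = np.zeros(n_meta, dtype=int)
    for cid, m in zip(kept_ids, labels):
        meta_sizes[m] += model.cluster_sizes[cid]

    threshold = min_meta_fraction * model.n_total
    kept_metas = meta_sizes >= threshold - _BOUNDARY_EPS * max(1.0, threshold)
    return MetaClusterModel(
        linkage=Z,
        n_meta=n_meta,
        meta_of_cluster=meta_of_cluster,
        meta_sizes=meta_sizes,
        kept_metas=kept_metas,
        min_meta_fraction=min_meta_fraction,
        n_total=model.n_total,
    )


def event_meta_ids(model: ClusterModel, meta: MetaClusterModel) -> np.ndarray:
    """Per-event meta id; -1 for events of discarded clusters or metas."""
    out = meta.meta_of_cluster[model.assignments]
    kept_lookup = np.append(meta.kept_metas, False)  # index -1 lands on False
    return np.where(kept_lookup[out], out, -1)


def metacluster_profiles(
    points: np.ndarray, meta_ids: np.ndarray, meta: MetaClusterModel
) -> dict[int, np.ndarray]:
    """Median phenotyping profile (arcsinh scale) per kept meta-cluster."""
    profiles: dict[int, np.ndarray] = {}
    for m in meta.kept_meta_ids():
        mask = meta_ids == m
        if mask.any():
            profiles[int(m)] = np.median(points[mask], axis=0)
        else:
            profiles[int(m)] = np.zeros(points.shape[1])
    return profiles


def annotate_profile(hi: dict[str, bool]) -> str:
    """Fixed-priority subset rule table over hi/lo marker calls."""
    if hi["CD20"] and hi["HLA-DR"]:
        return "Bc"
    if hi["CD3"] and hi["CD4"]:
        return "naive CD4 Tc" if hi["CD45RA"] else "memory CD4 Tc"
    if hi["CD3"] and hi["CD8a"]:
        return "CD8 Tc"
    if hi["CD56"] and not hi["CD3"]:
        return "NKc"
    if hi["CD14"] and hi["CD61"]:
        return "cM"
    if hi["CD11c"] and hi["HLA-DR"] and not hi["CD14"]:
        return "mDc"
    if hi["CD123"] and hi["HLA-DR"] and not hi["CD11c"]:
        return "pDc"
    return "unassigned"


def annotate_metaclusters(
    meta: MetaClusterModel,
    points: np.ndarray,
    meta_ids: np.ndarray,
    markers: list[str],
) -> dict[int, str]:
    """Annotate kept metas from their median profiles.

    A marker is called ``hi`` in a meta when its profile value lies strictly
    above the midpoint of that marker's range across the kept meta profiles
    (a zero-spread marker is ``lo`` everywhere).  The midpoint splits the
    bimodal hi/lo structure of lineage markers robustly, whereas a
    median-of-profiles cut sits inside the majority mode whenever fewer than
    half the metas express the marker, turning noise into spurious calls.
    The rule table is applied in fixed priority order; unmatched profiles
    are ``unassigned``.  Annotations are stored on ``meta`` and returned.
    """
    profiles = metacluster_profiles(points, meta_ids, meta)
    if not profiles:
        return {}
    mat = np.vstack([profiles[m] for m in sorted(profiles)])
    lo, hi_ = mat.min(axis=0), mat.max(axis=0)
    midpoint = (lo + hi_) / 2.0
    spread = hi_ - lo
    annotations: dict[int, str] = {}
    for m in sorted(profiles):
        hi = {
            marker: bool(spread[j] > 0 and profiles[m][j] > midpoint[j])
            for j, marker in enumerate(markers)
        }
        annotations[m] = annotate_profile(hi)
    meta.annotations = annotations
    return annotations
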