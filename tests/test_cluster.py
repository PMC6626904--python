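"""Farthest point sampling, Voronoi assignment, size filters, meta-clustering,
and subset annotation."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cytofps.cluster import (
    ClusterModel,
    annotate_profile,
    assign_events,
    cluster_events,
    covering_radius,
    farthest_point_sampling,
    filter_small_clusters,
    metacluster,
)


def fps_oracle(points, k, start):
    """Brute-force greedy FPS recomputing all pairwise distances each step."""
    chosen = [start]
    for _ in range(k - 1):
        d = cdist(points, points[chosen]).min(axis=1)
        best = int(np.argmax(d))
        if d[best] <= 0:
            raise ValueError("no distinct point left")
        chosen.append(best)
    return np.array(chosen)


def complete_linkage_oracle(points, n_groups):
    """Naive O(n^3) complete-linkage agglomeration; returns merge heights and
    the partition at ``n_groups`` clusters."""
    clusters = [[i] for i in range(len(points))]
    d = cdist(points, points)
    heights = []
    partition_at = None
    while len(clusters) > 1:
        if len(clusters) == n_groups:
            partition_at = [list(c) for c in clusters]
        best = (np.inf, None, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    if n_groups == 1:
        partition_at = [list(clusters[0])]
    return np.array(heights), partition_at


class TestFps:
    def test_forced_geometry_1d(self):
        points = np.array([[0.0], [1.0], [10.0]])
        idx = farthest_point_sampling(points, 2, start=0)
        assert list(idx) == [0, 2]

    def test_matches_bruteforce_oracle(self, rng):
        points = rng.normal(size=(200, 5))
        for start in rng.integers(0, 200, size=5):
            ours = farthest_point_sampling(points, 10, start=int(start))
            oracle = fps_oracle(points, 10, int(start))
            np.testing.assert_array_equal(ours, oracle)

    def test_duplicate_points_rejected_when_k_too_large(self):
        points = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ValueError, match="distinct"):
            farthest_point_sampling(points, 3, start=0)

    def test_covering_radius_non_increasing_in_k(self, rng):
        points = rng.normal(size=(300, 4))
        radii = [
            covering_radius(points, points[farthest_point_sampling(points, k, start=0)])
            for k in (2, 5, 10, 20)
        ]
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_seeded_first_pick_deterministic(self, rng):
        points = rng.normal(size=(50, 3))
        a = farthest_point_sampling(points, 5, seed=42)
        b = farthest_point_sampling(points, 5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_permuting_events_preserves_selected_points(self, rng):
        """With the same starting event, a permutation selects the same set
        of points (indices mapped through the permutation)."""
        points = rng.normal(size=(120, 4))
        perm = rng.permutation(120)
        inv = np.argsort(perm)
        a = farthest_point_sampling(points, 8, start=3)
        b = farthest_point_sampling(points[perm], 8, start=int(inv[3]))
        np.testing.assert_allclose(points[a], points[perm][b])


class TestAssign:
    def test_representative_maps_to_itself(self, rng):
        points = rng.normal(size=(40, 3))
        reps = points[[4, 9, 17]]
        assign = assign_events(points, reps)
        assert assign[4] == 0 and assign[9] == 1 and assign[17] == 2

    def test_equidistant_tie_to_lowest_index(self):
        reps = np.array([[0.0], [2.0]])
        assign = assign_events(np.array([[1.0]]), reps)
        assert assign[0] == 0

    def test_matches_full_distance_matrix_oracle(self, rng):
        points = rng.normal(size=(10_000, 6))
        reps = rng.normal(size=(15, 6))
        ours = assign_events(points, reps, chunk=777)
        oracle = cdist(points, reps).argmin(axis=1)
        np.testing.assert_array_equal(ours, oracle)


class TestSizeFilters:
    def _model(self, sizes):
        sizes = np.asarray(sizes)
        k = sizes.size
        assignments = np.repeat(np.arange(k), sizes)
        reps = np.arange(k, dtype=float)[:, None] * 10
        return ClusterModel(
            representatives=reps,
            representative_indices=np.arange(k),
            assignments=assignments,
            cluster_sizes=sizes,
            kept_clusters=np.ones(k, dtype=bool),
        )

    def test_boundary_strictly_less_discarded(self):
        """Total 1e6 at threshold 1/100,000: size 9 out, size 10 kept."""
        model = self._model([9, 10, 999_981])
        out = filter_small_clusters(model, 1e-5)
        assert list(out.kept_clusters) == [False, True, True]

    def test_zero_fraction_keeps_everything(self):
        model = self._model([1, 5, 100])
        out = filter_small_clusters(model, 0.0)
        assert out.kept_clusters.all()

    def test_conservation(self):
        model = self._model([3, 7, 90])
        out = filter_small_clusters(model, 0.05)
        kept_events = out.event_kept().sum()
        assert kept_events + (~out.event_kept()).sum() == model.n_total

    def test_all_discarded_is_error(self):
        model = self._model([1, 1])
        with pytest.raises(ValueError, match="every cluster"):
            filter_small_clusters(model, 0.9)

    def test_meta_boundary_half_percent(self):
        """A meta at 0.4% of events is discarded, at 0.5% kept."""
        model = self._model([4000, 5000, 991_000])
        meta = metacluster(model, n_meta=3, min_meta_fraction=0.005)
        sizes = {int(meta.meta_sizes[m]): bool(meta.kept_metas[m]) for m in range(3)}
        assert sizes[4000] is False
        assert sizes[5000] is True
        assert sizes[991_000] is True
        assert meta.meta_sizes.sum() == model.n_total


class TestMetacluster:
    def test_forced_geometry_line(self):
        points = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = cluster_events(points, k=4, start=0)
        meta = metacluster(model, n_meta=2, min_meta_fraction=0.0)
        groups = meta.meta_of_cluster[model.assignments]
        assert groups[0] == groups[1] != groups[2] == groups[3]

    def test_merge_heights_match_oracle(self, rng):
        for trial in range(10):
            points = rng.normal(size=(6, 3))
            model = cluster_events(points, k=6, start=0)
            meta = metacluster(model, n_meta=2, min_meta_fraction=0.0)
            heights, partition = complete_linkage_oracle(points, 2)
            np.testing.assert_allclose(
                np.sort(meta.linkage[:, 2]), np.sort(heights), rtol=1e-9
            )
            labels = meta.meta_of_cluster[model.assignments]
            oracle_labels = np.empty(6, dtype=int)
            for g, members in enumerate(partition):
                oracle_labels[members] = g
            # same partition up to relabeling
            mapping = {}
            for ours, theirs in zip(labels, oracle_labels):
                mapping.setdefault(ours, theirs)
                assert mapping[ours] == theirs

    def test_too_few_clusters_is_error(self, rng):
        points = rng.normal(size=(5, 2))
        model = cluster_events(points, k=3, start=0)
        with pytest.raises(ValueError, match="n_meta"):
            metacluster(model, n_meta=4)


class TestAnnotation:
    def _hi(self, *markers):
        base = {m: False for m in
                ["CD20", "CD3", "CD4", "CD8a", "CD45RA", "CD56", "CD16",
                 "CD14", "CD61", "CD11c", "CD123", "HLA-DR"]}
        for m in markers:
            base[m] = True
        return base

    @pytest.mark.parametrize(
        "markers,expected",
        [
            (("CD20", "HLA-DR"), "Bc"),
            (("CD3", "CD4", "CD45RA"), "naive CD4 Tc"),
            (("CD3", "CD4"), "memory CD4 Tc"),
            (("CD3", "CD8a"), "CD8 Tc"),
            (("CD56", "CD16"), "NKc"),
            (("CD14", "CD61", "CD11c", "HLA-DR"), "cM"),
            (("CD11c", "HLA-DR"), "mDc"),
            (("CD123", "HLA-DR"), "pDc"),
            ((), "unassigned"),
        ],
    )
    def test_rule_table(self, markers, expected):
        assert annotate_profile(self._hi(*markers)) == expected

    def test_all_zero_profile_unassigned(self):
        assert annotate_profile(self._hi()) == "unassigned"
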