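"""Feature summaries, arcsinh ratios, and feature-table assembly."""

import numpy as np
import pytest

from cytofps.cluster import MetaClusterModel
from cytofps.features import (
    arcsinh_ratio,
    build_feature_table,
    feature_descriptors,
    subset_summary,
)
from cytofps.panel import EventTable, default_panel

from conftest import make_manifest


def make_meta_model(n_meta=12):
    return MetaClusterModel(
        linkage=np.zeros((0, 4)),
        n_meta=n_meta,
        meta_of_cluster=np.arange(n_meta),
        meta_sizes=np.full(n_meta, 100),
        kept_metas=np.ones(n_meta, dtype=bool),
        n_total=100 * n_meta,
        annotations={i: "unassigned" for i in range(n_meta)},
    )


def make_cohort_tables(manifest, n_meta=12, per_meta=15, seed=0, short=()):
    """Transformed event tables + meta ids, ``per_meta`` events per meta
    (metas listed in ``short`` get only 3 events for one individual)."""
    panel = default_panel()
    rng = np.random.default_rng(seed)
    tables, mids = [], []
    for rec in manifest.records:
        counts = [per_meta] * n_meta
        if rec.individual_id == manifest.individuals[0]:
            for s in short:
                counts[s] = 3
        ids = np.concatenate([np.full(c, m) for m, c in enumerate(counts)])
        values = rng.normal(2.0, 0.5, size=(ids.size, panel.n_channels))
        tables.append(
            EventTable(values=values, panel=panel, individual_id=rec.individual_id,
                       group=rec.group, condition=rec.condition, transformed=True)
        )
        mids.append(ids)
    return tables, mids


class TestSummaries:
    def test_median(self):
        assert subset_summary(np.array([1.0, 2.0, 3.0]), "median") == 2.0

    def test_q90_interpolation_convention(self):
        """q90 of 1..10 with h=(n-1)*0.9: between the 9th and 10th order
        statistics at 9.1."""
        assert subset_summary(np.arange(1.0, 11.0), "q90") == pytest.approx(9.1)

    def test_q90_of_constant(self):
        assert subset_summary(np.full(7, 3.3), "q90") == pytest.approx(3.3)

    def test_empty_signals_missing(self):
        assert np.isnan(subset_summary(np.array([]), "median"))

    def test_ratio_identical_distributions_zero(self, rng):
        x = rng.normal(size=500)
        assert arcsinh_ratio(x, x) == 0.0

    def test_ratio_antisymmetric(self, rng):
        a, b = rng.normal(size=100), rng.normal(1.0, 1.0, size=100)
        assert arcsinh_ratio(a, b) == -arcsinh_ratio(b, a)

    def test_ratio_recovers_planted_shift(self, rng):
        basal = rng.normal(1.0, 0.4, size=10_000)
        stim = rng.normal(1.5, 0.4, size=10_000)
        assert arcsinh_ratio(stim, basal) == pytest.approx(0.5, abs=0.02)


class TestFeatureTable:
    def test_dimensions_12_metas(self):
        """12 kept metas x 9 markers: 216 basal, 108 ratio, 324 combined."""
        manifest = make_manifest(2, 2)
        tables, mids = make_cohort_tables(manifest)
        meta = make_meta_model(12)
        dims = {}
        for model in ("basal", "ratio", "combined"):
            ft = build_feature_table(tables, mids, meta, manifest, model=model)
            dims[model] = ft.n_features
            assert not np.isnan(ft.matrix).any()
        assert dims == {"basal": 216, "ratio": 108, "combined": 324}

    def test_combined_is_union_of_basal_and_ratio(self):
        meta = make_meta_model(3)
        markers = default_panel().functional_markers
        basal = set(feature_descriptors(meta, markers, "basal"))
        ratio = set(feature_descriptors(meta, markers, "ratio"))
        combined = set(feature_descriptors(meta, markers, "combined"))
        assert combined == basal | ratio
        assert not basal & ratio

    def test_basal_model_has_no_ratio_columns(self):
        manifest = make_manifest(2, 2)
        tables, mids = make_cohort_tables(manifest, n_meta=3)
        ft = build_feature_table(tables, mids, make_meta_model(3), manifest, model="basal")
        assert all(d.statistic != "arcsinh_ratio" for d in ft.descriptors)

    def test_column_order_deterministic(self):
        meta = make_meta_model(4)
        markers = default_panel().functional_markers
        a = [d.column_name for d in feature_descriptors(meta, markers, "combined")]
        b = [d.column_name for d in feature_descriptors(meta, markers, "combined")]
        assert a == b
        metas = [d.meta_id for d in feature_descriptors(meta, markers, "combined")]
        assert metas == sorted(metas)

    def test_below_min_cells_imputed_and_logged(self):
        manifest = make_manifest(2, 2)
        tables, mids = make_cohort_tables(manifest, n_meta=3, short=(1,))
        ft = build_feature_table(tables, mids, make_meta_model(3), manifest,
                                 model="basal", min_cells=10)
        first = manifest.individuals[0]
        logged = {(i, f) for i, f, _ in ft.imputation_log}
        assert any(i == first and "meta1" in f for i, f in logged)
        i0 = ft.individuals.index(first)
        for j, d in enumerate(ft.descriptors):
            if d.meta_id == 1:
                others = np.delete(ft.raw_matrix[:, j], i0)
                assert ft.matrix[i0, j] == pytest.approx(np.median(others))
                assert np.isnan(ft.raw_matrix[i0, j])

    def test_missing_condition_is_error(self):
        manifest = make_manifest(2, 2)
        tables, mids = make_cohort_tables(manifest)
        basal_only = [t for t in tables if t.condition == "basal"]
        mids_basal = [m for t, m in zip(tables, mids) if t.condition == "basal"]
        from cytofps.panel import CohortManifest

        broken = CohortManifest(records=[r for r in manifest.records])
        with pytest.raises(ValueError, match="stim"):
            build_feature_table(basal_only, mids_basal, make_meta_model(12), broken,
                                model="combined")

    def test_event_order_invariance(self, rng):
        manifest = make_manifest(1, 1)
        tables, mids = make_cohort_tables(manifest)
        ft1 = build_feature_table(tables, mids, make_meta_model(12), manifest,
                                  model="combined")
        shuffled, smids = [], []
        for t, m in zip(tables, mids):
            perm = rng.permutation(t.n_events)
            shuffled.append(
                EventTable(values=t.values[perm], panel=t.panel,
                           individual_id=t.individual_id, group=t.group,
                           condition=t.condition, transformed=True)
            )
            smids.append(m[perm])
        ft2 = build_feature_table(shuffled, smids, make_meta_model(12), manifest,
                                  model="combined")
        np.testing.assert_allclose(ft1.matrix, ft2.matrix, atol=1e-12)

    def test_planted_effect_scales_group_difference(self):
        """Doubling the planted basal delta doubles the group-mean gap of the
        matching median_basal column (up to sampling error)."""
        from cytofps.pipeline import PipelineConfig, run_pipeline
        from cytofps.simulate import default_scenario, simulate_cohort

        gaps = []
        for scale in (0.5, 1.0):
            cfg = default_scenario(effect_scale=scale, events_per_sample=600,
                                   n_hd=6, n_ra=6, between_individual_sd=0.05, seed=4)
            manifest, tables, _ = simulate_cohort(cfg)
            res = run_pipeline(tables, manifest,
                               config=PipelineConfig(seed=4, models=()))
            ft = res.feature_tables.get("basal")
            if ft is None:
                from cytofps.features import build_feature_table as bft
                ft = bft(res.tables, res.meta_ids_per_table, res.meta_model,
                         manifest, model="basal")
            cols = [j for j, d in enumerate(ft.descriptors)
                    if d.annotation == "memory CD4 Tc" and d.marker == "p-p38"
                    and d.statistic == "median_basal"]
            col = ft.matrix[:, cols].mean(axis=1)
            gaps.append(col[ft.labels == 1].mean() - col[ft.labels == 0].mean())
        assert gaps[1] / gaps[0] == pytest.approx(2.0, abs=0.5)
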