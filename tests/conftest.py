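import numpy as np
import pytest

from cytofps.panel import CohortManifest, EventTable, ManifestRecord, default_panel
from cytofps.simulate import default_scenario, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def raw_table(panel, rng):
    """A small raw event table with plausible non-negative values."""
    values = rng.gamma(shape=2.0, scale=50.0, size=(200, panel.n_channels))
    return EventTable(
        values=values, panel=panel, individual_id="HD01", group="HD", condition="basal"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared across read-only tests."""
    cfg = default_scenario(effect_scale=1.0, events_per_sample=800, seed=7)
    return simulate_cohort(cfg)


def truth_alignment(result, manifest, truth):
    """Align per-event meta annotations with planted subset labels.

    Returns (annotated labels, true labels) over cleaned, kept, non-debris
    events pooled across all samples.
    """
    meta = result.meta_model
    ann_all, tru_all = [], []
    for mids, mask, rec in zip(
        result.meta_ids_per_table, result.keep_masks, manifest.records
    ):
        labels = truth.subset_labels[(rec.individual_id, rec.condition)][mask]
        keep = (mids >= 0) & (labels != "debris")
        ann = np.array(
            [meta.annotations.get(int(m), "unassigned") for m in mids[keep]],
            dtype=object,
        )
        ann_all.append(ann)
        tru_all.append(labels[keep])
    return np.concatenate(ann_all), np.concatenate(tru_all)


def make_manifest(n_hd=2, n_ra=2):
    records = []
    for g, n in (("HD", n_hd), ("RA", n_ra)):
        for i in range(n):
            iid = f"{g}{i + 1:02d}"
            records.append(ManifestRecord(iid, g, "basal"))
            records.append(ManifestRecord(iid, g, "stim"))
    return CohortManifest(records=records)
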