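"""Synthetic CyTOF cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-group cohort (healthy donors, HD, vs rheumatoid-arthritis
patients, RA), each individual measured unstimulated (``basal``) and after
a short TNF stimulation (``stim``); events drawn from a mixture of immune
subsets with subset-specific lineage-marker profiles; functional
(signaling) markers with subset-specific basal levels, TNF-induced shifts,
and optional planted RA-vs-HD effects; and a doublet/debris artifact
population living in the QC channels.

Marker intensities are modeled as Gaussians on the arcsinh scale and
back-transformed to raw ion counts (``sinh(v) * cofactor``, truncated at
zero) — the standard log-normal-like noise shape of cytometry data.
Between-individual heterogeneity enters as random intercepts per
(individual, subset, functional marker), shared across that individual's
two conditions, so paired stim-minus-basal contrasts cancel them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import (
    CohortManifest,
    EventTable,
    FUNCTIONAL_CHANNELS,
    ManifestRecord,
    PHENOTYPING_CHANNELS,
    QC_CHANNELS,
    default_panel,
)

__all__ = [
    "SubsetSpec",
    "EffectSpec",
    "StimulationSpec",
    "QcModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "default_scenario",
    "null_scenario",
    "DEFAULT_SUBSET_NAMES",
]

PHENO_MARKERS = [m for _, m in PHENOTYPING_CHANNELS]
FUNC_MARKERS = [m for _, m in FUNCTIONAL_CHANNELS]

# arcsinh-scale levels realizing the hi/lo phenotype templates: separable
# but overlapping subset blobs.
HI_LEVEL = 4.0
LO_LEVEL = 0.5
PHENO_SD = 0.4


@dataclass(frozen=True)
class SubsetSpec:
    """One immune subset: abundance, lineage profile, basal signaling levels."""

    name: str
    proportion: float
    phenotype_template: dict[str, str]  # marker -> "hi" | "lo"
    functional_basal: dict[str, tuple[float, float]]  # marker -> (mean, sd)

    def phenotype_mean(self, marker: str) -> float:
        return HI_LEVEL if self.phenotype_template.get(marker, "lo") == "hi" else LO_LEVEL


@dataclass(frozen=True)
class EffectSpec:
    """A planted RA-vs-HD shift (arcsinh scale) on one subset x marker."""

    subset: str
    marker: str
    component: str  # "basal" (both conditions) | "stim_response" (stim only)
    delta: float

    def __post_init__(self) -> None:
        if self.component not in ("basal", "stim_response"):
            raise ValueError(f"unknown effect component {self.component!r}")


@dataclass(frozen=True)
class StimulationSpec:
    """TNF-induced mean shifts (arcsinh scale) per (subset, marker)."""

    response: dict[tuple[str, str], float] = field(default_factory=dict)

    def shift(self, subset: str, marker: str) -> float:
        return self.response.get((subset, marker), 0.0)


@dataclass(frozen=True)
class QcModel:
    """Raw-scale Gaussian QC-channel model for clean and artifact events.

    By default artifacts sit ``artifact_shift_sd`` clean standard deviations
    above the clean mean in every QC channel — the doublet-like signature
    (longer events, more DNA).
    """

    clean_mean: dict[str, float]
    clean_sd: dict[str, float]
    artifact_shift_sd: float = 4.0
    artifact_sd_scale: float = 1.0

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        cm = np.array([self.clean_mean[c] for c in QC_CHANNELS])
        cs = np.array([self.clean_sd[c] for c in QC_CHANNELS])
        dm = cm + self.artifact_shift_sd * cs
        ds = cs * self.artifact_sd_scale
        return cm, cs, dm, ds


def _default_qc_model(artifact_shift_sd: float = 4.0) -> QcModel:
    mean = {
        "Event_length": 25.0,
        "Center": 600.0,
        "Offset": 80.0,
        "Width": 100.0,
        "Residual": 70.0,
        "191Ir_DNA1": 300.0,
        "193Ir_DNA2": 200.0,
    }
    sd = {k: 0.1 * v for k, v in mean.items()}
    return QcModel(clean_mean=mean, clean_sd=sd, artifact_shift_sd=artifact_shift_sd)


@dataclass
class SimulationConfig:
    subsets: list[SubsetSpec]
    effects: list[EffectSpec] = field(default_factory=list)
    stimulation: StimulationSpec = field(default_factory=StimulationSpec)
    n_hd: int = 20
    n_ra: int = 20
    events_per_sample: int = 20_000
    debris_fraction: float = 0.08
    qc_model: QcModel = field(default_factory=_default_qc_model)
    between_individual_sd: float = 0.2
    cofactor: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(s.proportion for s in self.subsets)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subset proportions must sum to 1, got {total}")
        if not (0 <= self.debris_fraction < 1):
            raise ValueError("debris_fraction must be in [0, 1)")
        if self.between_individual_sd < 0:
            raise ValueError("between_individual_sd must be >= 0")
        names = {s.name for s in self.subsets}
        for e in self.effects:
            if e.subset not in names:
                raise ValueError(f"effect targets unknown subset {e.subset!r}")
            if e.marker not in FUNC_MARKERS:
                raise ValueError(f"effect targets unknown functional marker {e.marker!r}")
        for (s, m) in self.stimulation.response:
            if m not in FUNC_MARKERS:
                raise ValueError(f"stimulation shift on non-functional marker {m!r}")


@dataclass
class GroundTruth:
    """Planted truth aligned 1:1 with the generated event tables."""

    subset_labels: dict[tuple[str, str], np.ndarray]  # (individual, condition) -> names
    debris_flags: dict[tuple[str, str], np.ndarray]
    groups: dict[str, str]
    realized_proportions: dict[str, np.ndarray]  # individual -> subset fractions (non-debris)
    effects: list[EffectSpec] = field(default_factory=list)
    subset_names: list[str] = field(default_factory=list)


# -- default scenario --------------------------------------------------------

# Family-level abundances follow the reported meta-cluster composition
# (B 4.3%, T 75.3%, NK 5%, cM 5.7%, mDc 8.8%, pDc 1%; printed values sum to
# 100.1% and are renormalized).  The T compartment is split into naive CD4,
# memory CD4, and CD8 subsets.
_RAW_PROPORTIONS = {
    "Bc": 4.3,
    "naive CD4 Tc": 27.5,
    "memory CD4 Tc": 32.5,
    "CD8 Tc": 15.3,
    "NKc": 5.0,
    "cM": 5.7,
    "mDc": 8.8,
    "pDc": 1.0,
}
DEFAULT_SUBSET_NAMES = list(_RAW_PROPORTIONS)

_TEMPLATES: dict[str, list[str]] = {
    "Bc": ["CD20", "HLA-DR"],
    "naive CD4 Tc": ["CD3", "CD4", "CD45RA"],
    "memory CD4 Tc": ["CD3", "CD4"],
    "CD8 Tc": ["CD3", "CD8a", "CD45RA"],
    "NKc": ["CD56", "CD16", "CD45RA"],
    "cM": ["CD14", "CD61", "CD11c", "HLA-DR"],
    "mDc": ["CD11c", "HLA-DR", "CD16"],
    "pDc": ["CD123", "HLA-DR", "CD45RA"],
}

_MYELOID = ("cM", "mDc", "pDc")

# Basal arcsinh-scale levels for the functional markers (sd 0.4 throughout);
# CD86 and the TNF receptors sit higher on antigen-presenting cells.
_FUNC_BASE = {
    "Caspase3": 0.6,
    "p-p38": 1.0,
    "p-Akt": 1.0,
    "p-cJun": 0.8,
    "p-NFkB": 1.2,
    "IkBa": 1.5,
    "CD120a": 0.8,
    "CD120b": 0.8,
    "CD86": 0.5,
}
_FUNC_SD = 0.4


def _functional_basal(subset: str) -> dict[str, tuple[float, float]]:
    levels = dict(_FUNC_BASE)
    if subset in ("cM", "mDc"):
        levels["CD86"] = 2.5
        levels["CD120a"] = 1.2
        levels["CD120b"] = 1.2
    return {m: (v, _FUNC_SD) for m, v in levels.items()}


def _default_stimulation() -> StimulationSpec:
    """TNF response: IkBa degradation, p-NFkB/p-p38 induction, strongest in
    the receptor-rich myeloid compartment, moderate in T cells."""
    response: dict[tuple[str, str], float] = {}
    t_subsets = ("naive CD4 Tc", "memory CD4 Tc", "CD8 Tc")
    for s in ("cM", "mDc"):
        response[(s, "IkBa")] = -0.8
        response[(s, "p-NFkB")] = 0.8
        response[(s, "p-p38")] = 0.6
    for s in t_subsets:
        response[(s, "IkBa")] = -0.3
        response[(s, "p-NFkB")] = 0.4
        response[(s, "p-p38")] = 0.3
    return StimulationSpec(response=response)


def default_subsets() -> list[SubsetSpec]:
    total = sum(_RAW_PROPORTIONS.values())
    out = []
    for name, pct in _RAW_PROPORTIONS.items():
        template = {m: ("hi" if m in _TEMPLATES[name] else "lo") for m in PHENO_MARKERS}
        out.append(
            SubsetSpec(
                name=name,
                proportion=pct / total,
                phenotype_template=template,
                functional_basal=_functional_basal(name),
            )
        )
    return out


def default_effects(effect_scale: float = 1.0) -> list[EffectSpec]:
    """The planted RA signature: raised basal p-p38/IkBa in memory CD4 T
    cells, raised p-cJun in naive and memory CD4 T cells, raised p-NFkB and
    *lowered* CD86 in myeloid dendritic cells and classical monocytes.

    ``effect_scale`` is the shift magnitude in arcsinh units.
    """
    s = float(effect_scale)
    pairs = [
        ("memory CD4 Tc", "p-p38", +1.0),
        ("memory CD4 Tc", "IkBa", +1.0),
        ("memory CD4 Tc", "p-cJun", +1.0),
        ("naive CD4 Tc", "p-cJun", +1.0),
        ("mDc", "p-NFkB", +1.0),
        ("cM", "p-NFkB", +1.0),
        ("mDc", "CD86", -1.0),
        ("cM", "CD86", -1.0),
    ]
    return [EffectSpec(sub, m, "basal", sign * s) for sub, m, sign in pairs]


def default_scenario(effect_scale: float = 1.0, **overrides) -> SimulationConfig:
    """Cohort config planting the direction-signed RA signature.

    With ``effect_scale=0`` this degenerates to the null configuration (no
    group difference).  Keyword overrides are forwarded to
    :class:`SimulationConfig`.
    """
    cfg = SimulationConfig(
        subsets=default_subsets(),
        effects=default_effects(effect_scale),
        stimulation=_default_stimulation(),
        **overrides,
    )
    cfg.validate()
    return cfg


def null_scenario(**overrides) -> SimulationConfig:
    return default_scenario(effect_scale=0.0, **overrides)


# -- generation --------------------------------------------------------------


def _effect_arrays(cfg: SimulationConfig, subset_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    n_s, n_f = len(subset_names), len(FUNC_MARKERS)
    basal = np.zeros((n_s, n_f))
    stim_resp = np.zeros((n_s, n_f))
    for e in cfg.effects:
        si = subset_names.index(e.subset)
        mi = FUNC_MARKERS.index(e.marker)
        if e.component == "basal":
            basal[si, mi] += e.delta
        else:
            stim_resp[si, mi] += e.delta
    return basal, stim_resp


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortManifest, list[EventTable], GroundTruth]:
    """Generate one basal and one stim event table per individual.

    Fully deterministic under ``config.seed``.  Returns the manifest (one
    record per table, in table order), the raw-scale event tables, and the
    planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = default_panel(cofactor=config.cofactor)

    subset_names = [s.name for s in config.subsets]
    props = np.array([s.proportion for s in config.subsets])
    props = props / props.sum()  # exact renormalization for rng.choice
    n_s, n_p, n_f = len(subset_names), len(PHENO_MARKERS), len(FUNC_MARKERS)

    pheno_means = np.array(
        [[s.phenotype_mean(m) for m in PHENO_MARKERS] for s in config.subsets]
    )
    func_means = np.array(
        [[s.functional_basal[m][0] for m in FUNC_MARKERS] for s in config.subsets]
    )
    func_sds = np.array(
        [[s.functional_basal[m][1] for m in FUNC_MARKERS] for s in config.subsets]
    )
    stim_shift = np.array(
        [[config.stimulation.shift(s.name, m) for m in FUNC_MARKERS] for s in config.subsets]
    )
    ra_basal, ra_stim = _effect_arrays(config, subset_names)
    cm, cs, dm, ds = config.qc_model.arrays()

    pheno_idx = panel.indices("phenotyping")
    func_idx = panel.indices("functional")
    qc_idx = panel.indices("qc")

    manifest_records: list[ManifestRecord] = []
    tables: list[EventTable] = []
    truth = GroundTruth(
        subset_labels={},
        debris_flags={},
        groups={},
        realized_proportions={},
        effects=list(config.effects),
        subset_names=list(subset_names),
    )

    ids = [f"HD{i + 1:02d}" for i in range(config.n_hd)] + [
        f"RA{i + 1:02d}" for i in range(config.n_ra)
    ]
    groups = ["HD"] * config.n_hd + ["RA"] * config.n_ra

    for iid, group in zip(ids, groups):
        truth.groups[iid] = group
        intercepts = rng.normal(0.0, config.between_individual_sd, size=(n_s, n_f))
        counts = np.zeros(n_s)
        total_clean = 0
        for condition in ("basal", "stim"):
            n = config.events_per_sample
            debris = rng.random(n) < config.debris_fraction
            subset = rng.choice(n_s, size=n, p=props)

            pheno = rng.normal(pheno_means[subset], PHENO_SD)

            mean = func_means[subset] + intercepts[subset]
            if group == "RA":
                mean = mean + ra_basal[subset]
            if condition == "stim":
                mean = mean + stim_shift[subset]
                if group == "RA":
                    mean = mean + ra_stim[subset]
            func = rng.normal(mean, func_sds[subset])

            # Debris/doublet marker values: resample each marker from an
            # independently scrambled subset (pooled-distribution scramble).
            n_deb = int(debris.sum())
            if n_deb:
                scram_p = rng.choice(n_s, size=(n_deb, n_p), p=props)
                scram_f = rng.choice(n_s, size=(n_deb, n_f), p=props)
                pheno[debris] = rng.normal(
                    pheno_means[scram_p, np.arange(n_p)], PHENO_SD
                )
                func[debris] = rng.normal(
                    func_means[scram_f, np.arange(n_f)], func_sds[scram_f, np.arange(n_f)]
                )

            qc = rng.normal(cm, cs, size=(n, len(qc_idx)))
            if n_deb:
                qc[debris] = rng.normal(dm, ds, size=(n_deb, len(qc_idx)))

            values = np.zeros((n, panel.n_channels))
            values[:, qc_idx] = np.clip(qc, 0.0, None)
            values[:, pheno_idx] = np.clip(np.sinh(pheno) * config.cofactor, 0.0, None)
            values[:, func_idx] = np.clip(np.sinh(func) * config.cofactor, 0.0, None)

            tables.append(
                EventTable(
                    values=values,
                    panel=panel,
                    individual_id=iid,
                    group=group,
                    condition=condition,
                )
            )
            manifest_records.append(ManifestRecord(iid, group, condition))

            labels = np.array(subset_names, dtype=object)[subset]
            labels[debris] = "debris"
            truth.subset_labels[(iid, condition)] = labels
            truth.debris_flags[(iid, condition)] = debris
            counts += np.bincount(subset[~debris], minlength=n_s)
            total_clean += int((~debris).sum())

        truth.realized_proportions[iid] = counts / max(total_clean, 1)

    return CohortManifest(records=manifest_records), tables, truth
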