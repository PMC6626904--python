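"""Marker panel, cohort manifest, and the single-cell event table.

The panel follows the usual CyTOF ``metal_marker`` channel-naming dialect
(e.g. ``156Gd_p-p38``).  Three channel roles are distinguished:

``qc``
    Acquisition quality channels (event length, the instrument's Gaussian
    fit parameters, and the two iridium DNA intercalators).  Used only for
    doublet/debris cleanup and never arcsinh-transformed.
``phenotyping``
    Surface lineage markers used for clustering and subset annotation.
``functional``
    Intracellular/surface signaling readouts used as classification
    features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Channel",
    "PanelDefinition",
    "ManifestRecord",
    "CohortManifest",
    "EventTable",
    "MissingChannelError",
    "TransformStateError",
    "default_panel",
    "arcsinh_transform",
    "QC_CHANNELS",
    "PHENOTYPING_CHANNELS",
    "FUNCTIONAL_CHANNELS",
]


class MissingChannelError(KeyError):
    """Raised when required panel channels are absent from an input file."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"missing channels: {', '.join(self.missing)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"missing channels: {', '.join(self.missing)}"


class TransformStateError(ValueError):
    """Raised on a double arcsinh transform or persisting transformed data."""


QC_CHANNELS: tuple[str, ...] = (
    "Event_length",
    "Center",
    "Offset",
    "Width",
    "Residual",
    "191Ir_DNA1",
    "193Ir_DNA2",
)

# (channel, marker) pairs; channel names carry the conjugated metal isotope.
PHENOTYPING_CHANNELS: tuple[tuple[str, str], ...] = (
    ("147Sm_CD20", "CD20"),
    ("170Er_CD3", "CD3"),
    ("145Nd_CD4", "CD4"),
    ("146Nd_CD8a", "CD8a"),
    ("169Tm_CD45RA", "CD45RA"),
    ("176Yb_CD56", "CD56"),
    ("148Nd_CD16", "CD16"),
    ("160Gd_CD14", "CD14"),
    ("209Bi_CD61", "CD61"),
    ("159Tb_CD11c", "CD11c"),
    ("151Eu_CD123", "CD123"),
    ("174Yb_HLA-DR", "HLA-DR"),
)

FUNCTIONAL_CHANNELS: tuple[tuple[str, str], ...] = (
    ("142Nd_Caspase3", "Caspase3"),
    ("156Gd_p-p38", "p-p38"),
    ("152Sm_p-Akt", "p-Akt"),
    ("167Er_p-cJun", "p-cJun"),
    ("166Er_p-NFkB", "p-NFkB"),
    ("164Dy_IkBa", "IkBa"),
    ("155Gd_CD120a", "CD120a"),
    ("165Ho_CD120b", "CD120b"),
    ("150Nd_CD86", "CD86"),
)

GROUPS = ("HD", "RA")
CONDITIONS = ("basal", "stim")


@dataclass(frozen=True)
class Channel:
    name: str
    marker: str
    role: str  # qc | phenotyping | functional

    def __post_init__(self) -> None:
        if self.role not in ("qc", "phenotyping", "functional"):
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered channel list plus the arcsinh cofactor used throughout."""

    channels: tuple[Channel, ...]
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not self.cofactor > 0:
            raise ValueError("cofactor must be positive")

    # -- name/index helpers -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def role_channels(self, role: str) -> list[Channel]:
        return [c for c in self.channels if c.role == role]

    @property
    def qc_names(self) -> list[str]:
        return [c.name for c in self.role_channels("qc")]

    @property
    def phenotyping_markers(self) -> list[str]:
        return [c.marker for c in self.role_channels("phenotyping")]

    @property
    def functional_markers(self) -> list[str]:
        return [c.marker for c in self.role_channels("functional")]

    def index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise MissingChannelError([name])

    def indices(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.role == role], dtype=int
        )

    def marker_index(self, marker: str) -> int:
        for i, c in enumerate(self.channels):
            if c.marker == marker:
                return i
        raise MissingChannelError([marker])

    def validate_pipeline_ready(self) -> None:
        for role in ("qc", "phenotyping", "functional"):
            if not self.role_channels(role):
                raise ValueError(f"panel has no {role} channels")


def default_panel(cofactor: float = 5.0) -> PanelDefinition:
    """The 28-channel default panel: 7 QC + 12 phenotyping + 9 functional."""
    channels = (
        tuple(Channel(n, n, "qc") for n in QC_CHANNELS)
        + tuple(Channel(n, m, "phenotyping") for n, m in PHENOTYPING_CHANNELS)
        + tuple(Channel(n, m, "functional") for n, m in FUNCTIONAL_CHANNELS)
    )
    return PanelDefinition(channels=channels, cofactor=cofactor)


@dataclass(frozen=True)
class ManifestRecord:
    individual_id: str
    group: str  # HD | RA
    condition: str  # basal | stim
    source: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class CohortManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.individual_id, r.condition)
            if key in seen:
                raise ValueError(f"duplicate manifest entry {key}")
            seen.add(key)

    @property
    def individuals(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.individual_id not in out:
                out.append(r.individual_id)
        return out

    def group_of(self, individual_id: str) -> str:
        for r in self.records:
            if r.individual_id == individual_id:
                return r.group
        raise KeyError(individual_id)

    def record(self, individual_id: str, condition: str) -> ManifestRecord:
        for r in self.records:
            if r.individual_id == individual_id and r.condition == condition:
                return r
        raise KeyError((individual_id, condition))

    def require_paired(self) -> None:
        """Every individual must appear in both conditions (ratio/combined models)."""
        for iid in self.individuals:
            conds = {r.condition for r in self.records if r.individual_id == iid}
            if conds != set(CONDITIONS):
                raise ValueError(f"individual {iid} missing condition(s) {set(CONDITIONS) - conds}")


@dataclass
class EventTable:
    """Events x channels matrix with sample metadata.

    ``values`` columns follow ``panel.channels`` order.  Raw tables hold
    non-negative ion counts; after :func:`arcsinh_transform` the marker
    columns are on the arcsinh scale (QC columns stay raw) and
    ``transformed`` is set.
    """

    values: np.ndarray
    panel: PanelDefinition
    individual_id: str = ""
    group: str = "HD"
    condition: str = "basal"
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != self.panel.n_channels:
            raise ValueError(
                f"expected {self.panel.n_channels} channels, got {self.values.shape[1]}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("event values must be finite (no missing values)")
        if not self.transformed and self.values.size and self.values.min() < 0:
            raise ValueError("raw event values must be non-negative")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.panel.index(name)]

    def marker_column(self, marker: str) -> np.ndarray:
        return self.values[:, self.panel.marker_index(marker)]

    def qc_matrix(self) -> np.ndarray:
        return self.values[:, self.panel.indices("qc")]

    def phenotyping_matrix(self) -> np.ndarray:
        return self.values[:, self.panel.indices("phenotyping")]

    def functional_matrix(self) -> np.ndarray:
        return self.values[:, self.panel.indices("functional")]

    def subset(self, mask: np.ndarray) -> "EventTable":
        return replace(self, values=self.values[mask])


def arcsinh_transform(table: EventTable, cofactor: float | None = None) -> EventTable:
    """Variance-stabilize marker channels: ``x -> asinh(x / cofactor)``.

    QC channels are left on the raw scale (cleanup standardizes them
    separately).  Applying the transform twice is an error.
    """
    if table.transformed:
        raise TransformStateError("table is already arcsinh-transformed")
    c = table.panel.cofactor if cofactor is None else float(cofactor)
    if not c > 0:
        raise ValueError("cofactor must be positive")
    values = table.values.copy()
    marker_idx = np.concatenate(
        [table.panel.indices("phenotyping"), table.panel.indices("functional")]
    )
    values[:, marker_idx] = np.arcsinh(values[:, marker_idx] / c)
    return replace(table, values=values, transformed=True)
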