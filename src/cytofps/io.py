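"""Reading and writing event tables, manifests, and panels.

Two on-disk event formats are supported and resolved by file extension:
``.fcs`` (binary FCS 3.0/3.1 via :mod:`cytofps.fcs`) and delimited text
(TSV/CSV with a header row of channel names).  Channels are always
resolved *by name* against the panel, so column order in the file is
irrelevant; an optional alias map translates non-standard header names
(e.g. ``p-p38`` for ``156Gd_p-p38``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcs
from .panel import (
    Channel,
    CohortManifest,
    EventTable,
    ManifestRecord,
    MissingChannelError,
    PanelDefinition,
    TransformStateError,
)

__all__ = [
    "read_events",
    "write_events",
    "read_manifest",
    "write_manifest",
    "read_panel",
    "write_panel",
]


def _resolve_columns(
    header: list[str], panel: PanelDefinition, alias: dict[str, str] | None
) -> list[int]:
    """Map each panel channel to its column index in ``header`` by name."""
    alias = alias or {}
    canonical = {alias.get(h, h): i for i, h in enumerate(header)}
    missing = [n for n in panel.names if n not in canonical]
    if missing:
        raise MissingChannelError(missing)
    return [canonical[n] for n in panel.names]


def read_events(
    path,
    panel: PanelDefinition,
    meta: ManifestRecord | None = None,
    alias: dict[str, str] | None = None,
) -> EventTable:
    """Read one sample's events, aligning file columns to the panel by name."""
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        header, data = fcs.read_fcs(path)
    else:
        import csv

        try:
            frame = pd.read_csv(path, sep=None, engine="python")
        except (pd.errors.EmptyDataError, csv.Error) as exc:
            raise ValueError(f"empty or malformed event file: {path}") from exc
        header = [str(c) for c in frame.columns]
        data = frame.to_numpy(dtype=float)
    if data.shape[0] == 0:
        raise ValueError(f"event file contains no events: {path}")
    order = _resolve_columns(header, panel, alias)
    values = np.ascontiguousarray(data[:, order])
    meta = meta or ManifestRecord("unknown", "HD", "basal")
    return EventTable(
        values=values,
        panel=panel,
        individual_id=meta.individual_id,
        group=meta.group,
        condition=meta.condition,
    )


def write_events(table: EventTable, path) -> None:
    """Persist a raw event table as FCS (``.fcs``) or TSV (anything else)."""
    if table.transformed:
        raise TransformStateError("only raw (untransformed) tables are persisted")
    if table.n_events == 0:
        raise ValueError("refusing to write an empty event table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".fcs":
        fcs.write_fcs(path, table.panel.names, table.values)
    else:
        frame = pd.DataFrame(table.values, columns=table.panel.names)
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(
    manifest: CohortManifest, panel: PanelDefinition, alias: dict[str, str] | None = None
) -> list[EventTable]:
    return [read_events(r.source, panel, meta=r, alias=alias) for r in manifest.records]


# -- manifest / panel configs ------------------------------------------------


def write_manifest(manifest: CohortManifest, path) -> None:
    payload = [
        {
            "individual_id": r.individual_id,
            "group": r.group,
            "condition": r.condition,
            "source": r.source,
        }
        for r in manifest.records
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_manifest(path) -> CohortManifest:
    payload = yaml.safe_load(Path(path).read_text())
    records = [
        ManifestRecord(
            individual_id=str(item["individual_id"]),
            group=item["group"],
            condition=item["condition"],
            source=item.get("source"),
        )
        for item in payload
    ]
    return CohortManifest(records=records)


def write_panel(panel: PanelDefinition, path) -> None:
    payload = {
        "cofactor": panel.cofactor,
        "channels": [
            {"name": c.name, "marker": c.marker, "role": c.role} for c in panel.channels
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_panel(path) -> PanelDefinition:
    payload = json.loads(Path(path).read_text())
    channels = tuple(
        Channel(c["name"], c["marker"], c["role"]) for c in payload["channels"]
    )
    return PanelDefinition(channels=channels, cofactor=float(payload["cofactor"]))
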