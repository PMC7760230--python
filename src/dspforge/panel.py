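"""Probe panel: probe identities, classes and module assignments.

A DSP protein panel mixes three probe classes:

* ``target`` — antibodies against proteins of biological interest,
  organised in thematic modules (immune cell profiling, IO drug targets,
  immune activation status, immune cell typing, pan-tumour).
* ``igg_control`` — isotype IgG antibodies with no specific target; their
  counts estimate per-ROI nonspecific background.
* ``housekeeper`` — probes against proteins assumed biologically invariant
  (Histone H3, S6, GAPDH), used to derive normalization factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PROBE_CLASSES = ("target", "igg_control", "housekeeper")

# Default 58-probe immuno-oncology panel: 3 IgG isotype controls,
# 3 housekeepers and 52 targets across five modules.
_CONTROLS = [
    ("Rb IgG", "igg_control", "Controls", "Rb"),
    ("Ms IgG1", "igg_control", "Controls", "Ms"),
    ("Ms IgG2a", "igg_control", "Controls", "Ms"),
    ("Histone H3", "housekeeper", "Controls", None),
    ("S6", "housekeeper", "Controls", None),
    ("GAPDH", "housekeeper", "Controls", None),
]

_MODULES = {
    "Immune Cell Profiling": [
        "PD-1", "CD68", "HLA-DR", "Ki-67", "Beta-2M", "CD11c", "CD20",
        "CD3", "CD4", "CD45", "CD56", "CD8", "CTLA4", "GZMB", "PD-L1",
        "PanCk", "SMA", "Fibronectin",
    ],
    "IO Drug Target": [
        "4-1BB", "LAG3", "OX40L", "Tim-3", "VISTA", "ARG1", "B7-H3",
        "IDO1", "STING", "GITR",
    ],
    "Immune Activation Status": [
        "CD127", "CD25", "CD80", "ICOS", "PD-L2", "CD40", "CD44", "CD27",
    ],
    "Immune Cell Typing": [
        "CD45RO", "FOXP3", "CD34", "CD66b", "FAP-alpha", "CD14", "CD163",
    ],
    "Pan-Tumour Module": [
        "MART1", "NY-ESO-1", "S100B", "Bcl-2", "EpCAM", "Her2", "PTEN",
        "ER-alpha", "PR",
    ],
}


class PanelError(ValueError):
    """Raised when a probe panel violates its invariants."""


@dataclass
class ProbePanel:
    """Probe annotation table.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``probe_id``, ``probe_class``, ``module`` and optionally
        ``host`` (antibody host species for IgG controls).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"probe_id", "probe_class", "module"}
        missing = required - set(self.table.columns)
        if missing:
            raise PanelError(f"panel missing required column(s): {sorted(missing)}")
        if "host" not in self.table.columns:
            self.table = self.table.assign(host=None)
        ids = self.table["probe_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise PanelError(f"duplicate probe_id(s): {dup}")
        bad = set(self.table["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise PanelError(
                f"unknown probe_class {sorted(bad)}; allowed: {list(PROBE_CLASSES)}"
            )
        self.table = self.table.reset_index(drop=True)

    # -- class accessors -------------------------------------------------
    def _ids(self, cls: str) -> list[str]:
        mask = self.table["probe_class"] == cls
        return self.table.loc[mask, "probe_id"].tolist()

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    @property
    def targets(self) -> list[str]:
        return self._ids("target")

    @property
    def igg_controls(self) -> list[str]:
        return self._ids("igg_control")

    @property
    def housekeepers(self) -> list[str]:
        return self._ids("housekeeper")

    def probe_class(self, probe_id: str) -> str:
        row = self.table.loc[self.table["probe_id"] == probe_id]
        if row.empty:
            raise KeyError(probe_id)
        return row["probe_class"].iloc[0]

    def module(self, probe_id: str) -> str:
        row = self.table.loc[self.table["probe_id"] == probe_id]
        if row.empty:
            raise KeyError(probe_id)
        return row["module"].iloc[0]

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in set(self.table["probe_id"])

    def validate_for_pipeline(self) -> None:
        """The pipeline needs >=1 IgG control and >=2 housekeepers."""
        if len(self.igg_controls) < 1:
            raise PanelError("pipeline requires at least 1 igg_control probe")
        if len(self.housekeepers) < 2:
            raise PanelError("pipeline requires at least 2 housekeeper probes")

    def subset(self, probe_ids: list[str]) -> "ProbePanel":
        keep = self.table[self.table["probe_id"].isin(probe_ids)]
        return ProbePanel(keep.copy())


def make_default_panel() -> ProbePanel:
    """Build the default 58-probe panel (52 targets + 3 IgG + 3 housekeepers)."""
    rows = [
        {"probe_id": p, "probe_class": c, "module": m, "host": h}
        for p, c, m, h in _CONTROLS
    ]
    for module, probes in _MODULES.items():
        rows.extend(
            {"probe_id": p, "probe_class": "target", "module": module, "host": None}
            for p in probes
        )
    return ProbePanel(pd.DataFrame(rows))
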